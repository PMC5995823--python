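import itertools

import numpy as np
import pytest

import pepgram as pg
from pepgram.core import circular_diff
from pepgram.words import RfConfig


@pytest.mark.parametrize("n,expected", [(3, (3, 2)), (4, (3, 3)), (5, (4, 3)),
                                        (6, (4, 4)), (7, (5, 4)), (10, (6, 6))])
def test_minimal_fragment_lengths_formula(n, expected):
    assert pg.minimal_fragment_lengths(n) == expected


def test_minimal_fragment_lengths_rejects_small_targets():
    with pytest.raises(ValueError):
        pg.minimal_fragment_lengths(2)


class TestSplicePlan:
    def test_pentapeptide_from_two_tetrapeptides(self):
        # the published GGGGG construction: N-fragment supplies target units
        # 1-2, C-fragment supplies 3-4 from its units 2-3, junction (2, 3)
        plan = pg.make_splice_plan(5, 4, 4)
        assert list(plan.n_targets) == [1, 2]
        assert list(plan.c_targets) == [3, 4]
        assert list(plan.c_units_used) == [2, 3]
        assert plan.junction == (2, 3)

    def test_tetrapeptide_from_two_tetrapeptides(self):
        plan = pg.make_splice_plan(4, 4, 4)
        assert list(plan.n_targets) == [1, 2]
        assert list(plan.c_units_used) == [3]
        assert plan.junction == (2, 3)

    def test_tripeptide_from_two_tripeptides(self):
        plan = pg.make_splice_plan(3, 3, 3)
        assert list(plan.n_targets) == [1]
        assert list(plan.c_units_used) == [2]
        assert plan.junction == (1, 2)

    def test_default_lengths_are_minimal(self):
        plan = pg.make_splice_plan(7)
        assert (plan.n1, plan.n2) == pg.minimal_fragment_lengths(7)

    def test_unit_coverage_is_gap_free_partition(self):
        """For every valid (n, n1, n2) with n <= 12 the two fragments supply
        each target unit exactly once."""
        checked = 0
        for n in range(3, 13):
            for n1 in range(3, n + 1):
                for n2 in range(2, n + 1):
                    try:
                        plan = pg.SplicePlan(n=n, n1=n1, n2=n2)
                    except ValueError:
                        continue
                    assert plan.target_coverage() == list(range(1, n)), (n, n1, n2)
                    used = plan.c_units_used
                    assert used[0] >= 1 and used[-1] <= n2 - 1
                    checked += 1
        assert checked > 50

    def test_uncoverable_fragments_rejected(self):
        with pytest.raises(ValueError):
            pg.SplicePlan(n=8, n1=3, n2=3)
        with pytest.raises(ValueError):
            pg.SplicePlan(n=5, n1=2, n2=4)


class TestGenerateTrials:
    def test_cross_product_counts(self):
        plan = pg.make_splice_plan(5, 4, 4)
        ensN = pg.sample_ensemble("GFGG", 7, seed=1)
        ensC = pg.sample_ensemble("GFGG", 11, seed=2)
        trials = pg.generate_trials(ensN, ensC, plan)
        assert len(trials) == 77
        one = pg.generate_trials(
            pg.sample_ensemble("GFGG", 1, seed=3), pg.sample_ensemble("GFGG", 1, seed=4), plan
        )
        assert len(one) == 1

    def test_units_inherited_from_parents(self):
        plan = pg.make_splice_plan(5, 4, 4)
        ensN = pg.sample_ensemble("GFGG", 5, seed=5)
        ensC = pg.sample_ensemble("GFGG", 4, seed=6)
        byid_n = {c.id: c for c in ensN.low_energy}
        byid_c = {c.id: c for c in ensC.low_energy}
        for t in pg.generate_trials(ensN, ensC, plan):
            a, b = byid_n[t.parents[0]], byid_c[t.parents[1]]
            assert len(t.units) == 4
            # head from the N-parent, tail (incl. the junction unit) from the C-parent
            assert [u.as_tuple() for u in t.units[:2]] == [u.as_tuple() for u in a.units[:2]]
            assert [u.as_tuple() for u in t.units[2:]] == [u.as_tuple() for u in b.units[1:3]]

    def test_low_energy_window_limits_parents(self):
        plan = pg.make_splice_plan(3, 3, 3)
        ens = pg.sample_ensemble("GFG", 30, seed=7, energy_window=5.0)
        n_low = len(ens.low_energy)
        assert n_low < 30  # uniform (0, 10] energies exceed a 5 kcal/mol window
        trials = pg.generate_trials(ens, ens, plan)
        assert len(trials) == n_low**2

    def test_mismatched_fragment_length_rejected(self):
        plan = pg.make_splice_plan(5, 4, 4)
        with pytest.raises(ValueError):
            pg.generate_trials(
                pg.sample_ensemble("GFG", 3, seed=0), pg.sample_ensemble("GFGG", 3, seed=0), plan
            )


# a planted rule whose complement is itself far from every allowed centre,
# so both labels are unambiguous at the junction
ALLOWED = [("alphaR", "alphaR"), ("alphaL", "alphaL"), ("alphaR", "alphaL")]


@pytest.fixture(scope="module")
def grammar_model():
    combos = pg.make_grammar_benchmark(500, 500, margin=30, seed=8, allowed=ALLOWED)
    train, hold = pg.split_dataset(combos, 0.6, seed=8)
    return pg.train_grammar(train, hold, RfConfig(n_trees=500, random_state=8))


class TestScreenTrials:

    def test_accept_everything_model_keeps_all(self):
        class AcceptAll:
            def predict(self, X):
                return np.ones(len(X), dtype=int)

        plan = pg.make_splice_plan(5, 4, 4)
        trials = pg.generate_trials(
            pg.sample_ensemble("GFGG", 4, seed=9), pg.sample_ensemble("GFGG", 4, seed=10), plan
        )
        kept = pg.screen_trials(trials, AcceptAll(), plan)
        assert kept == trials
        assert all(t.screened == "accept" for t in kept)

    def test_survivors_match_exhaustive_junction_oracle(self, grammar_model):
        """Survival equals a brute-force check of each trial's junction pair
        against the planted allowed basin pairs."""
        basins = {b.name: np.array(b.mean) for b in pg.default_basins()
                  if b.name in ("alphaR", "alphaL")}
        spec = pg.GrammarSpec(allowed=frozenset(ALLOWED))
        plan = pg.make_splice_plan(5, 4, 4)
        ensN = pg.sample_ensemble("GFGG", 15, grammar=spec, seed=11)
        ensC = pg.sample_ensemble("GFGG", 15, grammar=spec, seed=12)
        trials = pg.generate_trials(ensN, ensC, plan)
        survivors = pg.screen_trials(trials, grammar_model, plan)

        def junction_allowed(t):
            u1, u2 = t.units[plan.junction[0] - 1], t.units[plan.junction[1] - 1]

            def basin_of(u):
                d = {n: np.max(circular_diff(np.array(u.as_tuple()), c)) for n, c in basins.items()}
                return min(d, key=d.get)

            return (basin_of(u1), basin_of(u2)) in spec.allowed

        oracle = [t for t in trials if junction_allowed(t)]
        assert [t.parents for t in survivors] == [t.parents for t in oracle]

    def test_survivors_are_an_ordered_subset(self, grammar_model):
        plan = pg.make_splice_plan(5, 4, 4)
        trials = pg.generate_trials(
            pg.sample_ensemble("GFGG", 10, seed=13), pg.sample_ensemble("GFGG", 10, seed=14), plan
        )
        survivors = pg.screen_trials(trials, grammar_model, plan)
        assert len(survivors) <= len(trials)
        ids = [t.parents for t in trials]
        assert [t.parents for t in survivors] == [p for p in ids if p in {t.parents for t in survivors}]


class TestSubstituteFragment:
    def _classes(self):
        # ggg units share classes with gfg units (planted equivalence)
        return pg.UnitClasses(mapping={"ggg1": 0, "ggg2": 1, "gfg1": 0, "gfg2": 1,
                                       "gtg1": 0, "gtg2": 0}, k=2)

    def test_equivalent_ensemble_substituted_and_tagged(self):
        gfg = pg.sample_ensemble("GFG", 5, seed=15)
        out = pg.substitute_fragment("GGG", self._classes(), [gfg])
        assert out.peptide == "GGG"
        assert out.meta["substituted_from"] == "GFG"
        assert [c.unit_array().tolist() for c in out.conformers] == [
            c.unit_array().tolist() for c in gfg.conformers
        ]

    def test_incompatible_candidate_reported_in_error(self):
        gtg = pg.sample_ensemble("GTG", 5, seed=16)
        with pytest.raises(ValueError, match="gtg2"):
            pg.substitute_fragment("GGG", self._classes(), [gtg])

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            pg.substitute_fragment("GGG", self._classes(), [])


class TestDedupeTrials:
    def _trial(self, units):
        return pg.TrialStructure(units=[pg.PhiPsiUnit(*u) for u in units], parents=("a", "b"))

    def test_identical_trials_collapse(self):
        t = [self._trial([(0, 0), (10, 10)]), self._trial([(0, 0), (10, 10)])]
        assert len(pg.dedupe_trials(t)) == 1

    def test_zero_tolerance_keeps_distinct(self):
        t = [self._trial([(0, 0)]), self._trial([(0.001, 0)]), self._trial([(5, 5)])]
        assert len(pg.dedupe_trials(t, tol=0)) == 3

    def test_matches_quadratic_brute_force(self, rng):
        trials = [self._trial(rng.uniform(-180, 180, size=(2, 2))) for _ in range(200)]
        tol = 40.0  # coarse so duplicates actually occur
        kept = pg.dedupe_trials(trials, tol=tol)
        # brute force greedy first-keeper
        ref = []
        for t in trials:
            a = t.unit_array().ravel()
            if not any(np.all(circular_diff(a, r.unit_array().ravel()) <= tol) for r in ref):
                ref.append(t)
        assert len(kept) == len(ref)
        assert [id(t) for t in kept] == [id(t) for t in ref]
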