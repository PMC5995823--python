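import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pepgram as pg
from pepgram.core import circular_diff
from pepgram.words import RfConfig

FAST_RF = RfConfig(n_trees=200, random_state=0)


def _toy_ensemble(unit_rows, peptide="GGG", energies=None):
    energies = energies or [0.0] * len(unit_rows)
    return pg.Ensemble(
        peptide=peptide,
        conformers=[
            pg.ConformerRecord(units=row, energy_rel=e, id=f"c{i}")
            for i, (row, e) in enumerate(zip(unit_rows, energies))
        ],
    )


def _brute_force_labels(conformers, combos, noise=3.0):
    out = []
    for combo in combos:
        ok = any(
            all(circular_diff(x, y) <= noise for x, y in zip(combo, obs))
            for obs in conformers
        )
        out.append(int(ok))
    return out


class TestEnumeratePairDataset:
    def test_single_conformer_self_combination(self):
        ens = _toy_ensemble([[(10, 20), (30, 40)]])
        data = pg.enumerate_pair_dataset([ens], (1, 2))
        assert len(data) == 1 and data[0].label == 1

    def test_two_conformer_cross_product(self):
        ens = _toy_ensemble([[(0, 0), (0, 0)], [(100, 100), (100, 100)]])
        data = pg.enumerate_pair_dataset([ens], (1, 2))
        assert len(data) == 4
        assert sum(c.label for c in data) == 2  # only the two observed diagonals

    @pytest.mark.parametrize("shift,label", [(2.9, 1), (3.1, 0)])
    def test_noise_threshold_boundary(self, shift, label):
        base = [(-60.0, -45.0), (-120.0, 130.0)]
        shifted = [(-60.0 + shift, -45.0 + shift), (-120.0 + shift, 130.0 + shift)]
        ens = _toy_ensemble([base, shifted])
        data = pg.enumerate_pair_dataset([ens], (1, 2))
        combo = next(
            c for c in data
            if c.phi_i == pytest.approx(-60 + shift) and c.phi_j == pytest.approx(-120.0)
        )
        # mixed combination: unit i from the shifted conformer, unit j from the base
        expected = _brute_force_labels(
            [np.r_[a[0], a[1]] for a in (base, shifted)], [combo.angles()]
        )[0]
        assert combo.label == expected == label

    def test_matches_brute_force_enumeration(self, rng):
        rows = [
            [tuple(rng.uniform(-180, 180, 2)), tuple(rng.uniform(-180, 180, 2))]
            for _ in range(5)
        ]
        ens = _toy_ensemble(rows)
        data = pg.enumerate_pair_dataset([ens], (1, 2))
        obs = [np.r_[r[0], r[1]] for r in rows]
        vals_i = {tuple(np.round(r[0], 9)) for r in rows}
        vals_j = {tuple(np.round(r[1], 9)) for r in rows}
        assert len(data) == len(vals_i) * len(vals_j)
        expected = _brute_force_labels(obs, [c.angles() for c in data])
        assert [c.label for c in data] == expected

    def test_observed_conformers_always_labeled_favorable(self, rng):
        rows = [
            [tuple(rng.uniform(-180, 180, 2)), tuple(rng.uniform(-180, 180, 2))]
            for _ in range(6)
        ]
        ens = _toy_ensemble(rows)
        data = {tuple(np.round(c.angles(), 6)): c.label for c in pg.enumerate_pair_dataset([ens], (1, 2))}
        for r in rows:
            assert data[tuple(np.round(np.r_[r[0], r[1]], 6))] == 1

    def test_pair_indices_validated(self):
        ens = _toy_ensemble([[(0, 0), (0, 0)]])
        with pytest.raises(ValueError):
            pg.enumerate_pair_dataset([ens], (1, 3))
        with pytest.raises(ValueError):
            pg.enumerate_pair_dataset([ens], (2, 3))

    def test_only_low_energy_conformers_enter(self):
        ens = _toy_ensemble(
            [[(0, 0), (0, 0)], [(100, 100), (100, 100)]], energies=[0.0, 11.0]
        )
        data = pg.enumerate_pair_dataset([ens], (1, 2))
        assert len(data) == 1


class TestSplitDataset:
    def _data(self, n=100):
        return pg.make_grammar_benchmark(n // 2, n // 2, margin=30, seed=9)

    def test_60_40_split_sizes(self):
        train, hold = pg.split_dataset(self._data(100), 0.6, seed=0)
        assert len(train) == 60 and len(hold) == 40
        # stratified: positive share preserved
        assert sum(c.label for c in train) == 30

    def test_boundary_fractions_rejected(self):
        for frac in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pg.split_dataset(self._data(20), frac, seed=0)

    def test_same_seed_identical_split(self):
        d = self._data(60)
        t1, h1 = pg.split_dataset(d, 0.6, seed=7)
        t2, h2 = pg.split_dataset(d, 0.6, seed=7)
        assert [c.angles().tolist() for c in t1] == [c.angles().tolist() for c in t2]
        assert [c.angles().tolist() for c in h1] == [c.angles().tolist() for c in h2]

    def test_single_label_rejected(self):
        d = [pg.PairCombo(0, 0, 0, 0, label=1)] * 10
        with pytest.raises(ValueError):
            pg.split_dataset(d, 0.6, seed=0)


class TestGrammarTraining:
    def test_separable_benchmark_learned_below_two_percent(self):
        combos = pg.make_grammar_benchmark(300, 300, margin=30, seed=3)
        train, hold = pg.split_dataset(combos, 0.6, seed=3)
        model = pg.train_grammar(train, hold, FAST_RF)
        assert model.in_sample_error_ < 0.02
        assert model.out_of_sample_error_ < 0.02

    def test_random_labels_are_unlearnable(self, rng):
        X = rng.uniform(-180, 180, size=(400, 4))
        y = rng.integers(0, 2, size=400)
        data = [pg.PairCombo(*x, label=int(l)) for x, l in zip(X, y)]
        train, hold = pg.split_dataset(data, 0.6, seed=0)
        model = pg.train_grammar(train, hold, FAST_RF)
        assert model.out_of_sample_error_ == pytest.approx(0.5, abs=0.12)

    def test_training_is_deterministic_given_seed(self):
        combos = pg.make_grammar_benchmark(100, 100, margin=30, seed=4)
        train, hold = pg.split_dataset(combos, 0.6, seed=4)
        m1 = pg.train_grammar(train, hold, FAST_RF)
        m2 = pg.train_grammar(train, hold, FAST_RF)
        X = np.array([c.angles() for c in hold])
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_single_label_training_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(ValueError):
            pg.GrammarClassifier().fit(X, np.ones(10, dtype=int))


class TestStabilityCheck:
    def test_errors_stable_across_fractions(self):
        combos = pg.make_grammar_benchmark(250, 250, margin=30, seed=5)
        report = pg.stability_check(combos, [0.5, 0.6, 0.7], seed=5, rf=FAST_RF)
        assert len(report["runs"]) == 3
        assert report["all_below_threshold"]
        for run in report["runs"]:
            assert run["out_of_sample_error"] < 0.02
            assert "seed" in run  # provenance

    def test_empty_fraction_list(self):
        report = pg.stability_check([], [], seed=0)
        assert report["runs"] == [] and report["all_below_threshold"]


@pytest.fixture(scope="module")
def trained():
    combos = pg.make_grammar_benchmark(300, 300, margin=30, seed=6)
    train, hold = pg.split_dataset(combos, 0.6, seed=6)
    return pg.train_grammar(train, hold, FAST_RF), train


class TestScreenCombo:

    def test_training_positive_accepted(self, trained):
        model, train = trained
        pos = next(c for c in train if c.label == 1)
        assert pg.screen_combo(model, pos)

    def test_planted_disallowed_region_rejected(self, trained):
        model, _ = trained
        # deep inside a disallowed basin pair (alphaL followed by alphaL)
        assert not pg.screen_combo(model, (57, 47, 57, 47))

    def test_screening_deterministic(self, trained):
        model, _ = trained
        combo = (-63, -43, -120, 130)
        assert all(pg.screen_combo(model, combo) == pg.screen_combo(model, combo) for _ in range(3))

    def test_untrained_model_rejected(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            pg.screen_combo(pg.GrammarClassifier(), (0, 0, 0, 0))
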