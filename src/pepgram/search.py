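"""Divide-and-conquer trial-structure generation and screening.

An n-residue target is split into an N-side fragment of n1 residues and a
C-side fragment of n2 residues that overlap at the junction residue.  Trial
unit strings are all cross-combinations of the two fragments' low-energy
conformers: target units 1..n1-2 come from the N-fragment, and target units
n1-1..n-1 come from the C-fragment (C-fragment unit k maps to target unit
k + n - n2).  At the boundary the C-fragment's value is authoritative — its
first used unit *replaces* the N-fragment's value for target unit n1-1.
Each trial is screened at the junction pair (n1-2, n1-1) by a trained
grammar model; only survivors are emitted for external optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ConformerRecord, Ensemble, PhiPsiUnit, circular_diff
from .grammar import GrammarClassifier
from .words import UnitClasses

__all__ = [
    "SplicePlan",
    "TrialStructure",
    "minimal_fragment_lengths",
    "make_splice_plan",
    "generate_trials",
    "screen_trials",
    "substitute_fragment",
    "dedupe_trials",
]


def minimal_fragment_lengths(n: int) -> tuple[int, int]:
    """Minimal (n1, n2) fragment lengths for an n-residue target:
    n1 = int((n-1)/2) + 2 and n2 = int(n/2) + 1 (integer truncation)."""
    if n < 3:
        raise ValueError(f"target length must be >= 3, got {n}")
    return (n - 1) // 2 + 2, n // 2 + 1


@dataclass(frozen=True)
class SplicePlan:
    """Mapping of two fragments' unit indices onto the target's units."""

    n: int
    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 < 3:
            raise ValueError("N-fragment must have n1 >= 3")
        if self.n2 < 2:
            raise ValueError("C-fragment must have n2 >= 2")
        if self.c_units_used[0] < 1:
            raise ValueError(
                f"fragments too short to cover {self.n} residues: "
                f"n1={self.n1}, n2={self.n2}"
            )
        if self.n1 - 2 > self.n - 2:
            raise ValueError("N-fragment longer than the target allows")

    @property
    def c_offset(self) -> int:
        """C-fragment unit k supplies target unit k + c_offset."""
        return self.n - self.n2

    @property
    def n_targets(self) -> range:
        """Target units supplied by the N-fragment (1..n1-2)."""
        return range(1, self.n1 - 1)

    @property
    def c_targets(self) -> range:
        """Target units supplied by the C-fragment (n1-1..n-1)."""
        return range(self.n1 - 1, self.n)

    @property
    def c_units_used(self) -> range:
        """C-fragment unit indices that map into the target."""
        return range(self.n1 - 1 - self.c_offset, self.n - self.c_offset)

    @property
    def junction(self) -> tuple[int, int]:
        """Adjacent target unit pair screened by the grammar."""
        return (self.n1 - 2, self.n1 - 1)

    def target_coverage(self) -> list[int]:
        """Multiset of target unit indices supplied by the two fragments."""
        return sorted(list(self.n_targets) + list(self.c_targets))


def make_splice_plan(n: int, n1: Optional[int] = None, n2: Optional[int] = None) -> SplicePlan:
    """Build a :class:`SplicePlan`; fragment lengths default to the minimal
    formulas of :func:`minimal_fragment_lengths`."""
    if n < 3:
        raise ValueError(f"target length must be >= 3, got {n}")
    min1, min2 = minimal_fragment_lengths(n)
    return SplicePlan(n=n, n1=n1 if n1 is not None else min1,
                      n2=n2 if n2 is not None else min2)


@dataclass
class TrialStructure:
    """A spliced trial unit string with its parent conformer ids."""

    units: list[PhiPsiUnit]
    parents: tuple[str, str]
    screened: str = "not-yet"  # accept / reject / not-yet

    def unit_array(self) -> np.ndarray:
        return np.array([u.as_tuple() for u in self.units], dtype=float)


def generate_trials(ensN: Ensemble, ensC: Ensemble, plan: SplicePlan) -> list[TrialStructure]:
    """All cross-combinations of the two fragments' low-energy conformers.

    Exactly ``|low_energy(ensN)| * |low_energy(ensC)|`` trials, ordered
    lexicographically by (N-parent id, C-parent id).
    """
    if ensN.n_units != plan.n1 - 1:
        raise ValueError(
            f"N-fragment {ensN.peptide} has {ensN.n_units} units, plan needs {plan.n1 - 1}"
        )
    if ensC.n_units != plan.n2 - 1:
        raise ValueError(
            f"C-fragment {ensC.peptide} has {ensC.n_units} units, plan needs {plan.n2 - 1}"
        )
    lowN = sorted(ensN.low_energy, key=lambda c: c.id)
    lowC = sorted(ensC.low_energy, key=lambda c: c.id)
    if not lowN or not lowC:
        raise ValueError("both fragment ensembles must have low-energy conformers")
    trials = []
    for a in lowN:
        head = [a.units[t - 1] for t in plan.n_targets]
        for b in lowC:
            tail = [b.units[k - 1] for k in plan.c_units_used]
            trials.append(TrialStructure(units=head + tail, parents=(a.id, b.id)))
    return trials


def screen_trials(trials: Sequence[TrialStructure], model: GrammarClassifier,
                  plan: SplicePlan) -> list[TrialStructure]:
    """Keep the trials whose junction combination the grammar accepts.

    The screened pair is the plan's junction (units n1-2 and n1-1 of the
    target).  Order is preserved; each trial's ``screened`` field is set.
    """
    if not trials:
        return []
    j1, j2 = plan.junction
    X = np.array(
        [
            np.r_[t.units[j1 - 1].as_tuple(), t.units[j2 - 1].as_tuple()]
            for t in trials
        ]
    )
    verdicts = model.predict(X)
    survivors = []
    for t, v in zip(trials, verdicts):
        t.screened = "accept" if v == 1 else "reject"
        if v == 1:
            survivors.append(t)
    return survivors


def substitute_fragment(target_fragment: str, classes: UnitClasses,
                        available: Sequence[Ensemble]) -> Ensemble:
    """Find an available ensemble class-equivalent to a requested fragment.

    Every unit of the candidate must share the class of the corresponding
    unit of ``target_fragment`` under ``classes``.  The returned ensemble
    is relabelled with the target's residue identities (so rebuilt
    structures carry the target's side chains) and tagged with the
    substitution in ``meta``.
    """
    target_fragment = target_fragment.upper()
    if not available:
        raise ValueError("no candidate ensembles supplied")
    n_units = len(target_fragment) - 1
    near_misses = []
    for ens in available:
        if ens.n_units != n_units:
            near_misses.append(f"{ens.peptide}: wrong length ({ens.n_units} units)")
            continue
        mismatches = []
        for i in range(1, n_units + 1):
            want = f"{target_fragment.lower()}{i}"
            have = f"{ens.peptide.lower()}{i}"
            try:
                if classes.class_of(want) != classes.class_of(have):
                    mismatches.append(f"unit {i}: {have} not in class of {want}")
            except KeyError as exc:
                mismatches.append(f"unit {i}: {exc.args[0]}")
        if not mismatches:
            return ens.with_peptide(
                target_fragment,
                substituted_from=ens.peptide,
                substituted_for=target_fragment,
            )
        near_misses.append(f"{ens.peptide}: " + "; ".join(mismatches))
    raise ValueError(
        f"no class-compatible ensemble for {target_fragment}; candidates: "
        + " | ".join(near_misses)
    )


def dedupe_trials(trials: Sequence[TrialStructure], tol: float = 3.0) -> list[TrialStructure]:
    """Greedy first-keeper deduplication: drop any trial whose unit string is
    within ``tol`` degrees (circular, per angle) of an earlier keeper."""
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    kept: list[TrialStructure] = []
    kept_arr: list[np.ndarray] = []
    for t in trials:
        arr = t.unit_array().ravel()
        dup = any(np.all(circular_diff(arr, k) <= tol) for k in kept_arr)
        if not dup:
            kept.append(t)
            kept_arr.append(arr)
    return kept
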