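"""Synthetic conformer ensembles with planted word classes and grammar.

The generator emulates the structure the analysis modules are built to
detect: each unit draws its (phi, psi) from a mixture of Ramachandran-like
basins (alpha-R, beta, PPII, alpha-L, gamma by default, 10-degree spread),
with the mixture weights depending on the unit's planted class and the
adjacent-unit basin pairs restricted to a planted allowed set.  Basin noise
is a truncated (3 sigma) wrapped Gaussian, so basins stay disjoint and the
planted ground truth is unambiguous for oracle tests.  Relative energies
are a placeholder (minimum 0, others uniform in (0, 10]); nothing
energetic is claimed or tested on generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ConformerRecord, Ensemble, PhiPsiUnit, circular_diff, wrap_angle
from .grammar import PairCombo

__all__ = [
    "BasinSpec",
    "GrammarSpec",
    "default_basins",
    "sample_ensemble",
    "make_grammar_benchmark",
]


@dataclass(frozen=True)
class BasinSpec:
    """One Ramachandran basin: centre and isotropic spread, in degrees."""

    name: str
    mean: tuple[float, float]
    std: float = 10.0

    def __post_init__(self):
        if self.std <= 0:
            raise ValueError("basin std must be > 0")
        object.__setattr__(self, "mean", (wrap_angle(self.mean[0]), wrap_angle(self.mean[1])))


def default_basins() -> list[BasinSpec]:
    """Five canonical basins: alpha-R, beta, PPII, alpha-L, gamma."""
    return [
        BasinSpec("alphaR", (-63.0, -43.0)),
        BasinSpec("beta", (-120.0, 130.0)),
        BasinSpec("ppII", (-75.0, 150.0)),
        BasinSpec("alphaL", (57.0, 47.0)),
        BasinSpec("gamma", (-85.0, 70.0)),
    ]


@dataclass(frozen=True)
class GrammarSpec:
    """Planted combination rule: allowed (basin, basin) pairs for adjacent
    units, and the margin (degrees) separating allowed from disallowed
    regions in benchmark generation."""

    allowed: frozenset
    margin: float = 30.0

    def __post_init__(self):
        object.__setattr__(self, "allowed", frozenset(tuple(p) for p in self.allowed))
        if not self.allowed:
            raise ValueError("allowed set must be non-empty")


def _truncated_basin_noise(rng: np.random.Generator, std: float, size) -> np.ndarray:
    """Gaussian noise re-drawn until within 3 sigma (keeps basins disjoint)."""
    out = rng.normal(0.0, std, size=size)
    bad = np.abs(out) > 3 * std
    while np.any(bad):
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 3 * std
    return out


def sample_ensemble(seq: str, n_conf: int, basins: Optional[Sequence[BasinSpec]] = None,
                    class_weights: Optional[Sequence[dict]] = None,
                    grammar: Optional[GrammarSpec] = None, seed: int = 0,
                    energy_window: float = 10.0) -> Ensemble:
    """Draw a synthetic ensemble for peptide ``seq``.

    ``class_weights`` gives, per unit, a dict basin-name -> weight (units
    sharing a dict are planted equivalents); default is uniform over all
    basins.  When a ``grammar`` is given, each unit after the first draws
    only from basins allowed to follow the previous unit's basin.  The
    first conformer sits at energy 0, the rest uniform in (0, 10].
    """
    if n_conf < 1:
        raise ValueError("n_conf must be >= 1")
    seq = seq.upper()
    n_units = len(seq) - 1
    if n_units < 1:
        raise ValueError("need at least a dipeptide")
    basins = list(basins) if basins is not None else default_basins()
    by_name = {b.name: b for b in basins}
    if class_weights is None:
        class_weights = [{b.name: 1.0 for b in basins}] * n_units
    if len(class_weights) != n_units:
        raise ValueError(f"need {n_units} class-weight profiles, got {len(class_weights)}")
    if grammar is not None:
        successors = {
            b.name: [q for (p, q) in grammar.allowed if p == b.name] for b in basins
        }
        reachable = {b for (b, _) in grammar.allowed} | {b for (_, b) in grammar.allowed}
        dead = [b for b in reachable if not successors.get(b)]
        if n_units > 1 and dead:
            raise ValueError(f"inconsistent grammar: no allowed continuation from {dead}")
    rng = np.random.default_rng(seed)
    conformers = []
    for ic in range(n_conf):
        chosen = []
        for u in range(n_units):
            weights = class_weights[u]
            if grammar is None:
                names = [b.name for b in basins if weights.get(b.name, 0) > 0]
            elif u == 0:
                # the first unit must leave at least one allowed continuation
                starts = [b.name for b in basins
                          if successors[b.name] or n_units == 1]
                names = [nm for nm in starts if weights.get(nm, 0) > 0] or starts
            else:
                allowed_next = successors[chosen[-1]]
                names = [nm for nm in allowed_next if weights.get(nm, 0) > 0]
                if not names:
                    names = allowed_next  # grammar overrides weights rather than dead-ending
            if not names:
                raise ValueError(f"no basin available for unit {u + 1}")
            w = np.array([max(weights.get(nm, 0.0), 0.0) for nm in names])
            if w.sum() == 0:
                w = np.ones(len(names))
            chosen.append(names[rng.choice(len(names), p=w / w.sum())])
        units = []
        for nm in chosen:
            b = by_name[nm]
            noise = _truncated_basin_noise(rng, b.std, 2)
            units.append(PhiPsiUnit(b.mean[0] + noise[0], b.mean[1] + noise[1]))
        energy = 0.0 if ic == 0 else float(rng.uniform(np.nextafter(0.0, 1.0), 10.0))
        conformers.append(ConformerRecord(units=units, energy_rel=energy, id=f"synth-{ic + 1:04d}"))
    return Ensemble(peptide=seq, conformers=conformers, energy_window=energy_window,
                    meta={"seed": seed, "generator": "sample_ensemble"})


def make_grammar_benchmark(n_pos: int, n_neg: int, margin: float = 30.0, seed: int = 0,
                           basins: Optional[Sequence[BasinSpec]] = None,
                           allowed: Optional[Sequence[tuple[str, str]]] = None) -> list[PairCombo]:
    """Labelled adjacent-unit combinations with a planted separation margin.

    Positives are drawn around allowed basin-pair centres with truncated
    (3 sigma) noise.  Negatives are drawn the same way around *disallowed*
    basin pairs, restricted to the pairs whose centre lies at Chebyshev
    (max-coordinate circular) distance >= 2*3sigma + margin from every
    allowed centre, so ``margin`` is the true gap between the supports of
    the two labels.  Returns n_pos positives followed by n_neg negatives.
    """
    if margin <= 0:
        raise ValueError("margin must be > 0 (margin 0 leaves the classes overlapping)")
    basins = list(basins) if basins is not None else default_basins()
    by_name = {b.name: b for b in basins}
    if allowed is None:
        allowed = [("alphaR", "alphaR"), ("beta", "ppII"), ("ppII", "beta"),
                   ("alphaR", "beta"), ("beta", "alphaR")]
    allowed = [tuple(p) for p in allowed]
    centres = np.array(
        [np.r_[by_name[p].mean, by_name[q].mean] for p, q in allowed]
    )
    std = max(b.std for b in basins)

    def _centre(p, q):
        return np.r_[by_name[p].mean, by_name[q].mean]

    # disallowed pairs far enough from every allowed centre for the margin
    # to be a genuine support gap (both supports extend 3 sigma)
    exclusion = 2 * 3 * std + margin
    disallowed = [
        (p.name, q.name)
        for p in basins
        for q in basins
        if (p.name, q.name) not in allowed
        and np.min(np.max(circular_diff(centres, _centre(p.name, q.name)), axis=1)) >= exclusion
    ]
    if n_neg > 0 and not disallowed:
        raise ValueError(
            f"margin {margin} with 3*sigma={3 * std} leaves no disallowed basin "
            "pair far enough from the allowed centres; no negatives can be placed"
        )
    rng = np.random.default_rng(seed)

    def _draw(pairs, label, count, tag):
        out = []
        for _ in range(count):
            p, q = pairs[rng.integers(len(pairs))]
            bp, bq = by_name[p], by_name[q]
            mean = np.r_[bp.mean, bq.mean]
            stds = np.array([bp.std, bp.std, bq.std, bq.std])
            x = mean + _truncated_basin_noise(rng, 1.0, 4) * stds
            out.append(PairCombo(*wrap_angle(x), label=label, source=f"{tag}:{p}-{q}"))
        return out

    return _draw(allowed, 1, n_pos, "pos") + _draw(disallowed, 0, n_neg, "neg")
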