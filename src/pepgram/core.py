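"""Domain types and angle arithmetic for peptide backbone dihedral analysis.

A peptide of ``n`` residues is described by its backbone dihedral pairs
(phi, psi).  Following the unit-indexing convention used throughout this
package, *unit i* of peptide ``X1 X2 ... Xn`` is the (phi, psi) pair of
residue ``i + 1`` (residue 1 has no phi), so an n-residue peptide carries
exactly ``n - 1`` units.  Units are named by the lower-cased sequence plus
the 1-based unit index, e.g. ``"gfgg2"`` is the second unit of GFGG.

All angles are degrees, canonicalized to the half-open interval
(-180, 180] with -180 mapped to +180.  Energies are relative kcal/mol.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "wrap_angle",
    "circular_diff",
    "PhiPsiUnit",
    "UnitLabel",
    "parse_unit_label",
    "ConformerRecord",
    "Ensemble",
]


def wrap_angle(x):
    """Map an angle in degrees onto the canonical interval (-180, 180].

    Accepts scalars or array-likes; the output is congruent to the input
    modulo 360.  The boundary convention maps -180 to +180 so every angle
    has a single canonical representative.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle must be finite, got %r" % (x,))
    wrapped = -((180.0 - arr) % 360.0) + 180.0
    if np.isscalar(x) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def circular_diff(a, b):
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    return np.abs(wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


@dataclass(frozen=True)
class PhiPsiUnit:
    """One backbone (phi, psi) pair in degrees, canonicalized on creation."""

    phi: float
    psi: float

    def __post_init__(self):
        object.__setattr__(self, "phi", wrap_angle(self.phi))
        object.__setattr__(self, "psi", wrap_angle(self.psi))

    def as_tuple(self) -> tuple[float, float]:
        return (self.phi, self.psi)


_LABEL_RE = re.compile(r"^([a-z]+)([0-9]+)$")


@dataclass(frozen=True)
class UnitLabel:
    """Name of one phi-psi unit: peptide sequence plus 1-based unit index.

    Unit ``index`` belongs to residue ``index + 1``; valid indices are
    ``1 .. len(peptide) - 1``.
    """

    peptide: str
    index: int

    def __post_init__(self):
        pep = self.peptide.upper()
        if not pep.isalpha():
            raise ValueError(f"peptide must be one-letter AA codes, got {self.peptide!r}")
        object.__setattr__(self, "peptide", pep)
        if not 1 <= self.index <= len(pep) - 1:
            raise ValueError(
                f"unit index {self.index} out of range 1..{len(pep) - 1} "
                f"for peptide {pep}"
            )

    def __str__(self) -> str:
        return f"{self.peptide.lower()}{self.index}"


def parse_unit_label(text: str) -> UnitLabel:
    """Parse a unit name like ``"gfgg2"`` into a :class:`UnitLabel`.

    Round-trips through ``str()``.  Raises ``ValueError`` for malformed
    text or an index outside ``1 .. n - 1``.
    """
    m = _LABEL_RE.match(text)
    if m is None:
        raise ValueError(f"malformed unit label {text!r}; expected e.g. 'gfgg2'")
    return UnitLabel(peptide=m.group(1), index=int(m.group(2)))


@dataclass
class ConformerRecord:
    """One conformer: its ordered phi-psi units, relative energy, and
    optionally Cartesian backbone coordinates (see :mod:`pepgram.io`)."""

    units: list[PhiPsiUnit]
    energy_rel: Optional[float] = None
    coords: Optional[object] = None
    id: str = ""

    def __post_init__(self):
        self.units = [
            u if isinstance(u, PhiPsiUnit) else PhiPsiUnit(*u) for u in self.units
        ]
        if self.energy_rel is not None and self.energy_rel < -1e-9:
            raise ValueError(f"energy_rel must be >= 0, got {self.energy_rel}")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit_array(self) -> np.ndarray:
        """(n_units, 2) array of (phi, psi) degrees."""
        return np.array([u.as_tuple() for u in self.units], dtype=float)


@dataclass
class Ensemble:
    """A conformer ensemble of one peptide.

    ``low_energy`` is the working set used everywhere downstream: the
    conformers within ``energy_window`` kcal/mol of the ensemble minimum
    (default 10).  Conformers without an energy are kept in the
    low-energy view.
    """

    peptide: str
    conformers: list[ConformerRecord]
    energy_window: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.peptide = self.peptide.upper()
        if self.conformers:
            n = len(self.peptide) - 1
            for c in self.conformers:
                if c.n_units != n:
                    raise ValueError(
                        f"conformer {c.id!r} has {c.n_units} units; peptide "
                        f"{self.peptide} requires {n}"
                    )

    @property
    def n_units(self) -> int:
        return len(self.peptide) - 1

    @property
    def low_energy(self) -> list[ConformerRecord]:
        return [
            c
            for c in self.conformers
            if c.energy_rel is None or c.energy_rel <= self.energy_window
        ]

    def unit_points(self, index: int, low_energy_only: bool = True) -> np.ndarray:
        """(m, 2) array of observed (phi, psi) for unit ``index`` (1-based)."""
        if not 1 <= index <= self.n_units:
            raise ValueError(f"unit index {index} out of range 1..{self.n_units}")
        source = self.low_energy if low_energy_only else self.conformers
        return np.array(
            [source_c.units[index - 1].as_tuple() for source_c in source], dtype=float
        )

    def unit_label(self, index: int) -> UnitLabel:
        return UnitLabel(self.peptide, index)

    def with_peptide(self, peptide: str, **meta) -> "Ensemble":
        """Copy of this ensemble relabelled as ``peptide`` (same units)."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, peptide=peptide, meta=new_meta)
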