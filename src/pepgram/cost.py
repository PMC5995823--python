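"""Trial-structure cost accounting for the three search strategies.

The built-in table holds the published total trial-structure counts for
peptide backbones of n = 3..10 residues under a fully systematic rotor
enumeration (N_sys), the path-matrix approach (N_PM), and the
random-forest-screened divide-and-conquer search (N_RF).  The systematic
count grows geometrically (x12 per residue); the screened search grows by
only ~1.2x per residue, which is the method's selling point.

The N_RF entries for n >= 7 were published as estimates (assuming ~50
additional low-energy fragment conformers per added residue); they are
carried here as data, not recomputed from a formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, log10
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["CostTable", "builtin_table2", "geometric_extrapolate", "growth_factor", "round_sig"]

_TABLE2 = {
    "n": [3, 4, 5, 6, 7, 8, 9, 10],
    "N_sys": [3456, 41472, 4.98e5, 5.97e6, 7.17e7, 8.60e8, 1.03e10, 1.24e11],
    "N_PM": [240, 1130, 5310, 2.49e4, 1.17e5, 5.50e5, 2.58e6, 1.21e7],
    "N_RF": [1838, 4096, 5438, 6649, 7318, 8540, 9613, 11341],
}


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass
class CostTable:
    """Trial-structure counts per method, indexed by residue count n."""

    data: pd.DataFrame  # columns n, N_sys, N_PM, N_RF

    def __post_init__(self):
        for col in ("N_sys", "N_PM", "N_RF"):
            vals = self.data[col].to_numpy(dtype=float)
            if np.any(vals <= 0) or np.any(np.diff(vals) < 0):
                raise ValueError(f"column {col} must be positive and non-decreasing")

    def column(self, name: str) -> list[tuple[int, float]]:
        return list(zip(self.data["n"].tolist(), self.data[name].astype(float).tolist()))

    def value(self, name: str, n: int) -> float:
        row = self.data.loc[self.data["n"] == n, name]
        if row.empty:
            raise KeyError(f"n={n} not in table")
        return float(row.iloc[0])


def builtin_table2() -> CostTable:
    """The published cost table (counts as printed, including the
    scientific-notation entries)."""
    return CostTable(data=pd.DataFrame(_TABLE2))


def geometric_extrapolate(known: Sequence[tuple[int, float]], n_target: int) -> float:
    """Extrapolate a geometric growth law fitted to the first two known
    points; the result is reported to 3 significant figures."""
    if len(known) < 2:
        raise ValueError("need at least 2 known (n, count) points")
    known = sorted(known)
    (n0, c0), (n1, c1) = known[0], known[1]
    if n_target < n0:
        raise ValueError(f"target n={n_target} below smallest known n={n0}")
    for n, c in known:
        if n == n_target:
            return float(c)
    r = (c1 / c0) ** (1.0 / (n1 - n0))
    return round_sig(c0 * r ** (n_target - n0), 3)


def growth_factor(column: Sequence[tuple[int, float]], n_range: Optional[tuple[int, int]] = None) -> float:
    """Per-residue growth: geometric mean of successive count ratios over
    ``n_range`` (inclusive), to 2 significant figures."""
    pts = sorted(column)
    if n_range is not None:
        lo, hi = n_range
        pts = [(n, c) for n, c in pts if lo <= n <= hi]
    if len(pts) < 2:
        raise ValueError("need at least 2 points in the requested range")
    ratios = [pts[i + 1][1] / pts[i][1] for i in range(len(pts) - 1) if pts[i + 1][0] == pts[i][0] + 1]
    if not ratios:
        raise ValueError("no successive-n pairs in range")
    gm = float(np.exp(np.mean(np.log(ratios))))
    return round_sig(gm, 2)
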