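"""Density-of-states curves for conformer ensembles.

Each conformer at relative energy E contributes a normalized Gaussian
``(1/(alpha*sqrt(pi))) * exp(-((x - E)/alpha)^2)`` with broadening
alpha = 0.24 kcal/mol by default, so the curve integrates to the number of
conformers.  ``compare_dos`` quantifies the overlap of two curves as
``integral(min) / integral(max)`` in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["DosCurve", "dos_curve", "compare_dos", "default_grid"]

DEFAULT_ALPHA = 0.24  # kcal/mol


def default_grid(alpha: float = DEFAULT_ALPHA, e_max: float = 4.0,
                 step: float = 0.01) -> np.ndarray:
    """Energy grid 0..e_max kcal/mol, padded by 5*alpha on each side so the
    terminal Gaussians integrate fully."""
    pad = 5.0 * alpha
    return np.arange(-pad, e_max + pad + step / 2, step)


@dataclass
class DosCurve:
    grid: np.ndarray
    density: np.ndarray
    alpha: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def dos_curve(energies_rel: Sequence[float], alpha: float = DEFAULT_ALPHA,
              grid: Optional[np.ndarray] = None) -> DosCurve:
    """Sum of normalized Gaussians at the conformer relative energies."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    energies = np.asarray(list(energies_rel), dtype=float)
    if energies.size and np.any(energies < -1e-9):
        raise ValueError("relative energies must be >= 0")
    if grid is None:
        grid = default_grid(alpha)
    grid = np.asarray(grid, dtype=float)
    density = np.zeros_like(grid)
    norm = 1.0 / (alpha * math.sqrt(math.pi))
    for e in energies:
        density += norm * np.exp(-(((grid - e) / alpha) ** 2))
    return DosCurve(grid=grid, density=density, alpha=alpha)


def compare_dos(a: DosCurve, b: DosCurve) -> float:
    """Overlap of two curves on a common grid: integral(min)/integral(max)."""
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("curves must share the same energy grid")
    lo = np.trapezoid(np.minimum(a.density, b.density), a.grid)
    hi = np.trapezoid(np.maximum(a.density, b.density), a.grid)
    if hi == 0:
        return 1.0
    return float(lo / hi)
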