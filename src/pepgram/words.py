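"""Group phi-psi units into equivalence classes ("words").

The similarity of two units is measured by how badly a random forest can
tell their (phi, psi) samples apart: the out-of-bag misclassification rate
of a two-class forest, after the larger sample is down-sampled to balance
the classes.  Indistinguishable distributions sit at the 0.5 chance level,
well-separated ones near 0.  The symmetric matrix of pairwise error rates
is turned into dissimilarities (default d = 1 - e), embedded in 2D by
classical (Torgerson) multidimensional scaling, and the embedded points are
clustered by average-linkage agglomerative clustering, with the number of
classes chosen by maximum mean silhouette when not given.

Angles enter the forest as (sin phi, cos phi, sin psi, cos psi) by default
so that the 360-degree periodicity is respected; raw degrees are available
behind ``feature_encoding="degrees"``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

from .core import UnitLabel, wrap_angle

__all__ = [
    "RfConfig",
    "UnitSample",
    "ErrorRateMatrix",
    "MdsResult",
    "UnitClasses",
    "encode_angles",
    "pairwise_error_rate",
    "error_rate_matrix",
    "classical_mds",
    "mds_embed",
    "cluster_units",
    "equivalent_units",
    "WordEquivalence",
]


@dataclass(frozen=True)
class RfConfig:
    """Random-forest settings shared by the pairwise unit comparisons.

    500 trees with out-of-bag scoring; the seed is recorded so matrices are
    reproducible.
    """

    n_trees: int = 500
    random_state: int = 0
    feature_encoding: str = "sincos"  # or "degrees"


@dataclass
class UnitSample:
    """The (phi, psi) observations of one named unit across an ensemble's
    low-energy conformers."""

    label: Union[UnitLabel, str]
    points: np.ndarray

    def __post_init__(self):
        self.points = wrap_angle(np.asarray(self.points, dtype=float).reshape(-1, 2))
        if len(self.points) < 2:
            raise ValueError(f"unit sample {self.name} needs >= 2 points")

    @property
    def name(self) -> str:
        return str(self.label)


def encode_angles(points: np.ndarray, encoding: str = "sincos") -> np.ndarray:
    """Feature encoding of (n, k) angle arrays in degrees."""
    points = np.asarray(points, dtype=float)
    if encoding == "degrees":
        return points
    if encoding != "sincos":
        raise ValueError(f"unknown encoding {encoding!r}")
    rad = np.radians(points)
    feats = np.empty((points.shape[0], 2 * points.shape[1]))
    feats[:, 0::2] = np.sin(rad)
    feats[:, 1::2] = np.cos(rad)
    return feats


def _pair_seed(base: int, name_a: str, name_b: str) -> int:
    """Seed derived from the unordered label pair, so matrices are invariant
    to input order."""
    key = "|".join(sorted([name_a, name_b])).encode()
    h = int.from_bytes(hashlib.blake2s(key, digest_size=4).digest(), "big")
    return (base + h) % (2**31 - 1)


def pairwise_error_rate(a: UnitSample, b: UnitSample, rf: RfConfig = RfConfig()) -> float:
    """Out-of-bag error of a forest separating two unit samples, in [0, 1].

    Class sizes are balanced by down-sampling the larger sample (seeded).
    High error means the two phi-psi distributions are similar.  The pair
    is canonicalized by label order, so the estimate is exactly symmetric
    in its arguments.
    """
    if a.name > b.name:
        a, b = b, a
    seed = _pair_seed(rf.random_state, a.name, b.name)
    rng = np.random.default_rng(seed)
    pa, pb = a.points, b.points
    m = min(len(pa), len(pb))
    if m < 2:
        raise ValueError("need at least 2 points per sample")
    if len(pa) > m:
        pa = pa[rng.choice(len(pa), size=m, replace=False)]
    if len(pb) > m:
        pb = pb[rng.choice(len(pb), size=m, replace=False)]
    X = encode_angles(np.vstack([pa, pb]), rf.feature_encoding)
    y = np.r_[np.zeros(m, dtype=int), np.ones(m, dtype=int)]
    forest = RandomForestClassifier(
        n_estimators=rf.n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return float(1.0 - forest.oob_score_)


@dataclass
class ErrorRateMatrix:
    """Symmetric matrix of pairwise unit error rates; diagonal undefined."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        off = ~np.eye(n, dtype=bool)
        vals = self.values[off]
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise ValueError("error rates must lie in [0, 1]")
        if not np.allclose(self.values[off], self.values.T[off], atol=1e-9):
            raise ValueError("error-rate matrix must be symmetric")

    def __getitem__(self, pair) -> float:
        i = self.labels.index(str(pair[0]))
        j = self.labels.index(str(pair[1]))
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def error_rate_matrix(samples: Sequence[UnitSample], rf: RfConfig = RfConfig()) -> ErrorRateMatrix:
    """All-pairs :func:`pairwise_error_rate`, symmetric by construction."""
    if len(samples) < 2:
        raise ValueError("need at least 2 unit samples")
    names = [s.name for s in samples]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate unit labels in {names}")
    n = len(samples)
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            e = pairwise_error_rate(samples[i], samples[j], rf)
            values[i, j] = values[j, i] = e
    return ErrorRateMatrix(labels=names, values=values)


@dataclass
class MdsResult:
    """Classical-MDS embedding: normalized eigenvalue spectrum plus the
    top-2 coordinates per label."""

    labels: list[str]
    eigenvalues: np.ndarray  # normalized by the largest, non-increasing
    coordinates: np.ndarray  # (n, 2)
    degenerate: bool = False


def classical_mds(d: np.ndarray, n_components: int = 2):
    """Torgerson scaling of a dissimilarity matrix.

    Double-centers -d^2/2, eigendecomposes, and returns (eigenvalues,
    coordinates) with coordinates scaled by sqrt(max(eigenvalue, 0)).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    coords = v[:, :n_components] * np.sqrt(np.clip(w[:n_components], 0.0, None))
    return w, coords


_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "one_minus": lambda e: 1.0 - e,
}


def mds_embed(m: ErrorRateMatrix,
              transform: Union[str, Callable[[np.ndarray], np.ndarray]] = "one_minus") -> MdsResult:
    """Embed an error-rate matrix in 2D by classical MDS.

    ``transform`` maps error rates to dissimilarities and must be monotone
    decreasing (similar units -> small distance); the default is
    d = 1 - e with a zero diagonal.  Eigenvalues are reported normalized by
    the largest.
    """
    fn = _TRANSFORMS[transform] if isinstance(transform, str) else transform
    e = m.values.copy()
    n = len(m.labels)
    off = ~np.eye(n, dtype=bool)
    d = np.zeros_like(e)
    d[off] = fn(e[off])
    d = 0.5 * (d + d.T)
    degenerate = np.allclose(d[off], d[off].flat[0])
    w, coords = classical_mds(d)
    if w[0] <= 0:
        raise ValueError("degenerate dissimilarities: no positive MDS eigenvalue")
    return MdsResult(
        labels=list(m.labels),
        eigenvalues=w / w[0],
        coordinates=coords,
        degenerate=degenerate,
    )


@dataclass
class UnitClasses:
    """Partition of unit labels into equivalence classes."""

    mapping: dict[str, int]
    k: int
    degenerate: bool = False

    def members(self, class_id: int) -> list[str]:
        return [l for l, c in self.mapping.items() if c == class_id]

    def class_of(self, label) -> int:
        name = str(label)
        if name not in self.mapping:
            raise KeyError(f"unknown unit label {name!r}")
        return self.mapping[name]


def cluster_units(emb: MdsResult, k: Optional[int] = None) -> UnitClasses:
    """Group embedded units by average-linkage agglomerative clustering.

    When ``k`` is not given it is chosen by maximum mean silhouette over
    k in 2..6 (capped by the number of labels).  An all-identical embedding
    is returned as a single degenerate class.
    """
    x = emb.coordinates
    n = len(emb.labels)
    if n < 3:
        raise ValueError("need at least 3 labels to cluster")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the number of labels ({n})")
    if np.allclose(x, x[0]):
        return UnitClasses(mapping={l: 0 for l in emb.labels}, k=1, degenerate=True)
    if k is None:
        best = None
        for kk in range(2, min(6, n - 1) + 1):
            lab = AgglomerativeClustering(n_clusters=kk, linkage="average").fit_predict(x)
            s = silhouette_score(x, lab)
            if best is None or s > best[0]:
                best = (s, kk, lab)
        _, k, labels_arr = best
    else:
        labels_arr = AgglomerativeClustering(n_clusters=k, linkage="average").fit_predict(x)
    return UnitClasses(mapping=dict(zip(emb.labels, (int(c) for c in labels_arr))), k=int(k))


def equivalent_units(classes: UnitClasses, label) -> list[str]:
    """All labels sharing ``label``'s class, excluding the label itself."""
    cid = classes.class_of(label)
    name = str(label)
    return [l for l in classes.members(cid) if l != name]


class WordEquivalence(BaseEstimator):
    """Estimator bundling the unit-equivalence pipeline.

    ``fit`` takes a list of :class:`UnitSample` and computes the pairwise
    error-rate matrix, its classical-MDS embedding and the unit classes.

    Parameters
    ----------
    n_trees : forest size per pairwise comparison (default 500).
    feature_encoding : "sincos" (periodicity-aware, default) or "degrees".
    transform : error-rate -> dissimilarity map ("one_minus" or callable).
    n_classes : fixed class count; None selects it by mean silhouette.
    random_state : base seed for balancing and forests.

    Attributes (after fit)
    ----------------------
    labels_in_ : unit names in input order.
    error_rate_matrix_ : :class:`ErrorRateMatrix`.
    mds_ : :class:`MdsResult`; ``eigenvalues_`` and ``embedding_`` are views.
    classes_ : :class:`UnitClasses`; ``labels_`` the per-unit class ids.
    """

    def __init__(self, n_trees: int = 500, feature_encoding: str = "sincos",
                 transform="one_minus", n_classes: Optional[int] = None,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.feature_encoding = feature_encoding
        self.transform = transform
        self.n_classes = n_classes
        self.random_state = random_state

    def fit(self, X: Sequence[UnitSample], y=None):
        rf = RfConfig(
            n_trees=self.n_trees,
            random_state=self.random_state,
            feature_encoding=self.feature_encoding,
        )
        self.labels_in_ = [s.name for s in X]
        self.error_rate_matrix_ = error_rate_matrix(X, rf)
        self.mds_ = mds_embed(self.error_rate_matrix_, self.transform)
        self.eigenvalues_ = self.mds_.eigenvalues
        self.embedding_ = self.mds_.coordinates
        self.classes_ = cluster_units(self.mds_, self.n_classes)
        self.labels_ = np.array([self.classes_.mapping[l] for l in self.labels_in_])
        self.n_classes_ = self.classes_.k
        return self

    def fit_predict(self, X: Sequence[UnitSample], y=None) -> np.ndarray:
        return self.fit(X).labels_

    def equivalent_units(self, label) -> list[str]:
        return equivalent_units(self.classes_, label)
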