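"""Learn the combination rule ("grammar") of adjacent phi-psi units.

Within one low-energy ensemble, the observed values of unit *i* and unit
*i+1* are recombined combinatorially; a four-angle combination is labelled
favorable (1) when some low-energy conformer of the same ensemble matches
it to within a per-angle circular tolerance (3 degrees by default), else
unfavorable (0).  A random forest trained on the labelled combinations is
then a screening predicate for freshly spliced trial structures.

Combinatorial negatives vastly outnumber positives, so the forest is
trained with balanced class weights rather than by discarding negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .core import Ensemble, circular_diff
from .words import RfConfig, encode_angles

__all__ = [
    "PairCombo",
    "combos_to_arrays",
    "enumerate_pair_dataset",
    "split_dataset",
    "GrammarClassifier",
    "train_grammar",
    "evaluate_grammar",
    "stability_check",
    "screen_combo",
]


@dataclass(frozen=True)
class PairCombo:
    """One adjacent-unit combination (phi_i, psi_i, phi_j, psi_j) with its
    favorable/unfavorable label and provenance."""

    phi_i: float
    psi_i: float
    phi_j: float
    psi_j: float
    label: int
    source: str = ""

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    def angles(self) -> np.ndarray:
        return np.array([self.phi_i, self.psi_i, self.phi_j, self.psi_j])


def combos_to_arrays(data: Sequence[PairCombo]):
    """(n, 4) angle matrix and label vector from a combo list."""
    X = np.array([c.angles() for c in data], dtype=float)
    y = np.array([c.label for c in data], dtype=int)
    return X, y


def enumerate_pair_dataset(ensembles: Sequence[Ensemble], pair: tuple[int, int],
                           noise_deg: float = 3.0) -> list[PairCombo]:
    """Cross-product dataset of unit-``i`` x unit-``j`` values per ensemble.

    ``pair`` must be adjacent indices (i, i+1).  Distinct observed values of
    each unit are combined within each ensemble; a combination is favorable
    iff all four angles lie within ``noise_deg`` (circular, per angle) of
    some low-energy conformer of that ensemble.  Every observed conformer's
    own combination therefore labels 1.
    """
    i, j = pair
    if j != i + 1:
        raise ValueError(f"pair must be adjacent, got {pair}")
    data: list[PairCombo] = []
    for ens in ensembles:
        if not 1 <= i <= ens.n_units - 1:
            raise ValueError(
                f"pair {pair} out of range for {ens.peptide} ({ens.n_units} units)"
            )
        observed = np.array(
            [
                np.r_[c.units[i - 1].as_tuple(), c.units[j - 1].as_tuple()]
                for c in ens.low_energy
            ]
        )
        vals_i = np.unique(observed[:, :2], axis=0)
        vals_j = np.unique(observed[:, 2:], axis=0)
        for a in vals_i:
            for b in vals_j:
                combo = np.r_[a, b]
                match = np.any(
                    np.all(circular_diff(observed, combo) <= noise_deg, axis=1)
                )
                data.append(
                    PairCombo(*combo, label=int(match), source=f"{ens.peptide.lower()}{i}{j}")
                )
    return data


def split_dataset(data: Sequence[PairCombo], frac: float = 0.6, seed: int = 0):
    """Stratified random split into (train, holdout) with ``frac`` in train."""
    if not 0 < frac < 1:
        raise ValueError(f"frac must lie strictly in (0, 1), got {frac}")
    labels = [c.label for c in data]
    if len(set(labels)) < 2:
        raise ValueError("both labels must be present to split")
    idx_train, idx_test = train_test_split(
        np.arange(len(data)), train_size=frac, random_state=seed, stratify=labels
    )
    return [data[i] for i in idx_train], [data[i] for i in idx_test]


class GrammarClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest classifier over adjacent-unit combinations.

    ``X`` is an (n, 4) array of (phi_i, psi_i, phi_j, psi_j) in degrees;
    ``y`` is 1 for favorable, 0 for unfavorable.  Angles are sin/cos-encoded
    internally by default.  Balanced class weights compensate for the
    combinatorial excess of negatives.

    Fitted attributes: ``rf_`` (the forest), ``in_sample_error_``, and —
    when a holdout is supplied to :func:`train_grammar` —
    ``out_of_sample_error_``.
    """

    def __init__(self, n_trees: int = 500, feature_encoding: str = "sincos",
                 class_weight="balanced", random_state: int = 0):
        self.n_trees = n_trees
        self.feature_encoding = feature_encoding
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must be (n, 4) adjacent-unit angles in degrees")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both labels")
        self.rf_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.rf_.fit(encode_angles(X, self.feature_encoding), y)
        self.classes_ = self.rf_.classes_
        self.in_sample_error_ = float(np.mean(self.predict(X) != y))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "rf_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        return self.rf_.predict(encode_angles(X, self.feature_encoding))


def train_grammar(train: Sequence[PairCombo], holdout: Optional[Sequence[PairCombo]] = None,
                  rf: RfConfig = RfConfig()) -> GrammarClassifier:
    """Fit a :class:`GrammarClassifier` on labelled combos.

    Records the training misclassification rate, and the holdout rate when
    a holdout set is given.
    """
    X, y = combos_to_arrays(train)
    model = GrammarClassifier(
        n_trees=rf.n_trees,
        feature_encoding=rf.feature_encoding,
        random_state=rf.random_state,
    ).fit(X, y)
    if holdout is not None:
        model.out_of_sample_error_ = evaluate_grammar(model, holdout)
    return model


def evaluate_grammar(model: GrammarClassifier, data: Sequence[PairCombo]) -> float:
    """Misclassification rate of a trained grammar on labelled combos."""
    X, y = combos_to_arrays(data)
    return float(np.mean(model.predict(X) != y))


def stability_check(data: Sequence[PairCombo], fracs: Sequence[float], seed: int = 0,
                    threshold: float = 0.02, rf: RfConfig = RfConfig()) -> dict:
    """Re-train at several train fractions and report the error stability.

    Returns ``{"runs": [...], "all_below_threshold": bool, "threshold": t}``
    with one entry per fraction holding the split seed and both error
    rates.
    """
    runs = []
    for idx, frac in enumerate(fracs):
        split_seed = seed + idx
        train, holdout = split_dataset(data, frac=frac, seed=split_seed)
        model = train_grammar(
            train, holdout,
            RfConfig(n_trees=rf.n_trees, random_state=split_seed,
                     feature_encoding=rf.feature_encoding),
        )
        runs.append(
            {
                "frac": float(frac),
                "seed": split_seed,
                "in_sample_error": model.in_sample_error_,
                "out_of_sample_error": model.out_of_sample_error_,
            }
        )
    all_below = all(
        r["in_sample_error"] <= threshold and r["out_of_sample_error"] <= threshold
        for r in runs
    )
    return {"runs": runs, "all_below_threshold": all_below, "threshold": threshold}


def screen_combo(model: GrammarClassifier, combo) -> bool:
    """Accept (True) iff the model predicts the combination favorable."""
    if isinstance(combo, PairCombo):
        combo = combo.angles()
    try:
        check_is_fitted(model, "rf_")
    except NotFittedError as exc:
        raise NotFittedError("grammar model is not trained") from exc
    return bool(model.predict(np.asarray(combo, dtype=float).reshape(1, 4))[0] == 1)
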