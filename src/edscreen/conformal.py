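"""Mondrian inductive conformal prediction for binary activity.

The training data are split (stratified) into a proper-training part, on
which a probabilistic base classifier is fit — a random forest by default —
and a calibration part. Nonconformity of an example is one minus the base
model's estimated probability of its true class. At prediction time the
p-value of a candidate class c is the smoothed rank of the query's
nonconformity among the calibration scores *of that class*:

    p_c = (#{alpha_cal >= alpha_query} + 1) / (n_cal_c + 1)

Calibrating each class separately (the Mondrian variant) keeps the error
guarantee per class even under heavy class imbalance, which is the regime
of toxicity panels where actives are a few percent of the data. A
prediction set at significance level epsilon contains every class whose
p-value exceeds epsilon; under exchangeability the probability that the
true class is excluded is at most (approximately) epsilon, per class.

Features for a query compound are its similarities to every training-set
compound — a row of the similarity matrix — so the classifier operates in
the same representation the molecular network thresholds.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .similarity import SimilarityMatrix

__all__ = [
    "ConformalModel",
    "PredictionSet",
    "similarity_features",
    "fit_icp",
    "p_value",
    "predict_set",
    "validity_efficiency",
    "DEFAULT_EPSILONS",
]

DEFAULT_EPSILONS = (0.15, 0.20, 0.25, 0.30)
CLASSES = (0, 1)  # inactive, active

_FORMAT_VERSION = 1


def default_base_model(seed: int = 0, class_weight: str | None = None):
    """Bagged-tree ensemble used as the base learner unless one is supplied."""
    return RandomForestClassifier(
        n_estimators=300, random_state=seed, class_weight=class_weight, n_jobs=1
    )


@dataclass
class PredictionSet:
    """Per-class p-values for one query."""

    p_active: float
    p_inactive: float

    def labels_at(self, epsilon: float) -> frozenset[str]:
        if not 0 < epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        out = set()
        if self.p_active > epsilon:
            out.add("active")
        if self.p_inactive > epsilon:
            out.add("inactive")
        return frozenset(out)


@dataclass
class ConformalModel:
    """Fitted base model plus per-class calibration nonconformity scores."""

    base_model: object
    calibration_scores: dict[int, np.ndarray]  # sorted descending
    feature_ids: list[str] | None
    seed: int

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "calibration_scores": {k: v.tolist() for k, v in
                                   self.calibration_scores.items()},
            "feature_ids": self.feature_ids,
            "seed": self.seed,
            "base_model": self.base_model,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ConformalModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return cls(
            base_model=payload["base_model"],
            calibration_scores={int(k): np.asarray(v, dtype=float)
                                for k, v in payload["calibration_scores"].items()},
            feature_ids=payload["feature_ids"],
            seed=payload["seed"],
        )


def similarity_features(
    query: str | np.ndarray,
    reference: SimilarityMatrix,
    train_ids: Sequence[str],
) -> np.ndarray:
    """Feature vector of a query: its similarity to each training compound.

    ``query`` is either an id resolvable in ``reference`` or an
    already-computed row of similarities aligned with ``reference.ids``.
    """
    missing = [t for t in train_ids if t not in reference.ids]
    if missing:
        raise KeyError(f"train ids missing from similarity matrix: {missing}")
    cols = [reference.ids.index(t) for t in train_ids]
    if isinstance(query, str):
        if query not in reference.ids:
            raise KeyError(f"unresolvable query id {query!r}")
        row = reference.values[reference.ids.index(query)]
    else:
        row = np.asarray(query, dtype=float)
        if row.shape != (len(reference.ids),):
            raise ValueError("query row length does not match matrix ids")
    return row[cols]


def fit_icp(
    features: np.ndarray,
    labels: Sequence[int],
    calibration_fraction: float = 0.2,
    seed: int = 0,
    base_model=None,
    feature_ids: Sequence[str] | None = None,
) -> ConformalModel:
    """Fit the inductive conformal classifier.

    The data are split (stratified, seeded) into proper-training and
    calibration parts; the base model sees only the former. Nonconformity
    alpha = 1 - P_hat(true class) is recorded on the calibration part,
    per class, sorted descending.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not 0 < calibration_fraction < 1:
        raise ValueError("calibration_fraction must be in (0, 1)")
    X_prop, X_cal, y_prop, y_cal = train_test_split(
        X, y, test_size=calibration_fraction, random_state=seed, stratify=y
    )
    for part, name in ((y_prop, "proper-training"), (y_cal, "calibration")):
        if set(np.unique(part)) != set(CLASSES):
            raise ValueError(f"class missing from the {name} part")
    model = clone(base_model) if base_model is not None else default_base_model(seed)
    model.fit(X_prop, y_prop)
    proba = model.predict_proba(X_cal)
    class_col = {c: list(model.classes_).index(c) for c in CLASSES}
    scores = {}
    for c in CLASSES:
        alpha = 1.0 - proba[y_cal == c, class_col[c]]
        scores[c] = np.sort(alpha)[::-1]
    return ConformalModel(
        base_model=model,
        calibration_scores=scores,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        seed=seed,
    )


def _alphas(model: ConformalModel, X: np.ndarray) -> np.ndarray:
    """Nonconformity of each row of X under each candidate class."""
    proba = model.base_model.predict_proba(X)
    cols = {c: list(model.base_model.classes_).index(c) for c in CLASSES}
    return np.column_stack([1.0 - proba[:, cols[c]] for c in CLASSES])


def p_value(model: ConformalModel, x: np.ndarray, c: int) -> float:
    """Smoothed Mondrian p-value of class ``c`` for one feature vector.

    Calibration scores tied with the query's nonconformity count toward the
    numerator (conservative).
    """
    if c not in CLASSES:
        raise ValueError(f"unknown class {c!r}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    alpha_x = _alphas(model, x)[0, list(CLASSES).index(c)]
    cal = model.calibration_scores[c]
    return float((np.sum(cal >= alpha_x) + 1) / (cal.size + 1))


def predict_set(model: ConformalModel, x: np.ndarray,
                epsilon: float | None = None) -> PredictionSet:
    """Per-class p-values for one query (``labels_at`` applies epsilon)."""
    if epsilon is not None and not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    return PredictionSet(
        p_active=p_value(model, x, 1),
        p_inactive=p_value(model, x, 0),
    )


def predict_p_values(model: ConformalModel, X: np.ndarray) -> np.ndarray:
    """Vectorized p-values; column k corresponds to class CLASSES[k]."""
    X = np.asarray(X, dtype=float)
    alphas = _alphas(model, X)
    out = np.empty_like(alphas)
    for k, c in enumerate(CLASSES):
        cal = model.calibration_scores[c]  # sorted descending
        asc = cal[::-1]
        # count of cal >= alpha via searchsorted on the ascending copy
        counts = cal.size - np.searchsorted(asc, alphas[:, k], side="left")
        out[:, k] = (counts + 1) / (cal.size + 1)
    return out


def validity_efficiency(
    model: ConformalModel,
    test_features: np.ndarray,
    test_labels: Sequence[int],
    epsilons: Sequence[float] = DEFAULT_EPSILONS,
) -> list[dict]:
    """Empirical per-class error and single-label efficiency per epsilon.

    Error for class c at epsilon: fraction of class-c test examples whose
    prediction set excludes c. Efficiency at epsilon: fraction of all test
    examples receiving exactly one label.
    """
    y = np.asarray(test_labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty test set")
    pvals = predict_p_values(model, test_features)
    rows = []
    for eps in epsilons:
        included = pvals > eps  # column k: class CLASSES[k] in the set
        efficiency = float(np.mean(included.sum(axis=1) == 1))
        for k, c in enumerate(CLASSES):
            mask = y == c
            err = float(np.mean(~included[mask, k])) if mask.any() else np.nan
            rows.append({
                "class": c,
                "epsilon": float(eps),
                "error_rate": err,
                "efficiency": efficiency,
                "n_class": int(mask.sum()),
            })
    return rows
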