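"""Fingerprint-based activity classification.

Binary molecular fingerprints (one bit per substructure) are cleaned —
constant bits, near-zero-variance bits, and one member of each highly
correlated bit pair are removed — and fed to a gradient-boosted tree
classifier tuned by randomized search under stratified cross-validation.
The cleaning report travels with the model so that prediction can validate
the incoming bit schema.

Near-zero variance follows the caret convention: a bit is dropped when the
ratio of its most common to second most common value frequency exceeds
``nzv_freq_ratio`` (default 19, i.e. 95/5) AND the percentage of distinct
values is below ``nzv_unique_pct``. Correlated removal is iterative: while
any remaining pair has |Pearson r| >= the cutoff, the pair with the highest
correlation is taken and the member with the larger mean absolute
correlation to all remaining bits is dropped (ties drop the
lexicographically later bit name).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FingerprintMatrix",
    "CleaningReport",
    "clean_features",
    "train_classifier",
    "predict_proba",
    "FingerprintModel",
    "DEFAULT_SEARCH_SPACE",
]


@dataclass
class FingerprintMatrix:
    """n x d binary fingerprint matrix with compound ids and bit names."""

    ids: list[str]
    bits: np.ndarray = field(repr=False)
    bit_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be 0 or 1")
        self.bits = self.bits.astype(np.uint8)
        n, d = self.bits.shape
        if len(self.ids) != n:
            raise ValueError("ids length does not match matrix")
        if not self.bit_names:
            self.bit_names = [f"bit_{k}" for k in range(d)]
        if len(self.bit_names) != d or len(set(self.bit_names)) != d:
            raise ValueError("bit_names must be unique and match matrix width")

    def select(self, names: Sequence[str]) -> "FingerprintMatrix":
        idx = [self.bit_names.index(b) for b in names]
        return FingerprintMatrix(list(self.ids), self.bits[:, idx], list(names))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.ids, columns=self.bit_names)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "FingerprintMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(),
                   list(df.columns.astype(str)))


@dataclass
class CleaningReport:
    removed_zero_variance: list[str] = field(default_factory=list)
    removed_near_zero_variance: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def removed(self) -> set[str]:
        return (set(self.removed_zero_variance)
                | set(self.removed_near_zero_variance)
                | {dropped for _, dropped, _ in self.removed_correlated})


def clean_features(
    fp: FingerprintMatrix,
    nzv_freq_ratio: float = 19.0,
    nzv_unique_pct: float = 10.0,
    corr_cutoff: float = 0.9,
) -> tuple[FingerprintMatrix, CleaningReport]:
    """Drop zero-variance, near-zero-variance and highly correlated bits."""
    n, _ = fp.bits.shape
    if n < 2:
        raise ValueError("need at least 2 compounds to assess variance")
    report = CleaningReport()
    X = fp.bits.astype(float)
    keep: list[int] = []
    for k, name in enumerate(fp.bit_names):
        col = X[:, k]
        counts = np.sort(np.bincount(col.astype(int), minlength=2))[::-1]
        counts = counts[counts > 0]
        if counts.size < 2:
            report.removed_zero_variance.append(name)
            continue
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * counts.size / n
        if freq_ratio > nzv_freq_ratio and unique_pct < nzv_unique_pct:
            report.removed_near_zero_variance.append(name)
            continue
        keep.append(k)
    if not keep:
        raise ValueError("all bits removed by variance filtering")

    names = [fp.bit_names[k] for k in keep]
    sub = X[:, keep]
    corr = np.abs(np.corrcoef(sub, rowvar=False))
    if corr.ndim == 0:  # single surviving bit
        corr = np.ones((1, 1))
    np.fill_diagonal(corr, 0.0)
    alive = list(range(len(names)))
    while True:
        a_idx = np.array(alive)
        block = corr[np.ix_(a_idx, a_idx)]
        if block.size == 0 or block.max() < corr_cutoff:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(block), block.shape)
        i, j = a_idx[min(i_loc, j_loc)], a_idx[max(i_loc, j_loc)]
        mean_i = block[min(i_loc, j_loc)].mean()
        mean_j = block[max(i_loc, j_loc)].mean()
        if mean_i > mean_j:
            drop, kept = i, j
        elif mean_j > mean_i:
            drop, kept = j, i
        else:  # tie: drop the later bit name
            drop, kept = ((i, j) if names[i] > names[j] else (j, i))
        report.removed_correlated.append(
            (names[kept], names[drop], float(corr[i, j])))
        alive.remove(drop)
    if not alive:
        raise ValueError("all bits removed by correlation filtering")
    survivors = [names[k] for k in alive]
    return fp.select(survivors), report


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "max_depth": [2, 3, 4, 6, 8],
    "learning_rate": [0.01, 0.03, 0.1, 0.3],
    "max_iter": [50, 100, 200, 400],
    "l2_regularization": [0.0, 0.1, 1.0],
    "class_weight": [None, "balanced"],
}


@dataclass
class FingerprintModel:
    """Trained classifier plus the bit schema and cleaning report."""

    model: object
    bit_names: list[str]
    report: CleaningReport
    cv_summary: pd.DataFrame

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "FingerprintModel":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ValueError("not a fingerprint model file")
        return obj


def _sample_config(rng: np.random.Generator, space: dict[str, list]) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in sorted(space.items())}


def train_classifier(
    fp: FingerprintMatrix,
    labels: Sequence[int],
    n_trials: int = 20,
    cv_folds: int = 5,
    seed: int = 0,
    search_space: dict[str, list] | None = None,
    report: CleaningReport | None = None,
) -> FingerprintModel:
    """Randomized hyperparameter search with stratified CV, refit on all data.

    Each trial samples one configuration from ``search_space`` and scores it
    by mean ROC-AUC over ``cv_folds`` stratified folds; the best
    configuration (ties: first sampled) is refit on the full data.
    Deterministic under ``seed``.
    """
    X = fp.bits.astype(float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("need both classes present")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    space = search_space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, (tr, _) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a CV fold is missing a class")
    rows = []
    for trial in range(n_trials):
        cfg = _sample_config(rng, space)
        aucs = []
        for tr, te in folds:
            m = HistGradientBoostingClassifier(random_state=seed, **cfg)
            m.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], m.predict_proba(X[te])[:, 1]))
        rows.append({"trial": trial, **cfg,
                     "mean_cv_auc": float(np.mean(aucs)),
                     "std_cv_auc": float(np.std(aucs))})
    summary = pd.DataFrame(rows)
    best = summary.loc[summary["mean_cv_auc"].idxmax()]
    best_cfg = {k: best[k] for k in space}
    best_cfg = {k: (None if pd.isna(v) else v) for k, v in best_cfg.items()}
    for key in ("max_depth", "max_iter"):
        if best_cfg.get(key) is not None:
            best_cfg[key] = int(best_cfg[key])
    final = HistGradientBoostingClassifier(random_state=seed, **best_cfg)
    final.fit(X, y)
    return FingerprintModel(
        model=final,
        bit_names=list(fp.bit_names),
        report=report or CleaningReport(),
        cv_summary=summary,
    )


def predict_proba(model: FingerprintModel, fp: FingerprintMatrix) -> np.ndarray:
    """Probability of activity per compound; validates the bit schema."""
    missing = [b for b in model.bit_names if b not in fp.bit_names]
    if missing:
        raise ValueError(f"missing bits: {missing}")
    aligned = fp.select(model.bit_names)
    proba = model.model.predict_proba(aligned.bits.astype(float))
    col = list(model.model.classes_).index(1)
    return proba[:, col]
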