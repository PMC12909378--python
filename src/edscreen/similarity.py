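"""Pairwise spectral and fingerprint similarity.

Two spectral scores are provided. The *greedy cosine* matches fragment
peaks whose m/z differ by at most a tolerance (default 0.2 Da), resolving
conflicts greedily by descending intensity product, and normalizes the
summed products by the L2 norms of the two intensity vectors — the cosine
of the angle between the matched peak representations. The *modified
cosine* additionally admits peak pairs offset by the precursor-mass
difference between the two spectra, so fragments shifted by a single
modification still match. Fingerprints are compared by Tanimoto similarity
(|intersection| / |union| of set bits).

Scores are symmetric, in [0, 1], and 1.0 on self-comparison; they are
assembled into a :class:`SimilarityMatrix`, the common currency feeding the
molecular network and the conformal model's feature vectors. Externally
computed matrices (e.g. from a trained neural scorer) are loaded from
delimited text and validated, never recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import LabeledCompound, Spectrum

__all__ = [
    "SimilarityConfig",
    "SimilarityMatrix",
    "greedy_cosine",
    "modified_cosine",
    "tanimoto",
    "pairwise_matrix",
    "pair_count",
    "load_external_matrix",
]

METRICS = ("greedy_cosine", "modified_cosine", "tanimoto", "external")


@dataclass(frozen=True)
class SimilarityConfig:
    metric: str = "greedy_cosine"
    mz_tolerance: float = 0.2

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.mz_tolerance <= 0:
            raise ValueError("mz_tolerance must be positive")


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity scores over an ordered id list."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")

    @property
    def n_pairs(self) -> int:
        """Number of distinct off-diagonal pairs, n(n-1)/2."""
        return pair_count(len(self.ids))

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def subset(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, float_format="%.6f")


def pair_count(n: int) -> int:
    """Distinct unordered pairs among n items."""
    return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# Spectral scores
# ---------------------------------------------------------------------------

def _greedy_match(
    mz_a: np.ndarray, int_a: np.ndarray,
    mz_b: np.ndarray, int_b: np.ndarray,
    shifts: Sequence[float], tol: float,
) -> float:
    """Greedy one-to-one peak matching over the allowed m/z shifts.

    Candidate pairs (i, j) satisfy |mz_a[i] - mz_b[j] - shift| <= tol for
    some shift. Pairs are taken by descending intensity product, ties by
    ascending (mz_a, mz_b); each peak is used at most once. Returns the sum
    of matched intensity products divided by the product of L2 norms.
    """
    diff = mz_a[:, None] - mz_b[None, :]
    mask = np.zeros(diff.shape, dtype=bool)
    for shift in shifts:
        mask |= np.abs(diff - shift) <= tol
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        return 0.0
    prod = int_a[ii] * int_b[jj]
    order = np.lexsort((mz_b[jj], mz_a[ii], -prod))
    used_a = np.zeros(mz_a.size, dtype=bool)
    used_b = np.zeros(mz_b.size, dtype=bool)
    total = 0.0
    for k in order:
        i, j = ii[k], jj[k]
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            total += prod[k]
    denom = float(np.linalg.norm(int_a) * np.linalg.norm(int_b))
    return min(total / denom, 1.0)


def greedy_cosine(a: Spectrum, b: Spectrum, tol: float = 0.2) -> float:
    """Cosine similarity over greedily matched peaks within ``tol`` Da."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot score an empty spectrum")
    return _greedy_match(a.mz, a.intensities, b.mz, b.intensities, (0.0,), tol)


def modified_cosine(a: Spectrum, b: Spectrum, tol: float = 0.2) -> float:
    """Cosine similarity admitting peaks shifted by the precursor-mass
    difference, so fragments displaced by a modification still match."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot score an empty spectrum")
    if a.precursor_mz is None or b.precursor_mz is None:
        raise ValueError("modified cosine requires precursor m/z on both spectra")
    delta = a.precursor_mz - b.precursor_mz
    shifts = (0.0,) if delta == 0 else (0.0, delta)
    return _greedy_match(a.mz, a.intensities, b.mz, b.intensities, shifts, tol)


def tanimoto(fa: np.ndarray, fb: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints."""
    fa = np.asarray(fa, dtype=bool)
    fb = np.asarray(fb, dtype=bool)
    if fa.shape != fb.shape:
        raise ValueError(f"fingerprint length mismatch: {fa.size} vs {fb.size}")
    union = int(np.sum(fa | fb))
    if union == 0:
        raise ValueError("both fingerprints are empty")
    return float(np.sum(fa & fb) / union)


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def pairwise_matrix(items: Sequence[LabeledCompound],
                    config: SimilarityConfig) -> SimilarityMatrix:
    """All-vs-all similarity for a compound list under one metric.

    n items produce n(n-1)/2 distinct off-diagonal scores; the matrix is
    symmetric with unit diagonal.
    """
    if config.metric == "external":
        raise ValueError("external matrices are loaded, not computed; "
                         "use load_external_matrix")
    ids = [c.compound_id for c in items]
    n = len(items)
    values = np.eye(n)
    if config.metric == "tanimoto":
        fps = []
        for c in items:
            if c.fingerprint is None:
                raise ValueError(f"{c.compound_id}: no fingerprint")
            fps.append(np.asarray(c.fingerprint, dtype=bool))
        fp = np.array(fps)
        inter = (fp[:, None, :] & fp[None, :, :]).sum(axis=2).astype(float)
        union = (fp[:, None, :] | fp[None, :, :]).sum(axis=2).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(union > 0, inter / union, 0.0)
        np.fill_diagonal(values, 1.0)
    else:
        score = greedy_cosine if config.metric == "greedy_cosine" else modified_cosine
        specs = []
        for c in items:
            if c.spectrum is None:
                raise ValueError(f"{c.compound_id}: no spectrum")
            specs.append(c.spectrum)
        for i in range(n):
            for j in range(i + 1, n):
                s = score(specs[i], specs[j], config.mz_tolerance)
                values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids, values)


def load_external_matrix(path: str | Path, ids: Sequence[str] | None = None,
                         sep: str = "\t", atol: float = 1e-6) -> SimilarityMatrix:
    """Load and validate a precomputed similarity matrix from delimited text.

    The file carries ids in the first row and column. The matrix must be
    square, symmetric within ``atol``, and contained in [0, 1]; rows and
    columns are reordered to ``ids`` when given.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("row ids and column ids differ")
    vals = df.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=atol):
        i, j = np.unravel_index(np.argmax(np.abs(vals - vals.T)), vals.shape)
        raise ValueError(
            f"asymmetric at ({df.index[i]}, {df.columns[j]}): "
            f"{vals[i, j]} vs {vals[j, i]}")
    bad = (vals < -atol) | (vals > 1 + atol)
    if bad.any():
        i, j = np.unravel_index(np.argmax(bad), vals.shape)
        raise ValueError(
            f"value out of [0, 1] at ({df.index[i]}, {df.columns[j]}): {vals[i, j]}")
    if ids is not None:
        missing = [i for i in ids if i not in df.index]
        if missing:
            raise ValueError(f"matrix missing ids: {missing}")
        df = df.loc[list(ids), list(ids)]
    vals = np.clip(df.to_numpy(dtype=float), 0.0, 1.0)
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(list(df.index), vals)
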