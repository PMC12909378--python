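"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results by brute force (exhaustive
assignment enumeration, naive per-node loops) so the package's optimized
paths are checked against something that cannot share their bugs.
"""

from __future__ import annotations

import numpy as np
import pytest

from edscreen.spectra import Spectrum


def make_spectrum(peaks, precursor=None, cid="X"):
    return Spectrum(compound_id=cid, peaks=tuple(peaks), precursor_mz=precursor)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def candidate_pairs(a: Spectrum, b: Spectrum, shifts, tol):
    """All peak index pairs allowed under any of the m/z shifts."""
    out = []
    for i, (ma, _) in enumerate(a.peaks):
        for j, (mb, _) in enumerate(b.peaks):
            if any(abs(ma - mb - s) <= tol for s in shifts):
                out.append((i, j))
    return out


def assignment_oracle(a: Spectrum, b: Spectrum, shifts=(0.0,), tol=0.2) -> float:
    """Optimal one-to-one peak assignment score by exhaustive recursion.

    Maximizes the summed intensity products over disjoint candidate pairs;
    feasible only for small spectra (<= ~6 peaks a side).
    """
    pairs = candidate_pairs(a, b, shifts, tol)
    ia, ib = a.intensities, b.intensities

    def best(k: int, used_a: frozenset, used_b: frozenset) -> float:
        if k == len(pairs):
            return 0.0
        i, j = pairs[k]
        skip = best(k + 1, used_a, used_b)
        if i in used_a or j in used_b:
            return skip
        take = ia[i] * ib[j] + best(k + 1, used_a | {i}, used_b | {j})
        return max(skip, take)

    denom = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    return best(0, frozenset(), frozenset()) / denom


def random_spectrum(rng, n_peaks, cid="R", precursor=None):
    mz = np.sort(rng.uniform(50, 500, size=n_peaks))
    inten = rng.uniform(0.05, 1.0, size=n_peaks)
    inten /= inten.max()
    return Spectrum(compound_id=cid, peaks=tuple(zip(mz, inten)),
                    precursor_mz=precursor)
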