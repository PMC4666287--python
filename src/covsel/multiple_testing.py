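"""Histogram-based estimation of the number of true nulls and Storey q-values.

``estimate_m0_histogram`` implements the iterative equal-bin histogram
estimator of the number of true null hypotheses m0: starting from m0 = m,
find the leftmost bin whose count is consistent with uniformity under the
current m0 and rescale the right tail.  Conversion to q-values follows
Storey's construction with the plug-in m0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QValueVector", "estimate_m0_histogram", "qvalues", "count_rejections"]


@dataclass
class QValueVector:
    q: np.ndarray
    m0_hat: float


def _pvec(p) -> np.ndarray:
    arr = np.asarray(getattr(p, "p", p), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return arr


def estimate_m0_histogram(p, B: int = 20, max_iter: int = 100) -> float:
    """Iterative fixed point of the equal-bin m0 recurrence.

    Bins are right-closed on [0, 1] with p = 0 placed in bin 1.  Given the
    current m0, ``b*`` is the smallest bin whose count is <= m0/B (B if
    none); the update rescales the count of bins b*..B by B/(B - b* + 1).
    """
    if B < 2:
        raise ValueError("need at least 2 bins")
    arr = _pvec(p)
    m = arr.size
    bins = np.clip(np.ceil(arr * B).astype(int), 1, B)
    counts = np.bincount(bins, minlength=B + 1)[1:]
    tail = np.cumsum(counts[::-1])[::-1]  # tail[b-1] = count in bins b..B
    m0 = float(m)
    for _ in range(max_iter):
        small = np.flatnonzero(counts <= m0 / B)
        bstar = int(small[0]) + 1 if small.size else B
        new = tail[bstar - 1] * B / (B - bstar + 1)
        if new == m0:
            break
        m0 = new
    return float(np.clip(m0, 0.0, m))


def qvalues(p, m0_hat: float) -> QValueVector:
    """Storey q-values with plug-in m0: ``q_(i) = min_{j>=i} min(1, m0 p_(j)/j)``.

    NaN p-values (unfit genes) propagate to NaN q-values; ranks are computed
    among the non-NaN entries.  Ties share a q-value by construction.
    """
    arr = np.asarray(getattr(p, "p", p), dtype=float)
    ok = ~np.isnan(arr)
    pv = arr[ok]
    m = pv.size
    if m == 0:
        raise ValueError("empty p-value vector")
    if not (0 <= m0_hat <= m):
        raise ValueError(f"m0_hat={m0_hat} outside [0, {m}]")
    order = np.argsort(pv, kind="mergesort")
    ranked = np.minimum(m0_hat * pv[order] / np.arange(1, m + 1), 1.0)
    qv_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = qv_sorted
    out = np.full(arr.shape, np.nan)
    out[ok] = qv
    return QValueVector(out, float(m0_hat))


def count_rejections(q: QValueVector | np.ndarray, alpha: float) -> int:
    """Number of q-values <= alpha (boundary included)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    arr = np.asarray(getattr(q, "q", q), dtype=float)
    return int(np.nansum(arr <= alpha))
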