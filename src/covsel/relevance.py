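"""Covariate relevance measures computed from a vector of per-gene p-values.

A variable that is irrelevant for every gene yields (approximately) uniform
p-values; a relevant one yields an excess of small p-values, i.e. an
empirical distribution stochastically smaller than uniform.  Two measures of
that departure are provided:

* ``p05`` — the number of p-values strictly below 0.05;
* ``gks`` — the Grenander–Kolmogorov–Smirnov statistic
  ``sqrt(m) * sup_x [Ftilde(x) - x]`` where ``Ftilde`` is the least concave
  majorant of the p-value ECDF (the distribution-function side of the
  Grenander decreasing-density estimator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["LCMFunction", "RelevanceScore", "relevance_p05", "lcm_ecdf",
           "relevance_gks", "relevance_score"]


@dataclass
class LCMFunction:
    """Piecewise-linear least concave majorant of an ECDF on [0, 1]."""

    knots_x: np.ndarray
    knots_y: np.ndarray

    def __call__(self, x) -> np.ndarray:
        return np.interp(x, self.knots_x, self.knots_y)


@dataclass
class RelevanceScore:
    value: float
    measure: str
    variable: int | None = None


def _clean(p) -> np.ndarray:
    arr = np.asarray(getattr(p, "p", p), dtype=float)
    nan = np.isnan(arr)
    if nan.any():
        logger.info("dropping %d NaN p-values before relevance", int(nan.sum()))
        arr = arr[~nan]
    if arr.size == 0:
        raise ValueError("no usable p-values")
    return arr


def relevance_p05(p) -> RelevanceScore:
    """Count of p-values strictly less than 0.05."""
    arr = _clean(p)
    var = getattr(p, "variable", None)
    return RelevanceScore(float(np.sum(arr < 0.05)), "p05", var)


def lcm_ecdf(p) -> LCMFunction:
    """Least concave majorant of the p-value ECDF, anchored at (0,0) and (1,1).

    Computed as the upper convex hull of ``{(0,0)} U {(p_(i), i/m)} U {(1,1)}``
    by a monotone-chain scan; ties in p contribute their largest ECDF value.
    """
    arr = np.sort(_clean(p))
    m = arr.size
    xs = np.concatenate(([0.0], arr, [1.0]))
    ys = np.concatenate(([0.0], np.arange(1, m + 1) / m, [1.0]))
    # collapse duplicate x to the max y (the ECDF value at that point)
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    np.maximum.at(uy, inv, ys)
    hull_x: list[float] = []
    hull_y: list[float] = []
    for x, y in zip(ux, uy):
        while len(hull_x) >= 2:
            x1, y1 = hull_x[-2], hull_y[-2]
            x2, y2 = hull_x[-1], hull_y[-1]
            # drop the middle point unless it is strictly above chord (x1,y1)-(x,y)
            if (y2 - y1) * (x - x2) <= (y - y2) * (x2 - x1):
                hull_x.pop()
                hull_y.pop()
            else:
                break
        hull_x.append(float(x))
        hull_y.append(float(y))
    return LCMFunction(np.array(hull_x), np.array(hull_y))


def relevance_gks(p) -> RelevanceScore:
    """GKS statistic ``sqrt(m) * sup_x [Ftilde(x) - x]``.

    The supremum of a concave piecewise-linear function minus the identity is
    attained at a knot of the majorant, so evaluating at the hull vertices is
    exact; the anchors contribute 0, making the statistic non-negative.
    """
    arr = _clean(p)
    m = arr.size
    lcm = lcm_ecdf(arr)
    sup = float(np.max(lcm.knots_y - lcm.knots_x))
    var = getattr(p, "variable", None)
    return RelevanceScore(np.sqrt(m) * max(sup, 0.0), "gks", var)


def relevance_score(p, measure: str) -> RelevanceScore:
    """Dispatch on measure name ('p05' or 'gks')."""
    if measure == "p05":
        return relevance_p05(p)
    if measure == "gks":
        return relevance_gks(p)
    raise ValueError(f"unknown relevance measure {measure!r}")
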