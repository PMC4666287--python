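"""Backward selection of a common covariate set for differential expression.

Starting from the model containing the primary factor and all covariates,
each iteration tests every variable in the current set against all genes,
removes the least relevant one (by the ``p05`` or ``gks`` measure of its
p-value vector), and records ``R_l(alpha)`` — the number of primary-factor
q-values at or below the FDR threshold.  Iteration stops when the primary
factor itself is judged least relevant.  The selected model is the one from
the earliest iteration maximizing ``R_l(alpha)``; final differential
expression calls come from the primary-factor test under that model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .data_io import CountMatrix, CovariateTable, OffsetVector
from .multiple_testing import count_rejections, estimate_m0_histogram, qvalues
from .qltest import PValueVector, test_all_variables
from .relevance import relevance_score

logger = logging.getLogger(__name__)

__all__ = ["IterationRecord", "SelectionTrace", "DEResultTable",
           "backward_select", "select_from_pvalues", "choose_model", "de_test"]


@dataclass
class IterationRecord:
    ell: int
    S: tuple[int, ...]
    relevance: dict[int, float]
    removed: int | None
    R: int
    m0_hat: float
    pvalues: dict[int, np.ndarray]
    qvalues: np.ndarray


@dataclass
class SelectionTrace:
    iterations: list[IterationRecord]
    measure: str
    alpha: float
    var_names: list[str] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.iterations)

    @property
    def ell_star(self) -> int:
        R = [rec.R for rec in self.iterations]
        return int(np.argmax(R)) + 1  # smallest maximizer (argmax = first)

    @property
    def S_hat(self) -> tuple[int, ...]:
        return self.iterations[self.ell_star - 1].S


@dataclass
class DEResultTable:
    """Per-gene primary-factor test results under the selected model."""

    table: pd.DataFrame  # columns: gene_id, p, q, coef..., mean_count, fitted, de
    S_hat: tuple[int, ...]
    alpha: float
    m0_hat: float


def _argmin_variable(scores: Mapping[int, float], S) -> int:
    """Least relevant variable; ties remove the largest index, but any tie
    that includes the primary factor stops the procedure (returns 1)."""
    vals = np.array([scores[j] for j in S], dtype=float)
    minval = vals.min()
    minimizers = [j for j, v in zip(S, vals) if v == minval]
    if 1 in minimizers:
        return 1
    if len(minimizers) > 1:
        logger.info("relevance tie among %s; removing variable %d",
                    minimizers, max(minimizers))
    return max(minimizers)


def select_from_pvalues(
    pvalue_provider: Callable[[tuple[int, ...]], Mapping[int, np.ndarray]],
    k: int,
    alpha: float,
    measure: str = "p05",
    var_names: list[str] | None = None,
) -> SelectionTrace:
    """Run the selection loop on an arbitrary p-value source.

    ``pvalue_provider(S)`` must return a mapping ``j -> length-m p-value
    array`` for every ``j`` in ``S``.  This is the algorithmic core;
    :func:`backward_select` plugs in the quasi-likelihood testing engine,
    and tests may plug in scripted p-value matrices.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    S: tuple[int, ...] = tuple(range(1, k + 1))
    iterations: list[IterationRecord] = []
    for ell in range(1, k + 1):
        pmat = {j: np.asarray(getattr(v, "p", v), dtype=float)
                for j, v in pvalue_provider(S).items()}
        if set(pmat) != set(S):
            raise ValueError(f"provider returned variables {sorted(pmat)} != S={S}")
        m0 = estimate_m0_histogram(pmat[1])
        qv = qvalues(pmat[1], m0)
        R = count_rejections(qv, alpha)
        scores = {j: relevance_score(pmat[j], measure).value for j in S}
        jstar = _argmin_variable(scores, S)
        removed = None if jstar == 1 else jstar
        iterations.append(IterationRecord(ell, S, scores, removed, R, m0, pmat, qv.q))
        if jstar == 1:
            break
        S = tuple(j for j in S if j != jstar)
    return SelectionTrace(iterations, measure, alpha, var_names or [])


def backward_select(cm: CountMatrix, ct: CovariateTable, o: OffsetVector,
                    alpha: float = 0.05, measure: str = "p05") -> SelectionTrace:
    """Backward selection on count data via quasi-likelihood F-tests."""

    def provider(S):
        pvals, _, _ = test_all_variables(cm, ct, o, S)
        return pvals

    return select_from_pvalues(provider, ct.k, alpha, measure,
                               var_names=ct.var_names)


def choose_model(trace: SelectionTrace, alpha: float | None = None) -> tuple[int, ...]:
    """Earliest iteration maximizing R_l(alpha) -> its variable set.

    ``alpha`` must match the trace's threshold if given (R was recorded at
    the trace's alpha; a different threshold requires re-running).
    """
    if alpha is not None and alpha != trace.alpha:
        raise ValueError(
            f"trace recorded R at alpha={trace.alpha}; re-run selection for {alpha}"
        )
    return trace.S_hat


def de_test(cm: CountMatrix, ct: CovariateTable, o: OffsetVector,
            S_hat, alpha: float = 0.05) -> DEResultTable:
    """Primary-factor differential expression calls under a fixed model."""
    S_hat = tuple(sorted(set(int(j) for j in S_hat)))
    pvals, _, fullfit = test_all_variables(cm, ct, o, S_hat)
    p1 = pvals[1].p
    m0 = estimate_m0_histogram(p1)
    qv = qvalues(p1, m0)
    blk = fullfit.design.column_blocks[1]
    coefs = fullfit.fit.beta[:, blk]
    coef_names = fullfit.design.column_names[blk]
    tab = pd.DataFrame({"gene_id": cm.gene_ids, "p": p1, "q": qv.q})
    for i, name in enumerate(coef_names):
        tab[f"coef:{name}"] = coefs[:, i]
    tab["mean_count"] = cm.counts.mean(axis=1)
    tab["fitted"] = ~np.isnan(p1)
    tab["de"] = np.nan_to_num(qv.q, nan=1.0) <= alpha
    return DEResultTable(tab, S_hat, alpha, m0)
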