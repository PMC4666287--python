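"""Negative-binomial log-linear model fitting with fixed dispersion.

Counts follow ``y ~ NB(mu, omega)`` with ``Var(y) = mu + omega * mu^2`` and
``log(mu_i) = o_i + x_i' beta``.  The dispersion ``omega`` is held fixed
during coefficient estimation; ``omega = 0`` is the Poisson limit.  Fitting
is iteratively reweighted least squares with step-halving, vectorized across
genes sharing a design matrix (the common case here: one design, thousands
of count vectors).

Dispersions are estimated by a per-gene moment estimator using Poisson-fit
means; downstream quasi-likelihood dispersions absorb residual
misspecification, which is the point of the quasi-likelihood approach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import DesignMatrix, OffsetVector

__all__ = [
    "GeneFit",
    "BatchFit",
    "LRTResult",
    "estimate_nb_dispersion",
    "moment_dispersions",
    "fit_nb_glm",
    "fit_nb_glm_batch",
    "lrt_stat",
    "nb_deviance",
    "nb_loglik",
]

_MAX_ITER = 50
_DEV_TOL = 1e-8
_ETA_CLIP = 30.0


@dataclass
class GeneFit:
    """Fitted NB GLM for one gene (fixed dispersion)."""

    beta: np.ndarray
    mu: np.ndarray
    deviance: float
    omega: float
    converged: bool
    iterations: int


@dataclass
class BatchFit:
    """Fits for m genes sharing one design: arrays stacked along axis 0."""

    beta: np.ndarray  # (m, p)
    mu: np.ndarray  # (m, n)
    deviance: np.ndarray  # (m,)
    omega: np.ndarray  # (m,)
    converged: np.ndarray  # (m,) bool
    iterations: int

    def gene(self, g: int) -> GeneFit:
        return GeneFit(
            self.beta[g], self.mu[g], float(self.deviance[g]),
            float(self.omega[g]), bool(self.converged[g]), self.iterations,
        )


@dataclass
class LRTResult:
    """Likelihood-ratio statistic for dropping one variable's block."""

    stat: float
    df1: int


def _as_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[None, :] if Y.ndim == 1 else Y


def nb_loglik(Y, mu, omega) -> np.ndarray:
    """NB2 log-likelihood per gene; ``omega`` may mix zeros (Poisson) and positives."""
    from scipy.special import gammaln

    Y = _as_matrix(Y)
    mu = _as_matrix(mu)
    omega = np.atleast_1d(np.asarray(omega, dtype=float))[:, None]
    pois = omega <= 0
    om = np.where(pois, 1.0, omega)  # placeholder to keep arithmetic finite
    r = 1.0 / om
    ll_nb = (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + Y * np.log(om * mu) - (Y + r) * np.log1p(om * mu)
    )
    ll_po = Y * np.log(np.where(mu > 0, mu, 1.0)) - mu - gammaln(Y + 1.0)
    return np.where(pois, ll_po, ll_nb).sum(axis=1)


def nb_deviance(Y, mu, omega) -> np.ndarray:
    """Residual deviance ``2*(loglik_saturated - loglik)`` per gene.

    The ``y log y`` saturated term is taken as 0 when ``y = 0``.
    """
    Y = _as_matrix(Y)
    mu = _as_matrix(mu)
    omega = np.atleast_1d(np.asarray(omega, dtype=float))[:, None]
    ylogy = np.where(Y > 0, Y * np.log(np.where(Y > 0, Y, 1.0) / mu), 0.0)
    pois = omega <= 0
    om = np.where(pois, 1.0, omega)
    nb_tail = -(Y + 1.0 / om) * (np.log1p(om * Y) - np.log1p(om * mu))
    po_tail = -(Y - mu)
    unit = 2.0 * (ylogy + np.where(pois, po_tail, nb_tail))
    return np.maximum(unit.sum(axis=1), 0.0)


def fit_nb_glm_batch(Y, X: DesignMatrix | np.ndarray, o: OffsetVector | np.ndarray,
                     omega, beta_start: np.ndarray | None = None) -> BatchFit:
    """IRLS fit of ``m`` NB GLMs sharing design ``X`` with fixed dispersions.

    Parameters
    ----------
    Y : (m, n) counts.
    X : design matrix (n, p) or :class:`DesignMatrix`.
    o : offsets (n,).
    omega : scalar or (m,) fixed NB dispersions, >= 0.
    beta_start : optional (m, p) warm start.
    """
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    ov = o.o if isinstance(o, OffsetVector) else np.asarray(o, dtype=float)
    Y = _as_matrix(Y)
    m, n = Y.shape
    p = Xm.shape[1]
    if n < p:
        raise ValueError(f"n={n} rows cannot identify p={p} coefficients")
    omega = np.broadcast_to(np.atleast_1d(np.asarray(omega, dtype=float)), (m,)).copy()
    if (omega < 0).any():
        raise ValueError("omega must be >= 0")

    if beta_start is None:
        beta = np.zeros((m, p))
        # start from the constant-mean fit on the offset scale
        ybar = np.maximum(np.mean(Y / np.exp(ov), axis=1), 1e-8)
        beta[:, 0] = np.log(ybar)
    else:
        beta = np.array(beta_start, dtype=float)

    eta = np.clip(ov[None, :] + beta @ Xm.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    dev = nb_deviance(Y, mu, omega)
    converged = np.zeros(m, dtype=bool)
    it = 0
    for it in range(1, _MAX_ITER + 1):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + omega[:, None] * mu)  # IRLS working weights, (m, n)
        z = (eta - ov[None, :]) + (Y - mu) / mu  # working response
        A = np.einsum("mn,np,nq->mpq", w[active], Xm, Xm)
        b = np.einsum("mn,np->mp", (w * z)[active], Xm)
        A[:, np.arange(p), np.arange(p)] += 1e-10  # guard exact singularity
        try:
            beta_new_act = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A[:, np.arange(p), np.arange(p)] += 1e-6
            beta_new_act = np.linalg.solve(A, b[..., None])[..., 0]
        beta_new = beta.copy()
        beta_new[active] = beta_new_act

        # step-halving where the deviance would increase
        step = np.ones(m)
        for _ in range(20):
            trial = beta + step[:, None] * (beta_new - beta)
            eta_t = np.clip(ov[None, :] + trial @ Xm.T, -_ETA_CLIP, _ETA_CLIP)
            mu_t = np.exp(eta_t)
            dev_t = nb_deviance(Y, mu_t, omega)
            bad = active & (dev_t > dev * (1 + 1e-12) + 1e-12) & (step > 1e-8)
            if not bad.any():
                break
            step[bad] *= 0.5
        delta = np.abs(dev - dev_t)
        newly = active & (delta < _DEV_TOL * (np.abs(dev_t) + 0.1))
        beta, eta, mu, dev = trial, eta_t, mu_t, dev_t
        converged |= newly
    return BatchFit(beta, mu, dev, omega, converged, it)


def fit_nb_glm(y, X: DesignMatrix | np.ndarray, o, omega: float) -> GeneFit:
    """Fit a single gene's NB GLM (see :func:`fit_nb_glm_batch`)."""
    fit = fit_nb_glm_batch(np.asarray(y)[None, :], X, o, float(omega))
    gf = fit.gene(0)
    if not np.all(np.isfinite(gf.mu)):
        raise FloatingPointError("non-finite fitted mean")
    return gf


def moment_dispersions(Y, X: DesignMatrix | np.ndarray, o) -> np.ndarray:
    """Per-gene moment estimates of the NB dispersion, floored at 0.

    ``omega_hat = max(0, sum[(y-mu)^2 - mu] / sum mu^2)`` with ``mu`` from a
    Poisson fit of the same design.
    """
    Y = _as_matrix(Y)
    pois = fit_nb_glm_batch(Y, X, o, 0.0)
    if not pois.converged.all():
        warnings.warn("Poisson mean fit did not converge for some genes; "
                      "moment dispersions may be rough")
    mu = pois.mu
    num = ((Y - mu) ** 2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    return np.maximum(num / np.maximum(den, 1e-300), 0.0)


def trended_dispersions(Y, X, o, n_bins: int = 10) -> np.ndarray:
    """Pool moment dispersions within mean-count bins (optional trended mode)."""
    Y = _as_matrix(Y)
    raw = moment_dispersions(Y, X, o)
    logmean = np.log(Y.mean(axis=1) + 0.5)
    order = np.argsort(logmean)
    out = np.empty_like(raw)
    splits = np.array_split(order, min(n_bins, len(order)))
    for idx in splits:
        out[idx] = np.median(raw[idx])
    return out


def estimate_nb_dispersion(y, X: DesignMatrix | np.ndarray, o) -> float:
    """Moment estimate of a single gene's NB dispersion (>= 0)."""
    return float(moment_dispersions(np.asarray(y)[None, :], X, o)[0])


def lrt_stat(full: GeneFit, reduced: GeneFit, dropped_block_width: int) -> LRTResult:
    """Likelihood-ratio statistic for a nested pair fit with the same omega.

    Equals the deviance difference; clipped at zero (numerical noise beyond
    1e-6 draws a warning — callers should warm-start the reduced fit).
    """
    stat = reduced.deviance - full.deviance
    if stat < -1e-6:
        warnings.warn(
            f"reduced deviance {reduced.deviance:.6g} below full "
            f"{full.deviance:.6g}; clipping LRT to 0"
        )
    return LRTResult(max(stat, 0.0), int(dropped_block_width))
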