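"""Huber M-estimation machinery.

The estimators in :mod:`rodeo.deconvolve` model every gene's bulk expression
as a non-negative mixture of cell type-specific expression levels weighted by
known proportions, with no intercept.  Outlier samples are handled by
replacing ordinary least squares with a Huber M-estimator: the loss is
quadratic for residuals within ``k`` robust standard deviations and linear
beyond, which bounds the influence any single sample can exert on the fit.

The solver is iteratively reweighted least squares (IRLS) with the residual
scale re-estimated each iteration by the (zero-centred) median absolute
deviation, matching the default behaviour of robust linear model fitters in
the M-estimation literature.  Because the mixing model has no intercept,
residuals of a correct fit scatter around zero, so the MAD is centred at
zero by default rather than at the residual median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RankDeficiencyError, UnderdeterminedError, ValidationError

#: Consistency constant making the MAD an unbiased scale estimate for
#: Gaussian residuals (the 0.75 normal quantile).
MAD_CONSISTENCY = 0.6745

#: Default Huber tuning constant: 95% Gaussian efficiency.
DEFAULT_K = 1.345


@dataclass(frozen=True)
class HuberConfig:
    """Tuning parameters for the Huber IRLS solver.

    Parameters
    ----------
    k
        Huber tuning constant in robust standard-deviation units.  The
        default 1.345 gives 95% efficiency under Gaussian noise.
    max_iter
        Maximum IRLS iterations before giving up (``converged`` is then
        False on the returned fit, not an error).
    tol
        Relative convergence tolerance on the coefficient vector:
        ``max_i |b_new - b_old| / max(1, |b_old|) < tol`` stops iterating.
    scale_floor
        If the robust residual scale falls to this value or below, the data
        are treated as (numerically) noise-free and the current
        least-squares solution is returned with unit weights.
    """

    k: float = DEFAULT_K
    max_iter: int = 50
    tol: float = 1e-6
    scale_floor: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k <= 0:
            raise ValidationError(f"Huber constant k must be positive, got {self.k!r}")
        if self.max_iter < 1:
            raise ValidationError(f"max_iter must be >= 1, got {self.max_iter!r}")
        if not np.isfinite(self.tol) or self.tol <= 0:
            raise ValidationError(f"tol must be positive, got {self.tol!r}")
        if self.scale_floor < 0:
            raise ValidationError(
                f"scale_floor must be non-negative, got {self.scale_floor!r}"
            )


@dataclass(frozen=True)
class RegressionFit:
    """Result of a single robust (or degenerate least-squares) regression."""

    coefficients: np.ndarray
    weights: np.ndarray
    scale: float
    n_iterations: int
    converged: bool


def huber_loss(x, k: float = DEFAULT_K):
    """Huber loss: ``x**2 / 2`` for ``|x| <= k``, else ``k*|x| - k**2 / 2``.

    Accepts scalars or arrays; symmetric in ``x`` and continuous (with
    continuous first derivative) at ``|x| = k``.
    """
    if not np.isfinite(k) or k <= 0:
        raise ValidationError(f"k must be a positive finite number, got {k!r}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("huber_loss requires finite input")
    ax = np.abs(x)
    out = np.where(ax <= k, 0.5 * x * x, k * ax - 0.5 * k * k)
    return out if out.ndim else float(out)


def huber_weight(residual, scale: float, k: float = DEFAULT_K):
    """IRLS weight of an observation: 1 inside ``k*scale``, ``k*scale/|r|`` beyond.

    This is the usual ``psi(r)/r`` weight of the Huber psi-function; values
    lie in ``(0, 1]``.
    """
    if not np.isfinite(scale) or scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale!r}")
    if not np.isfinite(k) or k <= 0:
        raise ValidationError(f"k must be positive, got {k!r}")
    r = np.asarray(residual, dtype=float)
    ar = np.abs(r)
    bound = k * scale
    with np.errstate(divide="ignore", over="ignore"):
        w = np.where(ar <= bound, 1.0, bound / np.where(ar > 0, ar, 1.0))
    return w if w.ndim else float(w)


def mad_scale(residuals, center: float | None = 0.0) -> float:
    """Median absolute deviation scale estimate, ``MAD / 0.6745``.

    Parameters
    ----------
    residuals
        Residual vector; must be non-empty and finite.
    center
        Value the deviations are taken from.  The default 0 matches
        no-intercept regression, where residuals of a correct fit pass
        through zero.  ``None`` centres at the residual median (the textbook
        MAD, which is 0 for any constant vector).
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size == 0:
        raise ValidationError("mad_scale requires at least one residual")
    if not np.all(np.isfinite(r)):
        raise ValidationError("mad_scale requires finite residuals")
    c = np.median(r) if center is None else float(center)
    return float(np.median(np.abs(r - c)) / MAD_CONSISTENCY)


def _check_design(X: np.ndarray, y: np.ndarray) -> None:
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError(
            f"y has shape {y.shape}, expected ({n},) to match X {X.shape}"
        )
    if p < 1:
        raise ValidationError("X must have at least one predictor column")
    if n < p:
        raise UnderdeterminedError(
            f"underdetermined system: {n} observations for {p} predictors"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("fit_huber requires finite X and y")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # QR with pivoting ranks columns by how much new span they add; the
        # trailing pivots are the (nearly) linearly dependent ones.
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        collinear = tuple(sorted(int(j) for j in piv[rank:]))
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {p} columns); "
            f"collinear predictor columns: {collinear}",
            collinear=collinear,
        )


def fit_huber(y, X, config: HuberConfig | None = None) -> RegressionFit:
    """Fit a no-intercept linear model by Huber IRLS.

    Initialises with ordinary least squares, then alternates
    (residuals -> MAD scale -> Huber weights -> weighted least squares)
    until the coefficients move less than ``config.tol`` or ``max_iter`` is
    reached.  If the scale estimate drops to ``scale_floor`` or below, the
    data are treated as noise-free and the current least-squares solution is
    returned with unit weights and ``converged=True``.
    """
    if config is None:
        config = HuberConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_design(X, y)
    n = X.shape[0]

    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    weights = np.ones(n)
    scale = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        resid = y - X @ beta
        scale = mad_scale(resid, center=0.0)
        if scale <= config.scale_floor:
            return RegressionFit(beta, np.ones(n), scale, n_iter, True)
        weights = huber_weight(resid, scale, config.k)
        sw = np.sqrt(weights)
        beta_new = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]
        delta = np.max(np.abs(beta_new - beta) / np.maximum(1.0, np.abs(beta)))
        beta = beta_new
        if delta < config.tol:
            converged = True
            break
    return RegressionFit(beta, weights, scale, n_iter, converged)
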