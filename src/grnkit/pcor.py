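"""Partial-correlation-based network inference.

Three estimators of the partial-correlation structure rho_jh =
-omega_jh / sqrt(omega_jj * omega_hh) of a Gaussian graphical model:

* :func:`shrinkage_pcor` — analytic shrinkage of the sample correlation
  matrix toward the identity, followed by (pseudo-)inversion.  Tuning-free.
* :func:`neighborhood_selection` — per-gene lasso regressions; an edge's
  strength is the larger |coefficient| of its two directions (OR rule).
* :func:`space` — joint sparse regression with the symmetric
  parameterization beta_{j<-h} = rho_jh sqrt(omega_hh / omega_jj), solved by
  coordinate descent over unordered pairs, alternating with updates of the
  residual precisions omega_jj.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, lasso_path

from .core import ExpressionMatrix, WeightedNetwork

__all__ = [
    "LassoPath",
    "shrinkage_pcor",
    "neighborhood_selection",
    "ns_path",
    "space",
    "space_path",
    "default_penalty_grid",
]

logger = logging.getLogger(__name__)

LASSO_TOL = 1e-7
LASSO_MAX_ITER = 10_000


@dataclass
class LassoPath:
    """A sweep of one penalized estimator over a descending penalty grid."""

    lambdas: np.ndarray
    networks: list[WeightedNetwork]

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.networks) != len(self.lambdas):
            raise ValueError("one network per lambda required")
        if np.any(np.diff(self.lambdas) > 0):
            raise ValueError("lambdas must be in descending order")

    def edge_counts(self, tol: float = 0.0) -> np.ndarray:
        return np.array([int(np.count_nonzero(np.abs(w.strengths) > tol) // 2) for w in self.networks])


def default_penalty_grid(x: ExpressionMatrix, n_points: int = 20, span: float = 100.0) -> np.ndarray:
    """Descending log-spaced penalty grid from saturation to dense.

    The top is the largest absolute off-diagonal sample covariance entry
    (the saturation point for the lasso-type problems here); the bottom is
    ``span`` times smaller.
    """
    s = x.values @ x.values.T / x.n_samples
    off = np.abs(s - np.diag(np.diag(s)))
    lam_max = float(off.max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max / span, n_points)


# ---------------------------------------------------------------------------
# shrinkage partial correlation


def _sample_correlation(x: ExpressionMatrix) -> np.ndarray:
    xs = x.values  # p x n, standardized rows
    n = x.n_samples
    r = xs @ xs.T / (n - 1)
    np.fill_diagonal(r, 1.0)
    return r


def _shrinkage_intensity(x: ExpressionMatrix) -> float:
    """Analytic shrinkage weight toward the identity target.

    lambda* = sum_{j!=h} Var-hat(r_jh) / sum_{j!=h} r_jh^2, clipped to
    [0, 1]: the ratio of estimated estimation noise in the off-diagonal
    correlations to their total squared size.
    """
    xs = x.values
    p, n = xs.shape
    w_bar = xs @ xs.T / n
    w2_sum = (xs ** 2) @ (xs ** 2).T
    var_r = n / (n - 1.0) ** 3 * (w2_sum - n * w_bar ** 2)
    r = xs @ xs.T / (n - 1)
    mask = ~np.eye(p, dtype=bool)
    denom = float((r[mask] ** 2).sum())
    if denom == 0.0:
        return 1.0
    return float(np.clip(var_r[mask].sum() / denom, 0.0, 1.0))


def precision_to_partial_corr(omega: np.ndarray) -> np.ndarray:
    """rho_jh = -omega_jh / sqrt(omega_jj omega_hh), zero diagonal."""
    d = np.sqrt(np.abs(np.diag(omega)))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


def shrinkage_pcor(x: ExpressionMatrix, shrinkage: float | None = None) -> WeightedNetwork:
    """Tuning-free shrinkage estimate of the partial-correlation matrix.

    The sample correlation matrix is shrunk toward the identity with an
    analytically chosen intensity (``shrinkage=None``), inverted with the
    Moore-Penrose pseudoinverse, and converted to partial correlations.
    Forcing ``shrinkage=0`` recovers the plain inverse-correlation estimate
    (only sensible for n > p).
    """
    if x.n_samples < 3:
        raise ValueError("shrinkage partial correlation needs at least 3 samples")
    lam = _shrinkage_intensity(x) if shrinkage is None else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")
    r = _sample_correlation(x)
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    omega = np.linalg.pinv(r_shrunk, hermitian=True)
    rho = precision_to_partial_corr(omega)
    return WeightedNetwork.from_raw(rho, x.gene_ids, "shrinkage_pcor")


# ---------------------------------------------------------------------------
# neighborhood selection


def _ns_coefficients(x: ExpressionMatrix, lam: float) -> np.ndarray:
    """B[j, h] = lasso coefficient of gene h in the regression of gene j."""
    xs = x.values.T  # n x p
    p = x.n_genes
    b = np.zeros((p, p))
    model = Lasso(alpha=lam, fit_intercept=False, tol=LASSO_TOL, max_iter=LASSO_MAX_ITER)
    idx = np.arange(p)
    for j in range(p):
        others = idx != j
        model.fit(xs[:, others], xs[:, j])
        b[j, others] = model.coef_
    return b


def neighborhood_selection(x: ExpressionMatrix, lam: float) -> WeightedNetwork:
    """Per-gene lasso regressions; OR-rule symmetrization.

    ``strength[j, h] = max(|beta_{j<-h}|, |beta_{h<-j}|)``: an edge needs
    only one of the two regressions to select it.  The lasso objective is
    ``1/(2n) ||y - Xb||^2 + lam ||b||_1`` (scikit-learn convention).
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    b = _ns_coefficients(x, lam)
    strengths = np.maximum(np.abs(b), np.abs(b.T))
    return WeightedNetwork.from_raw(strengths, x.gene_ids, "ns")


def ns_path(x: ExpressionMatrix, lambdas: np.ndarray | None = None) -> LassoPath:
    """Neighborhood-selection networks along a descending penalty grid."""
    if lambdas is None:
        lambdas = default_penalty_grid(x)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    xs = x.values.T
    p = x.n_genes
    idx = np.arange(p)
    coefs = np.zeros((len(lambdas), p, p))
    for j in range(p):
        others = idx != j
        # lasso_path wants increasing alphas internally; returns in given order
        _, coef, _ = lasso_path(xs[:, others], xs[:, j], alphas=lambdas, tol=LASSO_TOL, max_iter=LASSO_MAX_ITER)
        coefs[:, j, others] = coef.T
    nets = []
    for k in range(len(lambdas)):
        strengths = np.maximum(np.abs(coefs[k]), np.abs(coefs[k].T))
        nets.append(WeightedNetwork.from_raw(strengths, x.gene_ids, "ns"))
    return LassoPath(lambdas, nets)


# ---------------------------------------------------------------------------
# SPACE


def _space_objective(xs: np.ndarray, rho: np.ndarray, w: np.ndarray, lam: float, penalty: np.ndarray) -> float:
    n, p = xs.shape
    c = np.sqrt(w[None, :] / w[:, None])  # c[j,h] = sqrt(w_h / w_j)
    beta = rho * c
    np.fill_diagonal(beta, 0.0)
    resid = xs - xs @ beta.T
    loss = 0.5 / n * float((resid ** 2).sum())
    iu = np.triu_indices(p, k=1)
    return loss + float((penalty[iu] * np.abs(rho[iu])).sum()) * lam


def space(
    x: ExpressionMatrix,
    lam: float,
    outer_iters: int = 3,
    max_sweeps: int = 500,
    tol: float = 1e-6,
    penalty_weights: np.ndarray | None = None,
    rho_init: np.ndarray | None = None,
) -> WeightedNetwork:
    """Sparse partial correlation estimation by joint symmetric regression.

    Minimizes ``sum_j 1/(2n) ||X_j - sum_h rho_jh sqrt(w_h/w_j) X_h||^2 +
    lam * sum_{j<h} c_jh |rho_jh|`` by cyclic coordinate descent over the
    unordered pairs, then re-estimates the residual precisions
    ``w_j = 1/var(resid_j)`` and repeats (``outer_iters`` alternations).
    ``penalty_weights`` (c_jh, default 1) admits entrywise penalties, e.g.
    hub-informed priors.  Non-convergence of the inner loop is logged and
    the last iterate returned.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if outer_iters < 1:
        raise ValueError("outer_iters must be >= 1")
    xs = x.values.T.copy()  # n x p
    n, p = xs.shape
    pen = np.ones((p, p)) if penalty_weights is None else np.asarray(penalty_weights, dtype=float)
    rho = np.zeros((p, p)) if rho_init is None else rho_init.copy()
    w = np.ones(p)
    col_ss = (xs ** 2).sum(axis=0)
    iu, ju = np.triu_indices(p, k=1)

    for outer in range(outer_iters):
        c = np.sqrt(w[None, :] / w[:, None])
        beta = rho * c
        np.fill_diagonal(beta, 0.0)
        resid = xs - xs @ beta.T  # resid[:, j] residual of regression j

        converged = False
        for sweep in range(max_sweeps):
            max_delta = 0.0
            for j, h in zip(iu, ju):
                cjh = c[j, h]  # coef scale in regression j (predictor h)
                chj = c[h, j]
                r_j = resid[:, j] + rho[j, h] * cjh * xs[:, h]
                r_h = resid[:, h] + rho[j, h] * chj * xs[:, j]
                num = (cjh * (xs[:, h] @ r_j) + chj * (xs[:, j] @ r_h)) / n
                den = (cjh ** 2 * col_ss[h] + chj ** 2 * col_ss[j]) / n
                thr = lam * pen[j, h]
                new = 0.0 if abs(num) <= thr else (num - np.sign(num) * thr) / den
                delta = new - rho[j, h]
                if delta != 0.0:
                    resid[:, j] = r_j - new * cjh * xs[:, h]
                    resid[:, h] = r_h - new * chj * xs[:, j]
                    rho[j, h] = rho[h, j] = new
                    max_delta = max(max_delta, abs(delta))
                else:
                    resid[:, j] = r_j - rho[j, h] * cjh * xs[:, h]
                    resid[:, h] = r_h - rho[j, h] * chj * xs[:, j]
            if max_delta < tol:
                converged = True
                break
        if not converged:
            logger.warning("space inner loop did not converge (lam=%.4g, outer=%d)", lam, outer)
        resid_var = (resid ** 2).mean(axis=0)
        resid_var = np.maximum(resid_var, 1e-12)
        w = 1.0 / resid_var

    return WeightedNetwork.from_raw(rho, x.gene_ids, "space")


def space_path(
    x: ExpressionMatrix,
    lambdas: np.ndarray | None = None,
    outer_iters: int = 2,
    max_sweeps: int = 50,
    tol: float = 1e-5,
) -> LassoPath:
    """SPACE along a descending penalty grid, warm-started between points.

    The sweep runs with a looser inner tolerance and sweep cap than the
    single-penalty estimator: each grid point is one ROC operating point,
    and the dense small-penalty end converges slowly without affecting the
    curve.
    """
    if lambdas is None:
        lambdas = default_penalty_grid(x)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    nets: list[WeightedNetwork] = []
    rho_prev: np.ndarray | None = None
    for lam in lambdas:
        wn = space(
            x, float(lam), outer_iters=outer_iters, max_sweeps=max_sweeps, tol=tol, rho_init=rho_prev
        )
        rho_prev = wn.strengths.copy()
        nets.append(wn)
    return LassoPath(lambdas, nets)
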