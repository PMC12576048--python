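"""Complementary log-log GEE for survival pseudo-observations.

Under the Cox model the conditional survival satisfies
``log(-log S(tau_j | x)) = log Lambda0(tau_j) + x' beta``, so regressing the
pseudo-values on time-specific intercepts plus the covariates with the
cloglog link recovers the log cumulative baseline hazards and the log hazard
ratios jointly.  The estimating equation

``U(theta) = sum_i D_i' V_i^{-1} (S_i - mu_i(theta)) = 0``

is solved by damped Newton iteration with an independence (identity) working
covariance; the covariance of ``theta_hat`` is the sandwich
``I^{-1} [sum_i U_i U_i'] I^{-1}`` which remains valid although the
pseudo-values are neither independent across subjects' rows nor restricted
to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import LBRCSample
from .pseudo import PseudoMatrix

__all__ = [
    "inv_cloglog",
    "cloglog",
    "build_design",
    "GEEFit",
    "solve_gee",
    "sandwich_cov",
    "wald_ci",
    "is_valid",
]

logger = logging.getLogger(__name__)

_ETA_MAX = 30.0  # exp(eta) saturates well before this; guards overflow
_ETA_MIN = -700.0


def cloglog(x):
    """The complementary log-log link ``g(x) = log(-log x)`` for x in (0,1)."""
    return np.log(-np.log(x))


def inv_cloglog(eta):
    """Inverse link ``g^{-1}(eta) = exp(-exp(eta))``, saturating at 0/1."""
    eta = np.clip(np.asarray(eta, dtype=float), _ETA_MIN, _ETA_MAX)
    out = np.exp(-np.exp(eta))
    return out if out.ndim else float(out)


def _mu_and_deriv(eta):
    eta = np.clip(eta, _ETA_MIN, _ETA_MAX)
    ee = np.exp(eta)
    mu = np.exp(-ee)
    mu1 = -ee * mu  # d mu / d eta
    return mu, mu1, ee


def build_design(pseudo: PseudoMatrix, sample: LBRCSample):
    """Stacked (subject x grid-point) design for the cloglog GEE.

    Each subject contributes ``m`` rows: a unit indicator for its grid point
    (the m time-specific intercepts) followed by the ``p`` covariates.
    Subjects flagged invalid in the pseudo-matrix are dropped listwise.
    Returns ``(X, response, n_valid, n_invalid, names)``.
    """
    if pseudo.n != sample.n:
        raise ValueError("pseudo-matrix and sample are not aligned")
    keep = pseudo.valid
    n_invalid = pseudo.n_invalid
    if n_invalid:
        logger.info("dropping %d invalid subject(s) from the GEE", n_invalid)
    vals = pseudo.values[keep]
    x = sample.x[keep]
    n, m = vals.shape
    p = x.shape[1]
    blocks = np.tile(np.eye(m), (n, 1))
    design = np.hstack([blocks, np.repeat(x, m, axis=0)])
    names = [f"logLambda0({tau:g})" for tau in pseudo.grid] + list(sample.covariate_names)
    return design, vals.ravel(), n, n_invalid, names


@dataclass
class GEEFit:
    """GEE solution: ``theta = (m intercepts, p coefficients)`` + sandwich."""

    theta: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int
    n_invalid: int
    m: int
    names: list[str] = field(default_factory=list)
    max_score: float = np.nan

    @property
    def intercepts(self) -> np.ndarray:
        return self.theta[: self.m]

    @property
    def beta(self) -> np.ndarray:
        return self.theta[self.m :]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def predict_survival(self, tau_index: int, x) -> float:
        """Model-based survival ``exp(-exp(b0_j + x' beta))`` at grid point j."""
        eta = self.theta[tau_index] + np.asarray(x, dtype=float) @ self.beta
        return inv_cloglog(eta)

    def summary(self, level: float = 0.95):
        import pandas as pd

        se = self.se
        z = np.divide(self.theta, se, out=np.full_like(self.theta, np.nan), where=se > 0)
        pval = 2.0 * stats.norm.sf(np.abs(z))
        lo, hi = wald_ci(self, level)
        return pd.DataFrame(
            {
                "coefficient": self.names or [f"theta{k}" for k in range(self.theta.size)],
                "estimate": self.theta,
                "se": se,
                "z": z,
                "p_value": pval,
                f"ci_low_{level:g}": lo,
                f"ci_high_{level:g}": hi,
            }
        )


def _score_pieces(design, response, theta):
    mu, mu1, ee = _mu_and_deriv(design @ theta)
    resid = response - mu
    score = design.T @ (mu1 * resid)
    return mu, mu1, ee, resid, score


def solve_gee(
    pseudo: PseudoMatrix,
    sample: LBRCSample,
    tol: float = 1e-8,
    max_iter: int = 100,
    theta0: np.ndarray | None = None,
) -> GEEFit:
    """Solve the pseudo-observation estimating equation ``U(theta) = 0``.

    Damped Newton iteration (exact Jacobian, Fisher-scoring fallback, step
    halving up to 20 times); convergence requires both the max score
    component and the step norm below ``tol``.  Non-convergence or numerical
    breakdown returns a fit flagged ``converged=False``.
    """
    m_all = pseudo.m
    # Saturated grid points: when the estimated survival at tau_j is (numerically)
    # zero, the j-th intercept's root lies at +infinity and the corresponding
    # rows' score contributions vanish in that limit; fitting the reduced
    # system is the exact limiting solution.  Such intercepts are reported NaN.
    grid_all = pseudo.grid
    colmeans_all = pseudo.values[pseudo.valid].mean(axis=0)
    keep_cols = colmeans_all > 1e-6
    if not keep_cols.any():
        raise ValueError("every grid point is saturated (survival ~ 0 throughout)")
    if not keep_cols.all():
        logger.info("dropping %d saturated grid point(s)", int(np.sum(~keep_cols)))
        pseudo = PseudoMatrix(
            values=pseudo.values[:, keep_cols],
            grid=pseudo.grid[keep_cols],
            estimator_kind=pseudo.estimator_kind,
            valid=pseudo.valid,
        )
    design, response, n_valid, n_invalid, names = build_design(pseudo, sample)
    m = pseudo.m
    dim = design.shape[1]
    if dim >= n_valid:
        raise ValueError("more parameters than subjects; grid too fine for this n")

    if theta0 is None:
        colmeans = np.clip(pseudo.values[pseudo.valid].mean(axis=0), 1e-6, 1.0 - 1e-6)
        theta = np.concatenate([cloglog(colmeans), np.zeros(dim - m)])
    else:
        theta = np.asarray(theta0, dtype=float)[np.concatenate([keep_cols, np.ones(dim - m, bool)])].copy()

    converged = False
    it = 0
    step_norm = np.inf
    mu, mu1, ee, resid, score = _score_pieces(design, response, theta)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol and step_norm < tol:
            converged = True
            break
        mu2 = mu1 * (1.0 - ee)  # d mu1 / d eta
        w_newton = mu1**2 - mu2 * resid
        w_scoring = mu1**2
        step = None
        for w in (w_newton, w_scoring):
            jac = design.T @ (w[:, None] * design)
            try:
                cand = np.linalg.solve(jac, score)
            except np.linalg.LinAlgError:
                continue
            if np.all(np.isfinite(cand)):
                step = cand
                break
        if step is None:
            logger.warning("solve_gee: singular scoring matrix at iteration %d", it)
            break
        # damped update: halve until the score norm does not increase
        base = np.max(np.abs(score))
        scale = 1.0
        for _ in range(20):
            theta_new = theta + scale * step
            mu, mu1, ee, resid, score_new = _score_pieces(design, response, theta_new)
            if np.max(np.abs(score_new)) <= base or np.max(np.abs(score_new)) < tol:
                break
            scale *= 0.5
        with np.errstate(over="ignore"):
            step_norm = float(np.linalg.norm(scale * step))
        theta = theta_new
        score = score_new
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e3:
            logger.warning("solve_gee: divergence at iteration %d", it)
            theta = np.where(np.isfinite(theta), theta, 0.0)
            break

    cov = _sandwich(design, response, theta, n_valid, m) if converged else np.full(
        (dim, dim), np.nan
    )
    if not keep_cols.all():
        # re-embed into the full grid: saturated intercepts reported as NaN
        p = dim - m
        full_idx = np.concatenate([np.flatnonzero(keep_cols), np.arange(m_all, m_all + p)])
        theta_full = np.full(m_all + p, np.nan)
        theta_full[full_idx] = theta
        cov_full = np.full((theta_full.size, theta_full.size), np.nan)
        cov_full[np.ix_(full_idx, full_idx)] = cov
        theta, cov = theta_full, cov_full
        names = [f"logLambda0({tau:g})" for tau in grid_all] + list(sample.covariate_names)
    return GEEFit(
        theta=theta,
        cov=cov,
        converged=converged,
        n_iter=it,
        n_invalid=n_invalid,
        m=m_all,
        names=names,
        max_score=float(np.max(np.abs(score))),
    )


def _sandwich(design, response, theta, n_valid, m):
    """``Sigma = I^{-1} [sum_i U_i U_i'] I^{-1}`` at the solution.

    ``I`` is the Fisher-type bread ``sum_r x_r x_r' mu1_r^2`` (identity
    working covariance) and the meat stacks each subject's ``m`` rows into a
    per-subject score vector.
    """
    mu, mu1, ee = _mu_and_deriv(design @ theta)
    resid = response - mu
    w = mu1 * resid
    dim = design.shape[1]
    bread = design.T @ ((mu1**2)[:, None] * design)
    cond = np.linalg.cond(bread)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular information matrix (condition number {cond:.3g})"
        )
    ui = np.einsum("nmk,nm->nk", design.reshape(n_valid, m, dim), w.reshape(n_valid, m))
    meat = ui.T @ ui
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ meat @ bread_inv
    return 0.5 * (cov + cov.T)


def sandwich_cov(pseudo: PseudoMatrix, sample: LBRCSample, theta: np.ndarray) -> np.ndarray:
    """Sandwich covariance evaluated at a given ``theta`` (normally the root)."""
    design, response, n_valid, _, _ = build_design(pseudo, sample)
    return _sandwich(design, response, np.asarray(theta, dtype=float), n_valid, pseudo.m)


def wald_ci(fit: GEEFit, level: float = 0.95):
    """Per-coefficient Wald intervals ``theta_j +/- z * se_j``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    zq = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    se = fit.se
    return fit.theta - zq * se, fit.theta + zq * se


def is_valid(fit: GEEFit, coef_bound: float = 10.0) -> bool:
    """Validity rule for a fitted GEE.

    A fit is invalid when the estimation procedure did not converge or
    produced unrealistically extreme output: a covariate coefficient with
    ``|beta_j| > coef_bound`` (log hazard ratios of that size are
    meaningless), or a broken sandwich variance (non-finite, or a
    coefficient SE above the same bound -- the signature of an unidentified
    root on a degenerate cohort).
    """
    if not fit.converged:
        return False
    beta, beta_se = fit.beta, fit.se[fit.m :]
    if not (np.all(np.isfinite(beta)) and np.all(np.abs(beta) <= coef_bound)):
        return False
    # saturated-grid intercepts are legitimately NaN; the covariate block must
    # carry a usable variance
    if not np.all(np.isfinite(beta_se)) or np.any(beta_se > coef_bound):
        return False
    return True
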