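"""Jackknife pseudo-observations for LBRC survival estimators.

For an estimator ``S`` of the unbiased survival function evaluated on a grid
``tau_1 < ... < tau_m``, the pseudo-observation of subject ``i`` at ``tau_j``
is ``n S(tau_j) - (n - 1) S^{(-i)}(tau_j)`` with ``S^{(-i)}`` the
leave-one-out estimate.  Pseudo-values play the role of (possibly
out-of-range) surrogate responses for the indicators ``1{T_i > tau_j}`` in a
downstream regression.

For the two product-limit estimators the n leave-one-out curves are obtained
in closed form by subtracting subject ``i``'s contribution from the event and
risk tallies, which is algebraically identical to refitting on the reduced
sample; the NPMLE is refit by EM warm-started at the full-sample solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import LBRCSample
from .survfit import (
    SurvivalCurve,
    _event_table,
    _vardi_em,
    _vardi_em_arrays,
    _wang_risk_sum,
    ltrc_km,
    vardi_npmle,
    wang_estimator,
)

__all__ = ["PseudoMatrix", "default_grid", "parse_grid", "jackknife_pseudo"]

logger = logging.getLogger(__name__)

ESTIMATORS = ("wang", "vardi", "ltrc", "empirical")


@dataclass
class PseudoMatrix:
    """n x m matrix of jackknife pseudo-values on a fixed time grid."""

    values: np.ndarray
    grid: np.ndarray
    estimator_kind: str
    valid: np.ndarray  # per-subject validity flags

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def n_invalid(self) -> int:
        return int(np.sum(~self.valid))

    def to_frame(self):
        import pandas as pd

        n, m = self.values.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), m),
                "tau": np.tile(self.grid, n),
                "pseudo_value": self.values.ravel(),
            }
        )


def default_grid(sample: LBRCSample, m: int) -> np.ndarray:
    """Equally spaced probability quantiles of the uncensored times.

    Uses probabilities ``k/(m+1), k = 1..m`` (so ``m = 9`` spans the 10th to
    the 90th percentile) with linear interpolation between order statistics.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    yu = sample.y[sample.delta == 1]
    if yu.size < m:
        raise ValueError(f"need at least {m} uncensored observations, have {yu.size}")
    probs = np.arange(1, m + 1) / (m + 1)
    return np.quantile(yu, probs)


def parse_grid(spec: str) -> np.ndarray:
    """Parse ``"start:stop:step"`` into an inclusive evenly spaced grid."""
    try:
        start, stop, step = (float(v) for v in spec.split(":"))
    except ValueError as exc:
        raise ValueError(f"grid spec {spec!r} is not 'start:stop:step'") from exc
    npts = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(npts)
    if npts < 1 or grid[-1] > stop + 1e-9:
        raise ValueError(f"grid spec {spec!r} produces no points in range")
    return grid


def _check_grid(grid) -> np.ndarray:
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size < 1 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing positive times")
    return grid


def _eval_log_step(logfac: np.ndarray, times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """exp of row-wise cumulated log-factors evaluated at grid points."""
    cum = np.cumsum(logfac, axis=-1)
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.ones(logfac.shape[:-1] + (grid.size,))
    inside = idx >= 0
    if np.any(inside):
        out[..., inside] = np.exp(cum[..., idx[inside]])
    return out


def _loo_product_limit(d_eff, risk_full, risk_i, e_i):
    """Leave-one-out log factors for a product-limit estimator.

    ``d_eff``: (k,) effective event mass per distinct time (already on the
    scale matching the risk sums); ``risk_full``: (k,) full-sample risk sums;
    ``risk_i``, ``e_i``: (n, k) per-subject risk and event contributions.
    Returns (logfac (n,k), zero_risk_flags (n,)).
    """
    num = d_eff[None, :] - e_i
    den = risk_full[None, :] - risk_i
    bad = (den <= 0) & (num > 0)  # zero-risk rule: skip factor, flag subject
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    factors = np.clip(1.0 - frac, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        logfac = np.log(factors)
    logfac[bad] = 0.0
    return logfac, bad.any(axis=1)


def _wang_loo_values(sample: LBRCSample, grid: np.ndarray):
    times, d = _event_table(sample)
    sr = _wang_risk_sum(sample, times).astype(float)
    a, y, vt, delta = sample.a, sample.y, sample.vtilde, sample.delta
    risk_i = (
        ((a[:, None] <= times) & (times <= y[:, None])).astype(np.int8)
        + ((delta[:, None] == 1) & (vt[:, None] <= times) & (times <= y[:, None])).astype(
            np.int8
        )
    ).astype(float)
    e_i = 2.0 * ((delta[:, None] == 1) & (y[:, None] == times)).astype(float)
    logfac, bad = _loo_product_limit(2.0 * d.astype(float), sr, risk_i, e_i)
    return _eval_log_step(logfac, times, grid), bad


def _ltrc_loo_values(sample: LBRCSample, grid: np.ndarray):
    times, d = _event_table(sample)
    a, y, delta = sample.a, sample.y, sample.delta
    r = (
        np.searchsorted(np.sort(a), times, side="left")
        - np.searchsorted(np.sort(y), times, side="left")
    ).astype(float)
    risk_i = ((a[:, None] < times) & (times <= y[:, None])).astype(float)
    e_i = ((delta[:, None] == 1) & (y[:, None] == times)).astype(float)
    logfac, bad = _loo_product_limit(d.astype(float), r, risk_i, e_i)
    return _eval_log_step(logfac, times, grid), bad


def _vardi_loo_values(sample: LBRCSample, grid: np.ndarray, full: SurvivalCurve, tol, max_iter):
    """Leave-one-out NPMLE values, EM warm-started at the full-sample fit."""
    support, d = _event_table(sample)
    y_cens = sample.y[sample.delta == 0]
    p_full = full.masses
    n = sample.n
    loo = np.empty((n, grid.size))
    bad = np.zeros(n, dtype=bool)
    cens_pos = np.flatnonzero(sample.delta == 0)
    ev_pos = np.flatnonzero(sample.delta == 1)
    ev_idx = np.searchsorted(support, sample.y[ev_pos])

    def _refit(support_i, d_i, y_cens_i, p0):
        cens_idx, _ = _vardi_em_arrays(support_i, d_i, y_cens_i)
        p, _, _, conv = _vardi_em(support_i, d_i.astype(float), cens_idx, p0, tol, max_iter)
        q = p / support_i
        tail = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
        vals = tail[np.searchsorted(support_i, grid, side="right")] / tail[0]
        return vals, conv

    # censored subjects: same support, one censored term removed
    for j, i in enumerate(cens_pos):
        y_cens_i = np.delete(y_cens, j)
        loo[i], conv = _refit(support, d, y_cens_i, p_full)
        bad[i] |= not conv
    # event subjects: decrement the event count at their support point
    for j, i in enumerate(ev_pos):
        k = ev_idx[j]
        d_i = d.copy()
        d_i[k] -= 1
        if d_i[k] == 0:
            support_i = np.delete(support, k)
            d_i = np.delete(d_i, k)
            if d_i.size == 0:
                bad[i] = True
                loo[i] = np.nan
                continue
            p0 = np.delete(p_full, k)
        else:
            support_i = support
            p0 = p_full.copy()
            p0[k] *= (d_i[k]) / (d_i[k] + 1.0)
        loo[i], conv = _refit(support_i, d_i, y_cens, p0 / p0.sum())
        bad[i] |= not conv
    return loo, bad


def _empirical_loo_values(sample: LBRCSample, grid: np.ndarray):
    """Test hook: empirical survival of the raw times, ignoring truncation
    and censoring.  The jackknife of a sample mean returns its summand, so
    the pseudo-values reduce to ``1{y_i > tau_j}``."""
    ind = (sample.y[:, None] > grid).astype(float)
    loo = (ind.sum(axis=0)[None, :] - ind) / (sample.n - 1)
    return loo, np.zeros(sample.n, dtype=bool)


def jackknife_pseudo(
    sample: LBRCSample,
    estimator_kind: str = "wang",
    grid=None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> PseudoMatrix:
    """Jackknife pseudo-observations for one of the survival estimators.

    Parameters
    ----------
    estimator_kind : {"wang", "vardi", "ltrc", "empirical"}
        Survival estimator to jackknife.  ``empirical`` is a naive
        (truncation/censoring-blind) test hook.
    grid : array-like
        Strictly increasing positive evaluation times; defaults to the
        9-point quantile grid of :func:`default_grid`.
    tol, max_iter :
        EM controls, used by the ``vardi`` estimator only.
    """
    if estimator_kind not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator_kind!r}; choose from {ESTIMATORS}")
    if sample.n < 3:
        raise ValueError("jackknife needs at least 3 subjects")
    grid = default_grid(sample, 9) if grid is None else _check_grid(grid)
    n = sample.n

    if estimator_kind == "wang":
        full_vals = wang_estimator(sample)(grid)
        loo, bad = _wang_loo_values(sample, grid)
    elif estimator_kind == "ltrc":
        full_vals = ltrc_km(sample)(grid)
        loo, bad = _ltrc_loo_values(sample, grid)
    elif estimator_kind == "vardi":
        full = vardi_npmle(sample, tol=tol, max_iter=max_iter)
        full_vals = full(grid)
        loo, bad = _vardi_loo_values(sample, grid, full, tol, max_iter)
        if not full.converged:
            bad[:] = True
    else:  # empirical test hook
        full_vals = np.mean(sample.y[:, None] > grid, axis=0)
        loo, bad = _empirical_loo_values(sample, grid)

    values = n * np.atleast_1d(full_vals)[None, :] - (n - 1) * loo
    if bad.any():
        logger.warning(
            "jackknife_pseudo(%s): %d subject(s) flagged invalid",
            estimator_kind,
            int(bad.sum()),
        )
    return PseudoMatrix(
        values=values, grid=grid, estimator_kind=estimator_kind, valid=~bad
    )
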