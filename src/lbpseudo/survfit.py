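"""Nonparametric survival estimation under length-biased right censoring.

Three estimators of the *unbiased* survival function ``S`` are provided:

* :func:`wang_estimator` -- the closed-form product-limit estimator built
  from the LBRC risk process ``R_i(t) = 1{a_i <= t <= y_i} +
  delta_i 1{y_i - a_i <= t <= y_i}``, i.e. a subject is counted at risk both
  on the calendar segment it is under observation and, if it failed, on its
  residual-time segment.  The estimator is
  ``S_W(t) = prod_{u <= t} (1 - dH_n(u) / R_n(u))`` with
  ``H_n(t) = n^{-1} sum_i delta_i 1{y_i <= t}`` and
  ``R_n(t) = (2n)^{-1} sum_i R_i(t)``.
* :func:`vardi_npmle` -- the nonparametric maximum-likelihood estimator.
  The length-biased lifetime distribution ``F_LB`` is estimated by EM
  (events contribute ``f_LB(y_i)/y_i``, censored subjects contribute the
  1/x-weighted tail mass above ``y_i``), and the unbiased survival follows
  by inverting the length bias:
  ``S_V(y) = int_y^inf x^{-1} S_LB(dx) / int_0^inf x^{-1} S_LB(dx)``.
* :func:`ltrc_km` -- the left-truncation-adjusted Kaplan-Meier comparator,
  which uses only ``a_i < u <= y_i`` risk sets and ignores the uniform
  (stationary) law of the truncation times.

:func:`influence_phi` evaluates the plug-in influence function of the Wang
estimator, the first-order term of its linearization; it has mean zero and
serves as a variance/linearization oracle in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import LBRCSample

__all__ = [
    "SurvivalCurve",
    "risk_indicator",
    "risk_process",
    "wang_estimator",
    "ltrc_km",
    "vardi_npmle",
    "influence_phi",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Right-continuous non-increasing step estimate of a survival function.

    The curve equals 1 on ``[0, jump_times[0])``, takes ``values[k]`` on
    ``[jump_times[k], jump_times[k+1])`` and stays at ``values[-1]`` beyond
    the last jump.
    """

    jump_times: np.ndarray
    values: np.ndarray
    converged: bool = True
    flagged: bool = False
    n_iter: int = 0
    # NPMLE extras (None for the product-limit estimators)
    support: np.ndarray | None = None
    masses: np.ndarray | None = None
    loglik: float | None = None

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.jump_times.shape != self.values.shape:
            raise ValueError("jump_times and values must have equal length")
        if np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": np.concatenate([[0.0], self.jump_times]),
                "survival": np.concatenate([[1.0], self.values]),
            }
        )


def risk_indicator(record, t):
    """LBRC risk-set indicator ``R_i(t)`` in ``{0, 1, 2}``.

    ``record`` is anything with fields ``a``, ``y``, ``delta`` (scalars or
    arrays); ``R_i(t) = 1{a <= t <= y} + delta * 1{y - a <= t <= y}``.
    """
    a, y, delta = np.asarray(record.a), np.asarray(record.y), np.asarray(record.delta)
    t = np.asarray(t, dtype=float)
    vt = y - a
    first = (a <= t) & (t <= y)
    second = (delta == 1) & (vt <= t) & (t <= y)
    out = first.astype(np.int64) + second.astype(np.int64)
    return out if out.ndim else int(out)


def _event_table(sample: LBRCSample):
    """Distinct uncensored times (sorted) and their event counts."""
    yu = sample.y[sample.delta == 1]
    if yu.size == 0:
        raise ValueError("no uncensored events in the sample")
    return np.unique(yu, return_counts=True)


def _wang_risk_sum(sample: LBRCSample, t: np.ndarray) -> np.ndarray:
    """``sum_i R_i(t)`` evaluated at sorted times ``t`` in O(n log n)."""
    t = np.asarray(t, dtype=float)
    a_sorted = np.sort(sample.a)
    y_sorted = np.sort(sample.y)
    unc = sample.delta == 1
    v_sorted = np.sort(sample.vtilde[unc])
    yu_sorted = np.sort(sample.y[unc])
    # 1{a <= t <= y} summed: #{a_i <= t} - #{y_i < t}
    obs = np.searchsorted(a_sorted, t, side="right") - np.searchsorted(
        y_sorted, t, side="left"
    )
    # delta 1{v <= t <= y} summed over events (v <= y always for events)
    res = np.searchsorted(v_sorted, t, side="right") - np.searchsorted(
        yu_sorted, t, side="left"
    )
    return obs + res


def risk_process(sample: LBRCSample, t):
    """The pair ``(H_n(t), R_n(t))`` of LBRC counting processes.

    ``n H_n(t)`` counts uncensored failures up to ``t``; ``R_n(t)`` is half
    the mean risk indicator, the at-risk normalizer of the Wang estimator.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    unc = sample.delta == 1
    h = np.searchsorted(np.sort(sample.y[unc]), t, side="right") / sample.n
    r = _wang_risk_sum(sample, t) / (2.0 * sample.n)
    if scalar:
        return float(h[0]), float(r[0])
    return h, r


def _product_limit(times, d, risk, *, label) -> SurvivalCurve:
    """Common product-limit assembly with the zero-risk skip rule."""
    flagged = False
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(risk > 0, d / np.where(risk > 0, risk, 1.0), np.nan)
    if np.any(risk <= 0):
        flagged = True
        logger.warning(
            "%s: zero risk set at %d event time(s); factors skipped",
            label,
            int(np.sum(risk <= 0)),
        )
        frac = np.where(risk > 0, frac, 0.0)
    factors = np.clip(1.0 - frac, 0.0, 1.0)
    values = np.cumprod(factors)
    return SurvivalCurve(jump_times=times, values=values, flagged=flagged)


def wang_estimator(sample: LBRCSample) -> SurvivalCurve:
    """Product-limit estimator of the unbiased survival under LBRC data.

    Note that the sample size cancels in each factor:
    ``1 - dH_n(u)/R_n(u) = 1 - 2 d(u) / sum_i R_i(u)``.
    """
    times, d = _event_table(sample)
    sr = _wang_risk_sum(sample, times)
    return _product_limit(times, 2.0 * d, sr, label="wang_estimator")


def ltrc_km(sample: LBRCSample) -> SurvivalCurve:
    """Left-truncated Kaplan-Meier: risk set ``r(u) = #{a_i < u <= y_i}``.

    With all ``a_i = 0`` this is the ordinary Kaplan-Meier estimator.
    """
    times, d = _event_table(sample)
    r = np.searchsorted(np.sort(sample.a), times, side="left") - np.searchsorted(
        np.sort(sample.y), times, side="left"
    )
    return _product_limit(times, d.astype(float), r.astype(float), label="ltrc_km")


# ---------------------------------------------------------------------------
# Vardi NPMLE via EM
# ---------------------------------------------------------------------------


def _vardi_em_arrays(support, d, y_cens):
    """Precompute censored-subject tail indices; drop subjects with no tail.

    A censored subject only constrains mass strictly above its observed time;
    if no support point lies above it (it outlasts every event) its tail
    probability is undetermined and the subject is dropped from the
    likelihood, mirroring the Kaplan-Meier undetermined-tail convention.
    """
    idx = np.searchsorted(support, y_cens, side="right")
    keep = idx < support.size
    return idx[keep], int(np.sum(~keep))


def vardi_loglik(support, masses, d, cens_idx) -> float:
    """Log-likelihood of the discrete length-biased NPMLE (up to constants).

    ``sum_k d_k log p_k + sum_cens log sum_{s_k > y_i} p_k / s_k``.
    """
    q = masses / support
    tail = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
    with np.errstate(divide="ignore"):
        ll = float(d @ np.log(masses) + np.sum(np.log(tail[cens_idx])))
    return ll


def _vardi_em(support, d, cens_idx, p0, tol, max_iter):
    """EM iterations; returns (masses, loglik, n_iter, converged)."""
    p = np.asarray(p0, dtype=float)
    p = p / p.sum()
    total = float(d.sum() + cens_idx.size)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        q = p / support
        tail = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
        ti = tail[cens_idx]
        with np.errstate(divide="ignore"):
            ll = float(d @ np.log(p) + np.sum(np.log(ti)))
        if ll - ll_old < tol and np.isfinite(ll):
            converged = True
            ll_old = ll
            break
        ll_old = ll
        # E-step: censored subject i spreads weight q_k / T_i over s_k > y_i;
        # M-step: masses proportional to expected counts.
        w = np.bincount(cens_idx, weights=1.0 / ti, minlength=support.size)
        p = (d + q * np.cumsum(w)) / total
    return p, ll_old, it, converged


def vardi_npmle(
    sample: LBRCSample,
    tol: float = 1e-8,
    max_iter: int = 5000,
    init: np.ndarray | None = None,
) -> SurvivalCurve:
    """Vardi's NPMLE of the unbiased survival function under LBRC data.

    The length-biased distribution is supported on the distinct uncensored
    times; its masses are fit by EM (monotone in log-likelihood) and the
    unbiased-scale survival is recovered through the ``1/x`` inversion,
    renormalized so the curve starts at 1.

    Parameters
    ----------
    init :
        Optional starting masses aligned with the support (warm start for
        jackknife refits); defaults to uniform mass over the support.
    """
    support, d = _event_table(sample)
    y_cens = sample.y[sample.delta == 0]
    cens_idx, n_dropped = _vardi_em_arrays(support, d, y_cens)
    if n_dropped:
        logger.debug(
            "vardi_npmle: %d censored subject(s) beyond the last event dropped",
            n_dropped,
        )
    p0 = np.full(support.size, 1.0 / support.size) if init is None else init
    p, ll, it, converged = _vardi_em(support, d.astype(float), cens_idx, p0, tol, max_iter)
    if not converged:
        logger.warning("vardi_npmle: EM not converged after %d iterations", it)

    q = p / support
    tail = np.concatenate([np.cumsum(q[::-1])[::-1], [0.0]])
    values = tail[1:] / tail[0]
    return SurvivalCurve(
        jump_times=support,
        values=values,
        converged=converged,
        n_iter=it,
        support=support,
        masses=p,
        loglik=ll,
    )


def influence_phi(sample: LBRCSample, t: float) -> np.ndarray:
    """Plug-in influence function of the Wang estimator at time ``t``.

    ``phi_i(t) = delta_i 1{y_i <= t} / R_n(y_i)
    - (1/2) sum_{u <= t} R_n(u)^{-2} R_i(u) dH_n(u)``,
    summing over distinct uncensored times ``u <= t``.  ``E phi_i(t) = 0``
    asymptotically; the sample mean shrinks at the root-n rate.
    """
    n = sample.n
    times, d = _event_table(sample)
    sel = times <= t
    u = times[sel]
    du = d[sel] / n
    rn_u = _wang_risk_sum(sample, u) / (2.0 * n)
    ok = rn_u > 0
    if not ok.all():
        logger.warning("influence_phi: zero-risk event times inside [0, t] excluded")
    u, du, rn_u = u[ok], du[ok], rn_u[ok]

    # first term: event before t, weighted by 1 / R_n(y_i)
    first = np.zeros(n)
    ev = (sample.delta == 1) & (sample.y <= t)
    if np.any(ev):
        _, rn_y = risk_process(sample, sample.y[ev])
        first[ev] = 1.0 / rn_y

    # integral term: (1/2) sum_u R_n(u)^{-2} R_i(u) dH_n(u)
    rmat = (
        ((sample.a[:, None] <= u) & (u <= sample.y[:, None])).astype(np.int8)
        + (
            (sample.delta[:, None] == 1)
            & (sample.vtilde[:, None] <= u)
            & (u <= sample.y[:, None])
        ).astype(np.int8)
    )
    second = 0.5 * rmat @ (du / rn_u**2)
    return first - second
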