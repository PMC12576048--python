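"""Cohort simulator for length-biased right-censored survival data.

The generator reproduces a stationary-incidence prevalent cohort: unbiased
event times follow a Cox model with a Weibull-type baseline, disease onset is
uniform over a long calendar window, and a subject enters the cohort only if
still alive at the recruitment date.  Acceptance therefore tilts the sampled
event times toward longer durations (density ``t f(t) / mu``), and the
truncation time is uniform given the event time.  Residual censoring acts on
the time *since recruitment* and is uniform on ``(0, c)`` with the scale ``c``
calibrated to hit a target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cohort import LBRCSample

__all__ = [
    "TrueModel",
    "SCENARIOS",
    "scenario_model",
    "draw_unbiased_time",
    "simulate_cohort",
    "calibrate_censoring",
]

# baseline hazard families: lambda0(t), Lambda0(t), Lambda0^{-1}(s)
_BASELINES = {
    "constant": (lambda t: 2.0 * np.ones_like(t), lambda t: 2.0 * t, lambda s: s / 2.0),
    "linear": (lambda t: 2.0 * t, lambda t: t**2, np.sqrt),
    "quadratic": (lambda t: 24.0 * t**2, lambda t: 8.0 * t**3, lambda s: np.cbrt(s / 8.0)),
}

#: default log hazard ratios used throughout the simulation designs
DEFAULT_BETA = (np.log(2.0), np.log(0.8))


@dataclass(frozen=True)
class TrueModel:
    """Data-generating Cox model ``lambda(t|x) = lambda0(t) exp(x' beta)``.

    ``baseline_id`` selects the baseline hazard among ``constant`` (2),
    ``linear`` (2t) and ``quadratic`` (24 t^2); ``window`` is the length of
    the uniform onset window (recruitment happens at its right end).
    """

    baseline_id: str = "constant"
    beta: tuple[float, ...] = field(default=DEFAULT_BETA)
    window: float = 100.0

    def __post_init__(self) -> None:
        if self.baseline_id not in _BASELINES:
            raise ValueError(
                f"unknown baseline {self.baseline_id!r}; choose from {sorted(_BASELINES)}"
            )
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))

    def cum_hazard(self, t):
        return _BASELINES[self.baseline_id][1](np.asarray(t, dtype=float))

    def inv_cum_hazard(self, s):
        return _BASELINES[self.baseline_id][2](np.asarray(s, dtype=float))

    def survival(self, t, x):
        """Conditional survival ``S(t|x) = exp(-Lambda0(t) e^{x'beta})``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        eta = x @ np.asarray(self.beta)
        return np.exp(-np.multiply.outer(self.cum_hazard(t), np.exp(eta))).squeeze()


#: the three simulation scenarios (I: constant, II: linear, III: quadratic)
SCENARIOS = {"I": "constant", "II": "linear", "III": "quadratic"}


def scenario_model(scenario: str, beta=DEFAULT_BETA, window: float = 100.0) -> TrueModel:
    """Build the :class:`TrueModel` for scenario ``"I"``, ``"II"`` or ``"III"``."""
    key = str(scenario).upper()
    if key not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    return TrueModel(SCENARIOS[key], beta=tuple(beta), window=window)


def draw_unbiased_time(model: TrueModel, x, u):
    """Invert the conditional survival function at uniform draw(s) ``u``.

    Returns ``Lambda0^{-1}(-log(u) * exp(-x'beta))``, whose survival function
    is exactly ``exp(-Lambda0(t) e^{x'beta})``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie in the open interval (0, 1)")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    eta = x @ np.asarray(model.beta)
    s = -np.log(u) * np.exp(-eta.squeeze())
    return model.inv_cum_hazard(s)


def _draw_covariates(rng: np.random.Generator, size: int) -> np.ndarray:
    """Designed covariate mix: x1 binary, evenly split; x2 ~ U(-1, 1).

    The covariates are subject-level design variables, fixed before the
    length-biased acceptance step, so the cohort keeps the designed mix
    (acceptance tilts each subject's lifetime given its covariates, not the
    covariate distribution itself).
    """
    x1 = np.zeros(size)
    x1[: size // 2] = 1.0
    rng.shuffle(x1)
    x2 = rng.uniform(-1.0, 1.0, size=size)
    return np.column_stack([x1, x2])


def simulate_cohort(
    model: TrueModel,
    n: int,
    censor_scale: float | None = None,
    seed: int | np.random.Generator = 0,
    max_proposal_factor: int = 1000,
) -> LBRCSample:
    """Draw an LBRC cohort of ``n`` accepted subjects.

    Each subject carries fixed covariates ``x``; pairs ``(T, A)`` with
    ``T`` from the Cox model given ``x`` and ``A = window - xi``,
    ``xi ~ U(0, window)``, are redrawn until ``A <= T`` (alive at
    recruitment).  Acceptance induces the length-biased law of ``(A, T)``
    given ``x``: density ``f(t|x)/mu(x)`` on ``{t > a}``.  Residual
    censoring ``C ~ U(0, c)`` is then applied on the time since recruitment:
    ``Y = A + min(T - A, C)`` and ``delta = 1{T - A <= C}``.  With
    ``censor_scale=None`` no censoring is applied (``delta = 1``).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x = _draw_covariates(rng, n)
    rate = np.exp(-(x @ np.asarray(model.beta)))  # exp(-x'beta), scales -log(u)

    t = np.empty(n)
    a = np.empty(n)
    pending = np.arange(n)
    proposed = 0
    cap = max_proposal_factor * n
    k_per_round = 256  # proposals per pending subject per vectorized round
    while pending.size:
        npend = pending.size
        k = int(min(k_per_round, max(1, (cap - proposed) // max(npend, 1))))
        if proposed >= cap:
            raise RuntimeError(
                f"rejection sampler left {npend}/{n} subjects unaccepted after "
                f"{proposed} proposals; the onset window ({model.window}) likely "
                "dwarfs the lifetime support"
            )
        u = rng.uniform(size=(npend, k))
        tt = model.inv_cum_hazard(-np.log(u) * rate[pending, None])
        aa = model.window - rng.uniform(0.0, model.window, size=(npend, k))
        ok = aa <= tt
        has = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        rows = np.flatnonzero(has)
        done = pending[rows]
        t[done] = tt[rows, first[rows]]
        a[done] = aa[rows, first[rows]]
        pending = pending[~has]
        proposed += npend * k

    if censor_scale is None:
        y = t
        delta = np.ones(n, dtype=np.int64)
    else:
        if censor_scale <= 0:
            raise ValueError("censor_scale must be positive")
        c = rng.uniform(0.0, censor_scale, size=n)
        v = t - a
        delta = (v <= c).astype(np.int64)
        y = a + np.minimum(v, c)
    return LBRCSample(a=a, y=y, delta=delta, x=x, covariate_names=("x1", "x2"))


def calibrate_censoring(
    model: TrueModel,
    target_rate: float,
    n_pilot: int = 10_000,
    seed: int = 0,
) -> float:
    """Censoring scale ``c`` achieving the target censoring fraction.

    A pilot cohort is simulated once without censoring; conditional on its
    residual lifetimes ``V_i = T_i - A_i``, the censoring probability under
    ``C ~ U(0, c)`` is exactly ``r(c) = mean_i min(V_i / c, 1)``, a continuous
    decreasing function of ``c``, so the calibration reduces to deterministic
    root finding on the bracket ``[1e-3, 1e3]``.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValueError("target_rate must lie strictly between 0 and 1")
    pilot = simulate_cohort(model, n_pilot, censor_scale=None, seed=seed)
    v = pilot.vtilde

    def rate(c: float) -> float:
        return float(np.minimum(v / c, 1.0).mean())

    lo, hi = 1e-3, 1e3
    if rate(hi) > target_rate:
        raise ValueError(f"target censoring rate {target_rate} not reachable with c <= {hi}")
    if rate(lo) < target_rate:
        raise ValueError(f"target censoring rate {target_rate} not reachable with c >= {lo}")
    return float(brentq(lambda c: rate(c) - target_rate, lo, hi, xtol=1e-8, rtol=1e-12))
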