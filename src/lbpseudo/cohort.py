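"""Container for length-biased right-censored (LBRC) survival samples.

A prevalent-cohort observation consists of the truncation time ``a`` (disease
onset to recruitment), the total observed time ``y`` (onset to event or
censoring, so ``y = a + min(v, c)`` with ``v`` the residual lifetime and ``c``
the residual censoring time), the event indicator ``delta`` and a covariate
vector.  Inclusion in the cohort requires survival past recruitment
(``y >= a``), which is what induces the length bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["LBRCSample"]


@dataclass(frozen=True)
class LBRCSample:
    """An observed LBRC cohort ``(a_i, y_i, delta_i, x_i), i = 1..n``.

    Parameters
    ----------
    a : (n,) array
        Truncation times, onset -> recruitment.
    y : (n,) array
        Total observed times, onset -> event-or-censoring.
    delta : (n,) int array
        Event indicators (1 = event, 0 = right-censored).
    x : (n, p) array
        Baseline covariates.
    covariate_names : tuple of str
        Labels for the p covariate columns.
    """

    a: np.ndarray
    y: np.ndarray
    delta: np.ndarray
    x: np.ndarray
    covariate_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        y = np.asarray(self.y, dtype=float)
        delta = np.asarray(self.delta)
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if x.shape[0] != a.shape[0]:
            x = x.T
        if a.ndim != 1 or a.shape != y.shape or a.shape != delta.shape:
            raise ValueError("a, y and delta must be 1-d arrays of equal length")
        if a.shape[0] < 2:
            raise ValueError("an LBRC sample needs at least two subjects")
        if x.shape[0] != a.shape[0]:
            raise ValueError("covariate matrix must have one row per subject")
        if np.any(a < 0) or np.any(a > y):
            bad = int(np.flatnonzero((a < 0) | (a > y))[0])
            raise ValueError(f"subject {bad}: truncation times must satisfy 0 <= a <= y")
        if not np.isin(delta, (0, 1)).all():
            raise ValueError("delta must be binary")
        names = tuple(self.covariate_names) or tuple(
            f"x{j + 1}" for j in range(x.shape[1])
        )
        if len(names) != x.shape[1]:
            raise ValueError("covariate_names length must match covariate dimension")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "delta", delta.astype(np.int64))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def vtilde(self) -> np.ndarray:
        """Residual observed times ``y - a`` (time on study)."""
        return self.y - self.a

    def drop(self, i: int) -> "LBRCSample":
        """Leave-one-out subsample with subject ``i`` removed."""
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return self.subset(keep)

    def subset(self, mask: np.ndarray) -> "LBRCSample":
        return replace(
            self,
            a=self.a[mask],
            y=self.y[mask],
            delta=self.delta[mask],
            x=self.x[mask],
        )

    def permute(self, order: np.ndarray) -> "LBRCSample":
        return self.subset(np.asarray(order))
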