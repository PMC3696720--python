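"""Wald (inverse-Gaussian) first-passage-time distribution.

The drift core of the response-time model: evidence accumulates as a
biased random walk at ``v`` net steps per millisecond toward a response
criterion of ``C`` steps.  The first-passage time of the continuum limit
of that walk is Wald-distributed with density

    f(t) = C / sqrt(2 pi t^3) * exp(-(C - v t)^2 / (2 t)),   t > 0,

i.e. an inverse Gaussian with mean ``C/v`` and shape ``C**2``.  This
module provides the density, distribution function, quantile, closed-form
moments, a reproducible sampler, and a discrete random-walk simulator
that serves as an independent oracle for the continuum distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import log_ndtr, ndtr

__all__ = [
    "WaldParams",
    "wald_pdf",
    "wald_cdf",
    "wald_quantile",
    "wald_moments",
    "sample_wald",
    "random_walk_first_passage",
]


@dataclass(frozen=True)
class WaldParams:
    """Parameters of the accumulation process.

    Attributes
    ----------
    criterion : float
        Number of net computation steps required before a response is
        emitted (``C``).  Must be positive.
    speed : float
        Net drift of the accumulation in steps per millisecond (``v``);
        interpreted as the energy available for the response.  Must be
        positive.
    """

    criterion: float
    speed: float

    def __post_init__(self) -> None:
        if not (self.criterion > 0 and np.isfinite(self.criterion)):
            raise ValueError(f"criterion must be positive, got {self.criterion}")
        if not (self.speed > 0 and np.isfinite(self.speed)):
            raise ValueError(f"speed must be positive, got {self.speed}")

    @property
    def mean(self) -> float:
        """Implied mean first-passage time C/v in ms."""
        return self.criterion / self.speed

    def to_dict(self) -> dict:
        return {"criterion": self.criterion, "speed": self.speed}

    @classmethod
    def from_dict(cls, d: dict) -> "WaldParams":
        return cls(criterion=float(d["criterion"]), speed=float(d["speed"]))


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive (first-passage times are > 0)")
    return t


def wald_pdf(params: WaldParams, t):
    """Density (per ms) of the first-passage time at ``t`` ms.

    Vectorized over ``t``; raises ``ValueError`` for nonpositive ``t``.
    """
    t = _check_t(t)
    C, v = params.criterion, params.speed
    return C / np.sqrt(2.0 * np.pi * t**3) * np.exp(-((C - v * t) ** 2) / (2.0 * t))


def wald_cdf(params: WaldParams, t):
    """Distribution function P(first passage <= t).

    Evaluated as ``Phi((vt-C)/sqrt(t)) + exp(2Cv) * Phi(-(vt+C)/sqrt(t))``
    with the second term computed in log space: ``2Cv`` routinely exceeds
    50 for realistic parameters, so the naive product overflows while the
    true term is a well-scaled probability.
    """
    t = _check_t(t)
    C, v = params.criterion, params.speed
    s = np.sqrt(t)
    return ndtr((v * t - C) / s) + np.exp(2.0 * C * v + log_ndtr(-(v * t + C) / s))


def wald_quantile(params: WaldParams, p: float) -> float:
    """Time t (ms) with wald_cdf(t) = p, to 1e-9 in probability.

    Brackets the root around the mean and expands geometrically before
    handing off to Brent's method.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    m = params.mean
    lo, hi = m / 100.0, m * 100.0
    while wald_cdf(params, lo) > p:
        lo /= 10.0
    while wald_cdf(params, hi) < p:
        hi *= 10.0
    return brentq(lambda t: float(wald_cdf(params, t)) - p, lo, hi, xtol=1e-12, rtol=1e-14)


def wald_moments(params: WaldParams) -> tuple[float, float, float, float]:
    """Closed-form (mean, sd, cv, skewness).

    mean = C/v, sd = sqrt(C/v^3), cv = (Cv)^(-1/2), skew = 3 (Cv)^(-1/2).
    """
    C, v = params.criterion, params.speed
    mean = C / v
    sd = np.sqrt(C / v**3)
    cv = 1.0 / np.sqrt(C * v)
    return mean, sd, cv, 3.0 * cv


def sample_wald(params: WaldParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. first-passage times (ms), reproducibly.

    Uses the Michael–Schucany–Haas transformation method on the inverse
    Gaussian with mean ``C/v`` and shape ``C**2`` (var = C/v^3 =
    mean^3/shape).  ``seed`` may be an int or a ``numpy`` Generator.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = params.mean
    lam = params.criterion**2
    nu = rng.standard_normal(n)
    y = nu**2
    x = mu + mu * mu * y / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * y + (mu * y) ** 2
    )
    u = rng.random(n)
    return np.where(u <= mu / (mu + x), x, mu * mu / x)


def random_walk_first_passage(
    criterion: int, step_prob: float, n: int, seed, max_steps: int | None = None
) -> np.ndarray:
    """First-passage times of a discrete +/-1 random walk, 1 step per ms.

    Steps up with probability ``step_prob`` (> 0.5 so passage is certain
    in drift time ~ C/(2p-1)); returns the first times the running sum
    reaches ``criterion``.  The net velocity is ``v = 2 step_prob - 1``,
    but the walk's variance per step is ``1 - v**2``, slightly below the
    unit diffusion of the continuum Wald, so agreement is approximate.
    """
    if not 0.5 < step_prob <= 1.0:
        raise ValueError(f"step_prob must lie in (0.5, 1], got {step_prob}")
    if criterion < 1 or int(criterion) != criterion:
        raise ValueError(f"criterion must be a positive integer, got {criterion}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    criterion = int(criterion)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v = 2.0 * step_prob - 1.0
    if max_steps is None:
        # mean passage C/v plus a generous tail allowance
        max_steps = int(20 * criterion / v) + 200

    out = np.empty(n, dtype=float)
    remaining = n
    filled = 0
    block = criterion * 8 if step_prob < 1.0 else criterion
    while remaining > 0:
        m = min(remaining, 4000)
        pos = np.zeros(m, dtype=np.int64)
        hit_time = np.full(m, -1, dtype=np.int64)
        t = 0
        active = np.arange(m)
        while active.size and t < max_steps:
            steps = np.where(
                rng.random((active.size, block)) < step_prob, 1, -1
            ).cumsum(axis=1)
            paths = pos[active, None] + steps
            crossed = paths >= criterion
            any_cross = crossed.any(axis=1)
            if any_cross.any():
                first = crossed[any_cross].argmax(axis=1)
                hit_time[active[any_cross]] = t + first + 1
            pos[active] = paths[:, -1]
            active = active[~any_cross]
            t += block
        if np.any(hit_time < 0):  # pragma: no cover - max_steps is generous
            raise RuntimeError("random walk failed to reach criterion within max_steps")
        out[filled : filled + m] = hit_time.astype(float)
        filled += m
        remaining -= m
    return out
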