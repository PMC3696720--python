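"""Moment-matching imputation of drift parameters and stop-time analysis.

Published studies rarely report full response-time distributions, but
usually report a mean and a standard deviation (or coefficient of
variation).  Matching those two moments to the Wald closed forms
``mean = C/v`` and ``sd = sqrt(C/v^3)`` gives

    v = sqrt(mean) / sd        (steps per ms)
    C = mean * v               (steps)

Commission errors on NOGO trials are modelled by a race against a fixed
abort latency T_stop: a response slips through whenever its first-passage
time beats T_stop, so the predicted commission rate is the Wald CDF at
T_stop, and conversely T_stop can be inferred from an observed rate by
inverting the CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wald import WaldParams, wald_cdf, wald_quantile

__all__ = [
    "ConditionStats",
    "StopRule",
    "impute_params",
    "predict_fp",
    "infer_tstop",
]


@dataclass(frozen=True)
class ConditionStats:
    """Summary statistics for one condition or group.

    Exactly one of ``sd_rt`` (ms) or ``cv`` (dimensionless) must be
    given; a supplied cv is converted via sd = cv * mean.  ``foreperiod``
    is the wait (s) between trial onset and target; ``fp_observed`` is
    the observed commission-error rate as a fraction.

    A nonempty ``flag`` marks a degenerate summary (e.g. too few trials
    for an SD); flagged rows skip the moment invariants and are rejected
    by downstream estimation rather than silently dropped.
    """

    label: str
    mean_rt: float | None
    sd_rt: float | None = None
    cv: float | None = None
    foreperiod: float = 0.0
    fp_observed: float | None = None
    n: int | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.flag is None:
            if (self.sd_rt is None) == (self.cv is None):
                raise ValueError(
                    f"condition {self.label!r}: give exactly one of sd_rt or cv"
                )
            if self.mean_rt is None or not self.mean_rt > 0:
                raise ValueError(f"mean_rt must be positive, got {self.mean_rt}")
            if self.cv is not None:
                if not self.cv > 0:
                    raise ValueError(f"cv must be positive, got {self.cv}")
                object.__setattr__(self, "sd_rt", self.cv * self.mean_rt)
            if not self.sd_rt > 0:
                raise ValueError(f"sd_rt must be positive, got {self.sd_rt}")
        if self.foreperiod < 0:
            raise ValueError(f"foreperiod must be >= 0, got {self.foreperiod}")
        if self.fp_observed is not None and not 0.0 <= self.fp_observed <= 1.0:
            raise ValueError(f"fp_observed must be a probability, got {self.fp_observed}")


@dataclass(frozen=True)
class StopRule:
    """Fixed latency T_stop (ms) to abort an initiated response."""

    t_stop: float

    def __post_init__(self) -> None:
        if not self.t_stop > 0:
            raise ValueError(f"t_stop must be positive, got {self.t_stop}")


def impute_params(stats: ConditionStats) -> WaldParams:
    """Impute (C, v) from a condition's mean and SD by moment matching.

    Uses v = sqrt(mean)/sd, C = mean*v, the unique Wald parameters whose
    closed-form mean and SD equal the observed ones exactly.
    """
    if stats.flag is not None:
        raise ValueError(f"condition {stats.label!r} is flagged ({stats.flag}); cannot impute")
    v = float(np.sqrt(stats.mean_rt) / stats.sd_rt)
    return WaldParams(criterion=stats.mean_rt * v, speed=v)


def predict_fp(params: WaldParams, stop: StopRule) -> float:
    """Predicted commission rate: P(first passage < T_stop)."""
    return float(wald_cdf(params, stop.t_stop))


def infer_tstop(params: WaldParams, fp_observed: float) -> float:
    """Abort latency (ms) that reproduces an observed commission rate.

    Inverse of :func:`predict_fp`: the Wald quantile at ``fp_observed``.
    """
    if not 0.0 < fp_observed < 1.0:
        raise ValueError(f"fp_observed must lie strictly in (0, 1), got {fp_observed}")
    return wald_quantile(params, fp_observed)
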