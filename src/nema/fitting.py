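"""Least-squares estimation of the attentional model's parameters.

Two estimation problems are covered:

* :func:`fit_nema` recovers (C, v, lambda, tau) from condition-wise
  response-time means and SDs observed at several foreperiods, by
  minimising the unweighted sum of squared residuals of both moments
  jointly (means and SDs are on the same ms scale).
* :func:`fit_error_chain` recovers the Markov parameters (alpha, lambda)
  — and optionally the per-state error emissions — from a post-NOGO
  sequence of observed error probabilities.

Both use bounded trust-region least squares started from a fixed
multistart grid, so results are deterministic: no random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .attention import NEMAParams, error_curve, nema_moments
from .imputation import ConditionStats
from .wald import WaldParams

__all__ = ["FitResult", "fit_nema", "fit_error_chain", "NEMA_BOUNDS"]

# (C, v, lambda, tau) search box; brackets plausible human RT regimes
# with wide margins.
NEMA_BOUNDS = {
    "criterion": (1.0, 500.0),
    "speed": (0.01, 1.0),
    "lapse_prob": (0.0, 0.5),
    "recapture_mean_delay": (0.01, 5.0),
}


class UnderdeterminedError(ValueError):
    """Fewer independent observations than free parameters."""


@dataclass
class FitResult:
    params: NEMAParams
    loss: float
    residuals: np.ndarray
    converged: bool
    n_restarts_used: int
    extra: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "loss": self.loss,
            "residuals": list(map(float, self.residuals)),
            "converged": bool(self.converged),
            "n_restarts_used": self.n_restarts_used,
        }
        if self.extra:
            d.update(self.extra)
        return d


def _grid(bounds: tuple[float, float], k: int) -> np.ndarray:
    lo, hi = bounds
    # interior points: avoid starting pinned at a bound
    return lo + (hi - lo) * (np.arange(1, k + 1)) / (k + 1)


def _multistart(residual_fn, lower, upper, starts, xtol=1e-10, ftol=1e-14):
    """Run bounded TRF least squares from every start; best loss wins."""
    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residual_fn, x0, bounds=(lower, upper), method="trf",
                xtol=xtol, ftol=ftol, gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 0.0:
            best = sol
    if best is None:
        raise RuntimeError("all optimization starts failed")
    return best


def fit_nema(
    conditions: list[ConditionStats],
    variance_mode: str = "printed",
    n_grid: int = 3,
) -> FitResult:
    """Fit (C, v, lambda, tau) to condition means and SDs.

    Requires at least two distinct foreperiods (four unknowns need at
    least four observed moments).  Minimises
    sum_i (mu_i - mu_hat_i)^2 + (sd_i - sd_hat_i)^2 over the bounded box
    from a deterministic ``n_grid**4`` multistart grid.
    """
    flagged = [c.label for c in conditions if c.flag is not None]
    if flagged:
        raise ValueError(f"flagged condition rows cannot be fit: {flagged}")
    fps = sorted({c.foreperiod for c in conditions})
    if len(fps) < 2:
        raise UnderdeterminedError(
            f"need >= 2 distinct foreperiods to identify 4 parameters, got {fps}"
        )
    obs = np.array([[c.mean_rt, c.sd_rt] for c in conditions]).ravel()
    ts = np.array([c.foreperiod for c in conditions])

    def residual(x):
        C, v, lam, tau = x
        p = NEMAParams(WaldParams(C, v), lam, tau)
        pred = np.array([nema_moments(p, t, variance_mode) for t in ts]).ravel()
        return pred - obs

    names = ("criterion", "speed", "lapse_prob", "recapture_mean_delay")
    lower = np.array([NEMA_BOUNDS[n][0] for n in names])
    upper = np.array([NEMA_BOUNDS[n][1] for n in names])
    axes = [_grid(NEMA_BOUNDS[n], n_grid) for n in names]
    starts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(4, -1).T

    # a moment-matching warm start from the shortest foreperiod sharpens
    # convergence without breaking determinism
    c0 = min(conditions, key=lambda c: c.foreperiod)
    v0 = np.clip(np.sqrt(c0.mean_rt) / c0.sd_rt, *NEMA_BOUNDS["speed"])
    C0 = np.clip(c0.mean_rt * v0, *NEMA_BOUNDS["criterion"])
    starts = np.vstack([[C0, v0, 0.05, 0.3], starts])

    best = _multistart(residual, lower, upper, starts)
    C, v, lam, tau = best.x
    return FitResult(
        params=NEMAParams(WaldParams(C, v), lam, tau),
        loss=2.0 * best.cost,
        residuals=best.fun,
        converged=bool(best.success),
        n_restarts_used=len(starts),
    )


def fit_error_chain(
    observed,
    emissions_fixed: tuple[float, float] | None = None,
    start: str = "~A",
) -> FitResult:
    """Fit the Markov chain to a post-NOGO error-probability sequence.

    ``observed`` is a sequence of (trial index, error probability) with
    indices counted from 1 = first trial after the NOGO event.  Free
    parameters are (alpha, lambda), plus the two emissions when
    ``emissions_fixed`` is None.  A flat observed curve leaves the chain
    dynamics unidentifiable; the result is then flagged non-converged.
    """
    obs = np.asarray(list(observed), dtype=float)
    idx = obs[:, 0].astype(int)
    y = obs[:, 1]
    n_free = 2 if emissions_fixed is not None else 4
    if len(obs) < max(4, n_free):
        raise UnderdeterminedError(
            f"need >= {max(4, n_free)} observed points for {n_free} free parameters"
        )
    kmax = int(idx.max())

    def curve(alpha, lam, eA, enA):
        full = error_curve(lam, alpha, eA, enA, kmax, start=start)
        return full[idx - 1]

    if emissions_fixed is not None:
        eA, enA = emissions_fixed

        def residual(x):
            return curve(x[0], x[1], eA, enA) - y

        lower, upper = np.array([1e-6, 1e-6]), np.array([1.0, 1.0])
        axes = [np.linspace(0.05, 0.95, 5)] * 2
        starts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(2, -1).T
    else:

        def residual(x):
            return curve(x[0], x[1], x[2], x[3]) - y

        lower, upper = np.array([1e-6, 1e-6, 0.0, 0.0]), np.ones(4)
        axes = [np.linspace(0.1, 0.9, 3)] * 4
        starts = np.array(np.meshgrid(*axes, indexing="ij")).reshape(4, -1).T

    best = _multistart(residual, lower, upper, starts)
    alpha, lam = best.x[0], best.x[1]
    eA, enA = (emissions_fixed if emissions_fixed is not None else (best.x[2], best.x[3]))

    # a flat curve carries no dynamics: flag the degenerate fit
    degenerate = bool(np.ptp(y) < 1e-12 and emissions_fixed is None)
    params = NEMAParams(
        WaldParams(1.0, 1.0), lapse_prob=min(lam, 1.0 - 1e-12),
        recapture_mean_delay=1.0, recapture_prob=alpha,
    )
    return FitResult(
        params=params,
        loss=2.0 * best.cost,
        residuals=best.fun,
        converged=bool(best.success) and not degenerate,
        n_restarts_used=len(starts),
        extra={"alpha": float(alpha), "lambda": float(lam),
               "emission_A": float(eA), "emission_notA": float(enA),
               "degenerate": degenerate},
    )
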