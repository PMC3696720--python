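"""Two-state attentional lapse/recapture model layered on the Wald core.

A trial starts in the attentive state A.  From one second to the next
attention lapses to the inattentive state ~A with probability ``lambda``;
a conspicuous target recaptures attention, at the cost of an extra
exponentially distributed delay with mean ``tau`` seconds.  After ``t``
seconds the probability of still being attentive is ``(1 - lambda)**t``,
so condition-wise response-time moments are those of a mixture of a Wald
(attentive trials) and an ex-Wald (lapsed trials, exponential delay plus
Wald):

    mean     = C/v + q * tau
    variance = C/v^3 + q * tau^2            (printed mode)
    variance = C/v^3 + tau^2 * q * (2 - q)  (exact mixture variance)

with q = 1 - (1 - lambda)**t and tau in ms inside the formulas.  The
"printed" variance is the form the source model states and is the
default; the "exact" mode carries the full mixture variance, which adds
the between-component term tau^2 * q * (1 - q).

When no target interrupts, attention drifts back spontaneously with
per-step probability ``alpha``.  The resulting two-state Markov chain has
transition matrix [[1-lambda, lambda], [alpha, 1-alpha]] over (A, ~A),
occupancy P(A at k) = pi_A + (1-lambda-alpha)^k (P(A at 0) - pi_A), and
steady state pi_A = alpha / (alpha + lambda).  Post-NOGO error dynamics
follow by attaching per-state error emission probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wald import WaldParams

__all__ = [
    "NEMAParams",
    "TransitionMatrix",
    "OccupancyTrace",
    "p_attentive",
    "nema_moments",
    "transition_matrix",
    "occupancy",
    "steady_state",
    "error_curve",
    "emission_for_asymptote",
]

VARIANCE_MODES = ("printed", "exact")


@dataclass(frozen=True)
class NEMAParams:
    """Drift core plus attentional dynamics.

    Attributes
    ----------
    wald : WaldParams
        Criterion C (steps) and speed v (steps/ms).
    lapse_prob : float
        Per-second probability lambda of lapsing A -> ~A, in [0, 1).
    recapture_mean_delay : float
        Mean tau (seconds) of the exponential extra delay on lapsed
        trials when a target recaptures attention.
    recapture_prob : float or None
        Optional per-step probability alpha of spontaneous ~A -> A
        recovery, for the free-running Markov chain.
    """

    wald: WaldParams
    lapse_prob: float
    recapture_mean_delay: float
    recapture_prob: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_prob < 1.0:
            raise ValueError(f"lapse_prob must lie in [0, 1), got {self.lapse_prob}")
        if not self.recapture_mean_delay > 0:
            raise ValueError(
                f"recapture_mean_delay must be positive, got {self.recapture_mean_delay}"
            )
        if self.recapture_prob is not None and not 0.0 <= self.recapture_prob <= 1.0:
            raise ValueError(f"recapture_prob must lie in [0, 1], got {self.recapture_prob}")

    def to_dict(self) -> dict:
        d = {
            "criterion": self.wald.criterion,
            "speed": self.wald.speed,
            "lambda_per_s": self.lapse_prob,
            "tau_s": self.recapture_mean_delay,
        }
        if self.recapture_prob is not None:
            d["alpha"] = self.recapture_prob
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NEMAParams":
        return cls(
            wald=WaldParams(float(d["criterion"]), float(d["speed"])),
            lapse_prob=float(d["lambda_per_s"]),
            recapture_mean_delay=float(d["tau_s"]),
            recapture_prob=float(d["alpha"]) if d.get("alpha") is not None else None,
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 2x2 matrix over the ordered states (A, ~A)."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (2, 2):
            raise ValueError(f"transition matrix must be 2x2, got shape {P.shape}")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition-matrix rows must each sum to 1")
        object.__setattr__(self, "P", P)

    @property
    def lapse_prob(self) -> float:
        return float(self.P[0, 1])

    @property
    def recapture_prob(self) -> float:
        return float(self.P[1, 0])


@dataclass(frozen=True)
class OccupancyTrace:
    """P(attentive) at each step k = 0..n of the free-running chain."""

    steps: np.ndarray
    p_attentive: np.ndarray

    def __iter__(self):
        return iter(zip(self.steps.tolist(), self.p_attentive.tolist()))


def p_attentive(lapse_prob: float, t) -> np.ndarray | float:
    """Probability (1 - lambda)**t of still being attentive after t seconds."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = (1.0 - lapse_prob) ** t
    return float(out) if out.ndim == 0 else out


def nema_moments(
    params: NEMAParams, t: float, variance_mode: str = "printed"
) -> tuple[float, float]:
    """Condition mean and SD (ms) at foreperiod ``t`` seconds.

    ``variance_mode="printed"`` uses var = C/v^3 + q tau^2; ``"exact"``
    uses the full mixture variance C/v^3 + tau^2 q (2 - q).  Both share
    the mean C/v + q tau.  tau enters in ms.
    """
    if variance_mode not in VARIANCE_MODES:
        raise ValueError(f"variance_mode must be one of {VARIANCE_MODES}, got {variance_mode!r}")
    C, v = params.wald.criterion, params.wald.speed
    q = 1.0 - p_attentive(params.lapse_prob, t)
    tau_ms = params.recapture_mean_delay * 1000.0
    mean = C / v + q * tau_ms
    var = C / v**3 + (q * tau_ms**2 if variance_mode == "printed" else tau_ms**2 * q * (2.0 - q))
    return mean, float(np.sqrt(var))


def transition_matrix(lapse_prob: float, recapture_prob: float) -> TransitionMatrix:
    """Build [[1-lambda, lambda], [alpha, 1-alpha]] over (A, ~A)."""
    for name, p in (("lapse_prob", lapse_prob), ("recapture_prob", recapture_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return TransitionMatrix(
        np.array([[1.0 - lapse_prob, lapse_prob], [recapture_prob, 1.0 - recapture_prob]])
    )


def _check_state(start: str) -> int:
    if start not in ("A", "~A"):
        raise ValueError(f"start state must be 'A' or '~A', got {start!r}")
    return 0 if start == "A" else 1


def occupancy(matrix: TransitionMatrix, start: str, n_steps: int) -> OccupancyTrace:
    """P(A) after k = 0..n_steps transitions, by repeated multiplication.

    Equals the closed form pi_A + (1-lambda-alpha)^k (1{start=A} - pi_A).
    """
    if n_steps < 0:
        raise ValueError(f"n_steps must be >= 0, got {n_steps}")
    i = _check_state(start)
    dist = np.zeros(2)
    dist[i] = 1.0
    probs = np.empty(n_steps + 1)
    probs[0] = dist[0]
    for k in range(1, n_steps + 1):
        dist = dist @ matrix.P
        probs[k] = dist[0]
    return OccupancyTrace(steps=np.arange(n_steps + 1), p_attentive=probs)


def steady_state(lapse_prob: float, recapture_prob: float) -> float:
    """Long-run probability of being attentive: alpha / (alpha + lambda)."""
    if lapse_prob + recapture_prob <= 0.0:
        raise ValueError("degenerate chain: lapse_prob + recapture_prob must be > 0")
    return recapture_prob / (recapture_prob + lapse_prob)


def error_curve(
    lapse_prob: float,
    recapture_prob: float,
    emission_A: float,
    emission_notA: float,
    n_trials: int,
    start: str = "~A",
) -> np.ndarray:
    """Commission-error probability on trials 1..n after a NOGO event.

    The NOGO trial throws the observer into ~A (the default start); on
    each later trial the error probability is the state-occupancy mixture
    P(A at k) * emission_A + P(~A at k) * emission_notA, converging to
    the asymptote emission_A * pi_A + emission_notA * (1 - pi_A).
    """
    for name, e in (("emission_A", emission_A), ("emission_notA", emission_notA)):
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {e}")
    trace = occupancy(transition_matrix(lapse_prob, recapture_prob), start, n_trials)
    pA = trace.p_attentive[1:]
    return emission_A * pA + emission_notA * (1.0 - pA)


def emission_for_asymptote(
    lapse_prob: float, recapture_prob: float, asymptote: float, emission_A: float = 0.0
) -> float:
    """Inattentive-state emission that yields a given error asymptote.

    Solves emission_A * pi_A + e * (1 - pi_A) = asymptote for e, with
    pi_A = alpha / (alpha + lambda).
    """
    pi_A = steady_state(lapse_prob, recapture_prob)
    if pi_A >= 1.0:
        raise ValueError("chain never visits the inattentive state; emission undefined")
    return (asymptote - emission_A * pi_A) / (1.0 - pi_A)
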