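"""Trial-level synthetic-data engine for the attentional drift model.

Two paradigms are generated:

* a slow foreperiod choice task: each trial starts attentive, attention
  may lapse during the 2-, 4- or 8-second wait, and the target then
  triggers either a plain Wald response (attentive) or an exponential
  recapture delay followed by a Wald response (lapsed);
* a fast-paced GO/NOGO session (SART-style): latent attention evolves as
  the two-state Markov chain between targets, GO responses slower than
  the deadline are omissions, and NOGO responses faster than the abort
  latency T_stop are commission errors.

These simulations are the fixture source for all parameter-recovery
tests: summaries of the logs feed straight back into the imputation and
fitting routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .attention import NEMAParams, p_attentive
from .imputation import ConditionStats, StopRule
from .wald import sample_wald

__all__ = [
    "TrialRecord",
    "SessionConfig",
    "simulate_foreperiod_task",
    "simulate_sart",
    "summarize",
]


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial.

    ``rt`` is None on omitted GO trials and on NOGO trials without a
    commission; ``commission`` can only be set on NOGO trials and
    ``omission`` only on GO trials.
    """

    condition: str
    foreperiod: float
    trial_type: str  # "GO" | "NOGO"
    latent_state_at_target: str  # "A" | "~A"
    rt: float | None
    commission: bool = False
    omission: bool = False

    def __post_init__(self) -> None:
        if self.trial_type not in ("GO", "NOGO"):
            raise ValueError(f"trial_type must be GO or NOGO, got {self.trial_type!r}")
        if self.commission and self.trial_type != "NOGO":
            raise ValueError("commission errors can only occur on NOGO trials")
        if self.omission and self.trial_type != "GO":
            raise ValueError("omission errors can only occur on GO trials")
        if self.rt is not None and not self.rt > 0:
            raise ValueError(f"rt must be positive when present, got {self.rt}")


@dataclass(frozen=True)
class SessionConfig:
    """GO/NOGO session layout.

    ``pacing`` is the seconds between successive targets; the latent
    attentional state takes one Markov step per whole second of it.
    """

    n_trials: int
    nogo_fraction: float
    response_deadline: float  # ms; may be math.inf
    stop: StopRule
    pacing: float = 1.0
    seed: int = 0
    reset_after_nogo: bool = False  # throw state to ~A after every NOGO trial

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError(f"n_trials must be >= 0, got {self.n_trials}")
        if not 0.0 <= self.nogo_fraction <= 1.0:
            raise ValueError(f"nogo_fraction must lie in [0, 1], got {self.nogo_fraction}")
        if not self.response_deadline > 0:
            raise ValueError(f"response_deadline must be positive, got {self.response_deadline}")
        if self.pacing < 0:
            raise ValueError(f"pacing must be >= 0, got {self.pacing}")


def simulate_foreperiod_task(
    params: NEMAParams,
    foreperiods: list[float],
    n_per_condition: int,
    seed: int,
) -> list[TrialRecord]:
    """Simulate the slow choice task, one condition per foreperiod.

    Each trial restarts in the attentive state; by target onset the
    participant has lapsed with probability 1 - (1-lambda)**t.  Lapsed
    trials pay an exponential recapture delay (mean tau) before the Wald
    accumulation runs — the stimulus-driven recapture regime, with
    recapture at target presentation taken as certain.
    """
    if n_per_condition < 1:
        raise ValueError(f"n_per_condition must be >= 1, got {n_per_condition}")
    if not foreperiods:
        raise ValueError("foreperiods must be a nonempty list")
    rng = np.random.default_rng(seed)
    tau_ms = params.recapture_mean_delay * 1000.0
    records: list[TrialRecord] = []
    for t in foreperiods:
        q = 1.0 - p_attentive(params.lapse_prob, t)
        lapsed = rng.random(n_per_condition) < q
        rts = sample_wald(params.wald, n_per_condition, rng)
        delays = rng.exponential(tau_ms, n_per_condition)
        rts = rts + np.where(lapsed, delays, 0.0)
        label = f"fp{t:g}s"
        for i in range(n_per_condition):
            records.append(
                TrialRecord(
                    condition=label,
                    foreperiod=float(t),
                    trial_type="GO",
                    latent_state_at_target="~A" if lapsed[i] else "A",
                    rt=float(rts[i]),
                )
            )
    return records


def _markov_steps(state: int, lam: float, alpha: float, n: int, rng) -> int:
    """Advance the (A=0, ~A=1) chain by n one-second steps."""
    for _ in range(n):
        u = rng.random()
        if state == 0:
            state = 1 if u < lam else 0
        else:
            state = 0 if u < alpha else 1
    return state


def simulate_sart(params: NEMAParams, config: SessionConfig) -> list[TrialRecord]:
    """Simulate a GO/NOGO session with carry-over attentional state.

    Between targets the latent state takes one Markov step per whole
    second of pacing (spontaneous recapture probability alpha, 0 when
    unset: the stimulus-driven regime).  At a target, a lapsed
    participant pays the exponential recapture delay before the
    accumulation runs and is attentive again afterwards.  NOGO trials
    register a commission iff the (delay +) passage time beats T_stop;
    GO trials register an omission iff it exceeds the deadline.
    """
    rng = np.random.default_rng(config.seed)
    lam = params.lapse_prob
    alpha = params.recapture_prob if params.recapture_prob is not None else 0.0
    tau_ms = params.recapture_mean_delay * 1000.0
    n_steps = int(math.floor(config.pacing))
    frac = config.pacing - n_steps
    records: list[TrialRecord] = []
    state = 0  # start attentive
    for _ in range(config.n_trials):
        state = _markov_steps(state, lam, alpha, n_steps, rng)
        if frac > 0:  # fractional second: scaled transition probabilities
            lam_f = 1.0 - (1.0 - lam) ** frac
            alpha_f = 1.0 - (1.0 - alpha) ** frac
            u = rng.random()
            if state == 0:
                state = 1 if u < lam_f else 0
            else:
                state = 0 if u < alpha_f else 1
        is_nogo = rng.random() < config.nogo_fraction
        lapsed = state == 1
        passage = float(sample_wald(params.wald, 1, rng)[0])
        total = passage + (rng.exponential(tau_ms) if lapsed else 0.0)
        latent = "~A" if lapsed else "A"
        if is_nogo:
            commission = total < config.stop.t_stop
            records.append(
                TrialRecord(
                    condition="sart", foreperiod=config.pacing, trial_type="NOGO",
                    latent_state_at_target=latent,
                    rt=total if commission else None, commission=bool(commission),
                )
            )
            state = 1 if config.reset_after_nogo else state
        else:
            omission = total > config.response_deadline
            records.append(
                TrialRecord(
                    condition="sart", foreperiod=config.pacing, trial_type="GO",
                    latent_state_at_target=latent,
                    rt=None if omission else total, omission=bool(omission),
                )
            )
            if lapsed:
                state = 0  # target-driven recapture after responding
    return records


def summarize(trials: list[TrialRecord]) -> list[ConditionStats]:
    """Condition-wise summaries suitable for imputation or fitting.

    Per condition: mean and SD of completed GO response times (omissions
    excluded), commission rate among NOGO trials, and GO count.  A
    condition without at least two completed GO trials cannot yield an
    SD; its row is flagged rather than silently dropped, and downstream
    estimation refuses flagged rows.
    """
    if not trials:
        raise ValueError("trial list is empty")
    by_cond: dict[str, list[TrialRecord]] = {}
    for tr in trials:
        by_cond.setdefault(tr.condition, []).append(tr)
    out = []
    for label, recs in by_cond.items():
        go_rts = np.array([r.rt for r in recs if r.trial_type == "GO" and r.rt is not None])
        nogo = [r for r in recs if r.trial_type == "NOGO"]
        fp = sum(r.commission for r in nogo) / len(nogo) if nogo else None
        if go_rts.size == 0:
            out.append(
                ConditionStats(
                    label=label, mean_rt=None, foreperiod=recs[0].foreperiod,
                    fp_observed=fp, n=0, flag="no completed GO trials",
                )
            )
        elif go_rts.size == 1:
            out.append(
                ConditionStats(
                    label=label, mean_rt=float(go_rts[0]),
                    foreperiod=recs[0].foreperiod, fp_observed=fp, n=1,
                    flag="SD undefined with a single completed GO trial",
                )
            )
        else:
            out.append(
                ConditionStats(
                    label=label,
                    mean_rt=float(go_rts.mean()),
                    sd_rt=float(go_rts.std(ddof=1)),
                    foreperiod=recs[0].foreperiod,
                    fp_observed=fp,
                    n=int(go_rts.size),
                )
            )
    return out
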