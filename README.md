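# nema

Response-time modelling for sustained-attention tasks: a Wald
(inverse-Gaussian) first-passage drift core, with a two-state Markov
layer for attentional lapses and recapture.

The package is for researchers who have condition-level response-time
summaries — a mean, an SD or coefficient of variation, perhaps a
commission-error rate — from paradigms like the SART (a fast GO/NOGO
task where one rare digit must be withheld) or slow foreperiod choice
tasks, and who want to recode those statistics into process parameters.

## The model

A response is the first passage of a drifting accumulation: `v` net
computation steps per millisecond toward a criterion `C` steps away.
First-passage times are then Wald-distributed,

    f(t) = C / √(2πt³) · exp(−(C − vt)² / 2t),

with mean `C/v`, SD `√(C/v³)`, and cv `(Cv)^(−1/2)`.  From a reported
mean μ and SD σ the parameters are imputed by moment matching:
`v = √μ/σ`, `C = μv`.  Commission errors on NOGO trials are responses
that complete before the abort latency `T_stop`, predicted by the Wald
CDF at `T_stop`.

For slowly paced tasks, a two-state Markov chain over attentive (A) and
inattentive (~A) states is layered on top: per-second lapse probability
λ, recapture probability α (steady state `α/(α+λ)` attentive), and a
mean recapture delay τ paid when a target arrives during a lapse.
Condition moments become `μ = C/v + qτ` and `σ² = C/v³ + qτ²` with
`q = 1 − (1−λ)^t` at foreperiod `t` — the first two moments of a
Wald / ex-Wald mixture (see `docs/methods.md` for the exact-variance
variant).  The library imputes and fits these parameters, predicts and
inverts commission rates, computes occupancy and post-error curves, and
simulates trial-level data for both paradigms.

## Worked example

Two groups ran a fast GO/NOGO task; the file `groups.csv` holds their
summaries:

```
label,mean_ms,sd_ms,cv,foreperiod_s,fp_observed,n
adults,550,,0.19,0,0.12,20
adolescents,520,,0.26,0,0.32,20
```

Impute drift parameters and predict commission rates for a 440-ms abort
latency:

```
$ nema impute groups.csv --stop-ms 440 -o groups_out.csv
adults: C=123 v=0.224 FP_pred=14%
adolescents: C=88 v=0.169 FP_pred=30%
```

Adults accumulate faster (v = 0.224 vs 0.169 steps/ms) and hold a
higher response criterion (123 vs 88 steps) — less impulsive responding.
Racing each group's passage-time distribution against the same 440-ms
abort process predicts commission rates of 14% and 30%, close to the
observed 12% and 32%.  The same numbers are available in code:

```python
from nema import ConditionStats, StopRule, impute_params, predict_fp

adults = impute_params(ConditionStats("adults", 550, cv=0.19))
print(round(adults.criterion), round(adults.speed, 3))   # 123 0.224
print(round(100 * predict_fp(adults, StopRule(440))))    # 14
```

With the lapse layer, the fitted ADHD parameter row from a slow
foreperiod task (C=79, v=0.104, λ=0.108, τ=0.43 s) predicts the
8-second condition's moments:

```
$ nema nema-moments -C 79 -v 0.104 --lambda 0.108 --tau 0.43 -t 8
mean_ms=1017.27 sd_ms=425.47
```

i.e. a 760-ms drift core slowed by ~257 ms because the participant has
lapsed by target onset on `1 − 0.892⁸ ≈ 60%` of trials and then pays
the 430-ms average recapture delay.  Other subcommands: `fit` (recover
(C, v, λ, τ) from a condition table), `fit-error-chain`, `markov-curve`,
`predict-fp`, `simulate` (trial-level synthetic sessions).

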