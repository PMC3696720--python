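# Methods

## The drift core

A single response is modelled as the first passage of a biased random
walk: evidence drifts toward a response criterion `C` (computation
steps) at net speed `v` (steps per ms), with unit diffusion per ms.  The
first-passage time is Wald-distributed — an inverse Gaussian with mean
`C/v` and shape `C²` — with density

```
f(t) = C / sqrt(2 π t³) · exp(−(C − v t)² / (2 t)),   t > 0,
```

mean `C/v`, SD `sqrt(C/v³)`, coefficient of variation `(Cv)^(−1/2)`, and
skewness `3 (Cv)^(−1/2)`.  `v` is interpreted as the energy available to
the responding circuit; fatigue lowers `v`, which raises the mean and
raises the SD even faster (halving `v` doubles the mean and multiplies
the SD by `2√2`).  That asymmetry is why RT variability is the more
sensitive marker of slowed processing.

**Numerical evaluation.**  The CDF is

```
F(t) = Φ((vt − C)/√t) + exp(2Cv) · Φ(−(vt + C)/√t).
```

`2Cv` exceeds 50 for realistic parameters, so the second term is
computed as `exp(2Cv + logΦ(·))` via `scipy.special.log_ndtr`; the naive
product overflows double precision.  The quantile function brackets the
root geometrically around the mean and solves with Brent's method to
1e−12 in time (well below 1e−9 in probability).  Sampling uses the
Michael–Schucany–Haas transformation on the (mean = C/v, shape = C²)
parameterisation.  `scipy.stats.invgauss` is used in the test suite as
an independent cross-check of the CDF, never as the implementation.

**Discrete-walk oracle.**  `random_walk_first_passage` simulates ±1
steps at 1 step/ms with up-probability `p`, giving drift `v = 2p − 1`
but variance per step `1 − v²` rather than 1.  Its mean first passage is
exactly `C/v` (Wald's identity), while its spread is slightly narrower
than the continuum Wald.  The walk is therefore held to a 2% tolerance
on the mean and a location test against the continuum sampler, and is
not rescaled to match exactly; the two constructions are both kept as
stated.  Up-probabilities ≤ 0.5 are rejected: without positive drift the
passage distribution is defective.

## Imputation and the stop-time race

Given a reported mean μ and SD σ (or cv, with σ = cv·μ), the unique
Wald parameters reproducing both moments are

```
v = √μ / σ,      C = μ · v.
```

(The equivalent form `v = √(μ/σ²)` makes the dimensional bookkeeping
explicit.)  Imputation is exact by construction: feeding the closed-form
moments back recovers (C, v) to machine precision.

Commission errors on NOGO trials arise from a race against a fixed
abort latency `T_stop` (ms): any accumulation that completes before the
abort process slips through, so the predicted commission rate is
`F(T_stop)` and an observed rate inverts to `T_stop` through the
quantile function.  Reported values follow the field's display
conventions — C to the nearest integer, v to 3 decimals, rates as
integer percentages — while everything internal is a fraction.

## The attentional layer

Fast-paced tasks leave little room for frank lapses, but slow foreperiod
tasks do.  The model adds a two-state Markov chain over attentive (A)
and inattentive (~A) states.  During a foreperiod of `t` seconds the
probability of remaining attentive is `p(A) = (1 − λ)^t` with λ the
per-second lapse probability (continuous `t` is allowed; the law extends
naturally).  A target arriving during a lapse recaptures attention at
the cost of an exponential delay with mean τ seconds, so the RT
distribution is a mixture of a Wald (weight `1 − q`) and an ex-Wald
(weight `q = 1 − p(A)`), with

```
mean = C/v + q·τ
var  = C/v³ + q·τ²              ("printed" mode, default)
var  = C/v³ + τ²·q·(2 − q)      ("exact" mode)
```

(τ in ms inside the formulas; parameters are stored in the task's
natural units, λ per second and τ in seconds, and converted only here.)
The printed form is the variance expression the model is usually quoted
with; it omits the between-component term `τ²·q·(1 − q)` of the stated
mixture.  Both are implemented behind an explicit `variance_mode`
switch; the printed form is the default so that published parameter
tables reproduce, and the exact form is what trial-level simulation
converges to.  Fitting printed-mode equations to exact-mode data biases
τ upward — a property the suite asserts.

Free-running attention (no targets) evolves by the transition matrix

```
P = | 1−λ   λ  |
    |  α   1−α |
```

over (A, ~A), with per-step recapture probability α.  Occupancy after
k steps is `π_A + (1−λ−α)^k (1{start=A} − π_A)` with steady state
`π_A = α/(α+λ)`; the implementation iterates the matrix product and the
suite checks it against the closed form to 1e−12.  Post-NOGO error
dynamics assume the rare NOGO event throws the observer into ~A; the
error probability on trial k after it is the occupancy mixture of two
per-state emission probabilities.  The mapping from occupancy to error
rate is not pinned down by steady-state considerations alone (the
long-run P(~A) of the published chains is ≈0.69 while the error
asymptote is 0.32), so emissions are free parameters with a calibration
helper `emission_for_asymptote` rather than fixed constants.

α and τ describe the same recovery process at different grains: τ is
approximately the mean return time when recapture is checked once per
second with probability α.  No exact conversion is imposed; both are
carried, and the simulator uses τ for stimulus-driven recapture and α
for spontaneous recovery between targets.

## Fitting

`fit_nema` minimises the unweighted SSE over condition means and SDs
jointly (both in ms, hence commensurate; no likelihood or weighting
scheme is imposed) over (C, v, λ, τ) within bounds C ∈ [1, 500],
v ∈ [0.01, 1], λ ∈ [0, 0.5], τ ∈ [0.01, 5] s — wide margins around all
published values.  Optimisation is bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) launched from a fixed 3×3×3×3
interior grid plus one moment-matching warm start; the best final loss
wins, ties to first found.  There is no randomness anywhere in fitting,
so refits are byte-reproducible.  At least two distinct foreperiods are
required (four unknowns, two moments each); fewer raises an explicit
under-determined error.  `fit_error_chain` does the same for (α, λ) —
and optionally the two emissions — against an observed post-NOGO error
sequence, flagging flat sequences as degenerate (a constant curve
carries no dynamics).

**Identifiability.**  Noiseless moments are inverted essentially
exactly (loss < 1e−10, parameters to ≤1e−4 relative).  Under noise the
2/4/8-s three-foreperiod design identifies C and v well (delta-method
relative SE ≈ 5% at 2% moment noise) and τ moderately (≈17%), but λ and
τ trade off along a ridge that leaves λ with relative SE ≈ 55%.  This
is a property of the design, not of the optimizer: across noisy
replicates the fitted loss never exceeds the loss at the generating
truth.  The recovery suite asserts tight medians for C, v, τ and only a
scale bound for λ.  Users fitting real three-condition data should
treat fitted λ as order-of-magnitude information unless more
foreperiods (or longer ones) are available.

## The simulator

`simulate_foreperiod_task` emulates a slow choice task: every trial
restarts attentive (no inter-trial carry-over; whether lapses continue
through the inter-trial interval is left out by this convention), lapses
by target onset with probability `1 − (1−λ)^t`, and pays the exponential
recapture delay when lapsed — stimulus-driven recapture idealised to
certainty, with the delay carrying the entire cost.  Sample moments
converge to the exact-mode closed forms, which is the dual-route check
the suite runs at n = 50 000 per condition (3-SE tolerances; SD compared
with a skew allowance).

`simulate_sart` emulates a paced GO/NOGO session: the latent state takes
one Markov step per whole second of pacing (fractional seconds use the
power-law-scaled probabilities), NOGO responses faster than `T_stop` are
commissions, GO responses beyond the deadline are omissions, and a
lapsed participant pays the recapture delay and returns to A after
responding.  Lapsed NOGO trials can in principle produce commissions but
almost never do (delay + passage rarely beats `T_stop`), matching the
reading that inattentive observers are effectively blind to the rare
stimulus.  An optional `reset_after_nogo` flag throws the state to ~A
after every NOGO trial, enabling post-error dynamics of the error-curve
kind; it is off by default so that the pure drift-core commission
prediction holds exactly.

Synthetic data emulate the *model's* data-generating process.  They do
not emulate response-key confusions, stimulus identity, fatigue drift in
v across a session, anticipations, or censoring by the response window —
so passing recovery tests demonstrates internal consistency of
estimation, not that real SART data satisfy the model.

## Problem sizes and tolerances

Defaults used by the test suite and worked examples, chosen as the
smallest sizes at which Monte-Carlo error is far below the assertion
tolerances: 50 000 trials per condition for moment checks and
end-to-end recovery (3 SE), 20 000 walks for the discrete oracle (2% on
a mean of 225 ms), 40 fixed-seed replicates for the noisy-recovery
study.  Quantile inversion is tolerated at 1e−8 in probability,
occupancy closed-form agreement at 1e−12, and printed-table
reproduction at the tables' own display precision (integer C, 3-decimal
v, integer percent).  One printed value differs from the computation in
the last digit: the adult group's speed computes to 0.2244 but is
printed as 0.223, consistent with truncation rather than rounding;
the package reports 0.224 and the tests hold it to ±0.001.
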