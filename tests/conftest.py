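import hypothesis
import pytest

from nema import ConditionStats, NEMAParams, WaldParams, impute_params

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

# Group summaries from a fast-paced GO/NOGO study of adults vs adolescents:
# mean RT (ms), coefficient of variation, observed commission rate.
ADULTS = dict(label="adults", mean_rt=550.0, cv=0.19, fp_observed=0.12)
ADOLESCENTS = dict(label="adolescents", mean_rt=520.0, cv=0.26, fp_observed=0.32)

# Fitted lapse-model parameter rows for a slow foreperiod choice task
# (ADHD children vs controls): C, v, lambda (per s), tau (s).
ADHD_ROW = dict(criterion=79.0, speed=0.104, lapse_prob=0.108, recapture_mean_delay=0.43)
CONTROL_ROW = dict(criterion=115.0, speed=0.194, lapse_prob=0.091, recapture_mean_delay=0.19)

# Markov-chain rows fit to post-NOGO error dynamics: alpha, lambda,
# conditional on a correct (E|C) vs erroneous (E|E) prior NOGO trial.
CHAIN_PRIOR_CORRECT = dict(recapture_prob=0.115, lapse_prob=0.258)
CHAIN_PRIOR_ERROR = dict(recapture_prob=0.046, lapse_prob=0.095)


@pytest.fixture
def adults_stats() -> ConditionStats:
    return ConditionStats(**ADULTS)


@pytest.fixture
def adolescents_stats() -> ConditionStats:
    return ConditionStats(**ADOLESCENTS)


@pytest.fixture
def adults_params(adults_stats) -> WaldParams:
    return impute_params(adults_stats)


@pytest.fixture
def adolescents_params(adolescents_stats) -> WaldParams:
    return impute_params(adolescents_stats)


def nema_params(row: dict) -> NEMAParams:
    return NEMAParams(
        wald=WaldParams(row["criterion"], row["speed"]),
        lapse_prob=row["lapse_prob"],
        recapture_mean_delay=row["recapture_mean_delay"],
    )


@pytest.fixture
def adhd_params() -> NEMAParams:
    return nema_params(ADHD_ROW)


@pytest.fixture
def control_params() -> NEMAParams:
    return nema_params(CONTROL_ROW)
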