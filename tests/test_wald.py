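"""Wald first-passage distribution: density, CDF, quantile, moments,
sampler, and the discrete random-walk oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import invgauss, ttest_ind

from nema import (
    WaldParams,
    random_walk_first_passage,
    sample_wald,
    wald_cdf,
    wald_moments,
    wald_pdf,
    wald_quantile,
)

params_st = st.builds(
    WaldParams,
    criterion=st.floats(5.0, 400.0),
    speed=st.floats(0.02, 0.9),
)


class TestParams:
    @pytest.mark.parametrize("C,v", [(0, 0.2), (-5, 0.2), (75, 0), (75, -1), (np.inf, 0.2)])
    def test_invalid_parameters_rejected(self, C, v):
        with pytest.raises(ValueError):
            WaldParams(C, v)

    def test_json_round_trip(self):
        p = WaldParams(123.4, 0.224)
        assert WaldParams.from_dict(p.to_dict()) == p


class TestPdf:
    @pytest.mark.parametrize(
        "C,v", [(75, 1 / 3), (123.43, 0.2244), (10, 0.1), (200, 0.9), (2, 0.5)]
    )
    def test_density_integrates_to_one(self, C, v):
        p = WaldParams(C, v)
        # split at the mean so quad cannot step over a narrow peak
        left, _ = quad(lambda t: wald_pdf(p, t), 1e-12, p.mean, limit=200)
        right, _ = quad(lambda t: wald_pdf(p, t), p.mean, np.inf, limit=200)
        assert left + right == pytest.approx(1.0, abs=1e-6)

    def test_mean_by_integration_matches_c_over_v(self):
        p = WaldParams(123.0, 0.223)
        m, _ = quad(lambda t: t * wald_pdf(p, t), 1e-12, np.inf, limit=200)
        assert m == pytest.approx(123.0 / 0.223, rel=1e-6)
        # consistent with a reported group mean of about 550 ms
        assert m == pytest.approx(550, abs=3)

    def test_density_vanishes_at_origin(self):
        p = WaldParams(75, 1 / 3)
        assert wald_pdf(p, 1e-9) == 0.0

    def test_nonpositive_time_rejected(self):
        p = WaldParams(75, 1 / 3)
        for t in (0.0, -1.0):
            with pytest.raises(ValueError):
                wald_pdf(p, t)
            with pytest.raises(ValueError):
                wald_cdf(p, t)


class TestCdf:
    def test_matches_reference_inverse_gaussian(self):
        # independent route: scipy's inverse Gaussian with mean C/v, shape C^2
        p = WaldParams(123.43, 0.2244)
        mu, lam = p.mean, p.criterion**2
        for t in [200.0, 440.0, 551.6, 900.0]:
            assert wald_cdf(p, t) == pytest.approx(
                invgauss.cdf(t, mu / lam, scale=lam), abs=1e-12
            )

    def test_commission_window_probabilities(self, adults_params, adolescents_params):
        # probability of completing before a 440-ms abort deadline
        assert round(100 * wald_cdf(adults_params, 440.0)) == 14
        assert round(100 * wald_cdf(adolescents_params, 440.0)) == 30

    def test_no_overflow_at_large_drift(self):
        # 2Cv ~ 360 here; the naive exp(2Cv) term overflows double precision
        p = WaldParams(400, 0.45)
        val = wald_cdf(p, p.mean * 0.5)
        assert np.isfinite(val) and 0 < val < 1

    def test_strictly_increasing(self):
        p = WaldParams(88, 0.169)
        ts = np.linspace(100, 2000, 200)
        assert np.all(np.diff(wald_cdf(p, ts)) > 0)

    def test_limits(self):
        p = WaldParams(88, 0.169)
        assert wald_cdf(p, 1e-6) < 1e-12
        assert wald_cdf(p, 1e7) == pytest.approx(1.0, abs=1e-12)

    def test_higher_criterion_thins_fast_tail(self):
        v = 0.2
        cdfs = [wald_cdf(WaldParams(C, v), 440.0) for C in (60, 90, 123, 200)]
        assert np.all(np.diff(cdfs) < 0)

    @given(params_st)
    def test_derivative_matches_density(self, p):
        # five-point stencil keeps truncation error below the tolerance
        m = p.mean
        ts = np.linspace(0.2 * m, 3 * m, 7)
        h = 1e-3 * m
        num = (
            -wald_cdf(p, ts + 2 * h) + 8 * wald_cdf(p, ts + h)
            - 8 * wald_cdf(p, ts - h) + wald_cdf(p, ts - 2 * h)
        ) / (12 * h)
        assert num == pytest.approx(wald_pdf(p, ts), rel=1e-6, abs=1e-12)


class TestQuantile:
    @pytest.mark.parametrize("prob", [0.1, 0.5, 0.9])
    def test_cdf_quantile_round_trip(self, prob):
        p = WaldParams(123.43, 0.2244)
        assert wald_cdf(p, wald_quantile(p, prob)) == pytest.approx(prob, abs=1e-8)

    def test_time_round_trip(self):
        p = WaldParams(88, 0.169)
        assert wald_quantile(p, float(wald_cdf(p, 300.0))) == pytest.approx(300.0, abs=1e-6)

    def test_median_below_mean_right_skew(self):
        p = WaldParams(123, 0.2244)
        assert wald_quantile(p, 0.5) < p.mean

    def test_adolescent_commission_rate_inverts_to_stop_time(self, adolescents_params):
        fp = float(wald_cdf(adolescents_params, 440.0))
        assert wald_quantile(adolescents_params, fp) == pytest.approx(440.0, abs=1e-6)

    @pytest.mark.parametrize("prob", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_probability_rejected(self, prob):
        with pytest.raises(ValueError):
            wald_quantile(WaldParams(75, 1 / 3), prob)


class TestMoments:
    def test_closed_forms(self):
        C, v = 123.0, 0.2244
        mean, sd, cv, skew = wald_moments(WaldParams(C, v))
        assert mean == pytest.approx(C / v)
        assert sd == pytest.approx(np.sqrt(C / v**3))
        assert cv == pytest.approx(1 / np.sqrt(C * v))
        assert mean == pytest.approx(548.1, abs=1)
        assert cv == pytest.approx(0.190, abs=0.002)

    def test_halving_speed_doubles_mean_and_inflates_sd(self):
        m1, s1, *_ = wald_moments(WaldParams(100, 0.3))
        m2, s2, *_ = wald_moments(WaldParams(100, 0.15))
        assert m2 == pytest.approx(2 * m1)
        assert s2 == pytest.approx(2 * np.sqrt(2) * s1)

    @given(params_st)
    def test_skewness_is_three_times_cv(self, p):
        _, _, cv, skew = wald_moments(p)
        assert skew == pytest.approx(3 * cv, rel=1e-12)


class TestSampler:
    def test_moments_within_monte_carlo_error(self):
        p = WaldParams(123.0, 0.2244)
        n = 100_000
        x = sample_wald(p, n, seed=42)
        mean, sd, *_ = wald_moments(p)
        assert x.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(n))
        assert mean == pytest.approx(548.1, abs=1)

    def test_empirical_cdf_matches_analytic(self):
        p = WaldParams(123.0, 0.2244)
        n = 100_000
        x = sample_wald(p, n, seed=7)
        target = float(wald_cdf(p, 440.0))
        se = np.sqrt(target * (1 - target) / n)
        assert (x < 440.0).mean() == pytest.approx(target, abs=3 * se)

    def test_seed_determinism(self):
        p = WaldParams(88, 0.169)
        assert np.array_equal(sample_wald(p, 1000, seed=3), sample_wald(p, 1000, seed=3))

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            sample_wald(WaldParams(75, 1 / 3), 0, seed=1)


class TestRandomWalkOracle:
    def test_mean_first_passage_matches_wald(self):
        # criterion 75, up-step probability 2/3 => drift 1/3, mean 225 ms
        t = random_walk_first_passage(75, 2 / 3, 20_000, seed=11)
        assert t.mean() == pytest.approx(225.0, rel=0.02)

    def test_tails_are_populated(self):
        t = random_walk_first_passage(75, 2 / 3, 20_000, seed=11)
        assert (t < 150).mean() > 0.005  # fast passages near 100 ms exist
        assert (t > 400).sum() > 0  # and occasional very slow ones

    def test_location_agrees_with_continuum_sampler(self):
        # the walk's variance per step is 1 - v^2, so only location is compared
        walk = random_walk_first_passage(75, 2 / 3, 20_000, seed=13)
        cont = sample_wald(WaldParams(75, 1 / 3), 20_000, seed=13)
        assert ttest_ind(walk, cont, equal_var=False).pvalue > 1e-3

    def test_deterministic_walk_hits_exactly_at_criterion(self):
        t = random_walk_first_passage(75, 1.0, 50, seed=1)
        assert np.all(t == 75.0)

    @pytest.mark.parametrize("p", [0.5, 0.3, 0.0, 1.2])
    def test_nonpositive_drift_rejected(self, p):
        with pytest.raises(ValueError):
            random_walk_first_passage(75, p, 10, seed=1)

    def test_fractional_criterion_rejected(self):
        with pytest.raises(ValueError):
            random_walk_first_passage(75.5, 2 / 3, 10, seed=1)
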