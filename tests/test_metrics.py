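"""Divergences, decoding, psychometric fits and reward quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spikinghm.metrics import (
    FitFailure,
    Histogram2D,
    LogisticFit,
    RewardSpec,
    decode_position,
    fit_logistic,
    iqr_keep_mask,
    js_divergence,
    match_test,
    mean_deviation,
    optimal_threshold,
    r_logistic,
    reward_analysis,
)


class TestHistogram:
    def test_mass_is_normalised(self, rng):
        h = Histogram2D.from_samples(rng.uniform(0, 60, size=(500, 2)))
        assert h.mass.sum() == pytest.approx(1.0)

    def test_out_of_range_samples_clipped_into_edge_bins(self):
        h = Histogram2D.from_samples(np.array([[100.0, 100.0], [30.0, 30.0]]))
        assert h.mass.sum() == pytest.approx(1.0)
        assert h.mass[-1, -1] == pytest.approx(0.5)

    def test_known_truncated_gaussian_close_to_analytic_histogram(self, rng):
        # diagonal covariance: analytic bin mass is a product of 1-D CDFs
        mu, sd = 30.0, 5.0
        samples = np.maximum(rng.normal(mu, sd, size=(100_000, 2)), 0.0)
        h = Histogram2D.from_samples(samples)
        edges = np.linspace(0, 60, 41)
        cdf = stats.norm.cdf(edges, mu, sd)
        m1 = np.diff(cdf) / (cdf[-1] - cdf[0])
        analytic = Histogram2D(mass=np.outer(m1, m1))
        assert js_divergence(h, analytic) < 0.02


class TestJSDivergence:
    def test_identical_distributions_give_zero(self, rng):
        h = Histogram2D.from_samples(rng.uniform(0, 60, size=(300, 2)))
        assert js_divergence(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        a = np.zeros((40, 40)); a[0, 0] = 1.0
        b = np.zeros((40, 40)); b[-1, -1] = 1.0
        assert js_divergence(a, b) == pytest.approx(1.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_symmetric_bounded_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        p = r.random((40, 40)); p /= p.sum()
        q = r.random((40, 40)); q /= q.sum()
        d = js_divergence(p, q)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(js_divergence(q, p), rel=1e-9)

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError):
            js_divergence(np.ones((40, 40)), np.ones((40, 40)))


class TestMatchTest:
    def test_self_samples_match_perfectly(self, rng):
        data = {
            "a": rng.normal([20, 20], 3, size=(2000, 2)).clip(0),
            "b": rng.normal([45, 45], 3, size=(2000, 2)).clip(0),
        }
        inst = [{n: data[n][:1000] for n in data}]
        res = match_test(inst, data)
        assert res["matches"].all()
        assert res["confusion"].trace() == 2
        # each confusion row sums to the number of instances
        assert np.all(res["confusion"].sum(axis=1) == 1)

    def test_requires_two_candidates(self):
        with pytest.raises(ValueError):
            match_test([], {"a": np.ones((5, 2))})


class TestDecoding:
    def test_decoding_line_endpoints(self):
        assert decode_position([15.0, 15.0], "decoding") == pytest.approx(0.0)
        assert decode_position([30.0, 30.0], "decoding") == pytest.approx(1.0)

    def test_reward_antisymmetry_and_reference_point(self):
        assert decode_position([20.0, 20.0], "reward") == pytest.approx(0.0)
        assert decode_position([0.0, 25.0], "reward") == pytest.approx(1.0)

    def test_mean_deviation_identity_and_offset(self, rng):
        C = rng.uniform(0, 1, 100)
        assert mean_deviation(C, C) == 0.0
        assert mean_deviation(C + 0.25, C) == pytest.approx(0.25)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_deviation([], [])


class TestLogisticFit:
    def test_simulation_recovery(self, rng):
        mu0, s0 = 0.2, 0.1
        C = rng.uniform(-1, 1, 2000)
        resp = rng.random(2000) < 1.0 / (1.0 + np.exp(-(C - mu0) / s0))
        fit = fit_logistic(C, resp)
        assert abs(fit.mu - mu0) < 0.03
        assert abs(fit.s - s0) / s0 < 0.2

    def test_symmetric_responses_give_zero_threshold(self, rng):
        C = rng.uniform(-1, 1, 3000)
        resp = rng.random(3000) < 1.0 / (1.0 + np.exp(-C / 0.2))
        assert abs(fit_logistic(C, resp).mu) < 0.03

    def test_steeper_curve_yields_smaller_scale(self, rng):
        C = rng.uniform(-1, 1, 3000)
        fits = []
        for s0 in (0.3, 0.1):
            resp = rng.random(3000) < 1.0 / (1.0 + np.exp(-C / s0))
            fits.append(fit_logistic(C, resp).s)
        assert fits[1] < fits[0]

    def test_separation_raises(self):
        C = np.array([-0.5, -0.4, 0.4, 0.5])
        with pytest.raises(FitFailure):
            fit_logistic(C, C > 0)
        with pytest.raises(FitFailure):
            fit_logistic(C, np.ones(4, dtype=bool))


class TestReward:
    def test_equal_rewards_have_zero_optimal_threshold(self):
        assert abs(optimal_threshold(0.1, 0.5, 0.5)) < 1e-3

    def test_noiseless_limit_approaches_half(self):
        assert r_logistic(0.0, 1e-4, 0.5, 0.5) == pytest.approx(0.5, abs=1e-3)

    def test_minimum_reward_formula(self):
        res = reward_analysis(
            np.array([1.0, -1.0]), np.array([0.5, -0.5]),
            RewardSpec(0.8, 0.2), LogisticFit(0.0, 0.1),
        )
        assert res["R_min"] == pytest.approx(0.4)

    def test_threshold_shifts_away_from_richer_choice_monotonically(self):
        s = 0.15
        mus = [optimal_threshold(s, r1, 1.0 - r1) for r1 in (0.5, 0.65, 0.8)]
        # larger reward for the positive choice -> threshold moves negative
        assert mus[0] > mus[1] > mus[2]

    def test_symmetry_flip_applied_when_it_raises_reward(self, rng):
        C = rng.uniform(-1, 1, 1000)
        res = reward_analysis(-C, C, RewardSpec(0.5, 0.5), LogisticFit(0.0, 0.1))
        assert res["R"] == pytest.approx(0.5)  # perfect decode after the flip

    def test_iqr_mask_drops_outliers(self):
        t = np.array([0.0, 0.05, -0.02, 0.01, 5.0])
        mask = iqr_keep_mask(t)
        assert not mask[-1] and mask[:-1].all()
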