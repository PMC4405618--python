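"""Rate-based Helmholtz machine: sampling and wake-sleep updates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikinghm.data import make_dataset, unimodal_prior
from spikinghm.metrics import Histogram2D, js_divergence
from spikinghm.rate_hm import (
    RateHMParams,
    approx_delta_update,
    conditional_sample,
    exact_ws_update,
    generate_samples,
    sample_truncated_gaussian,
    train_rate_hm,
)


class TestTruncatedSampling:
    def test_samples_stay_in_nonnegative_orthant(self, rng):
        mu = np.array([2.0, -1.0])
        for _ in range(200):
            s = sample_truncated_gaussian(mu, 9.0 * np.eye(2), rng)
            assert np.all(s >= 0)

    def test_mean_far_from_boundary_matches_untruncated_oracle(self, rng):
        n = 100_000
        draws = np.array([
            sample_truncated_gaussian([30.0, 30.0], 25.0 * np.eye(2), rng)
            for _ in range(2000)
        ])
        se = 5.0 / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - 30.0) < 3 * se)

    def test_degenerate_covariance_limit(self, rng):
        s = sample_truncated_gaussian([30.0, 30.0], 1e-12 * np.eye(2), rng)
        np.testing.assert_allclose(s, [30.0, 30.0], atol=1e-4)

    def test_pathological_mean_raises(self, rng):
        with pytest.raises(RuntimeError):
            sample_truncated_gaussian([-100.0, -100.0], 1.0 * np.eye(2), rng)

    def test_conditional_identity_map_in_low_noise_limit(self, rng):
        p = RateHMParams(W_G=np.eye(2), B_G=[0.0, 0.0], Sigma=1e-10 * np.eye(2))
        x = np.array([17.0, 33.0])
        y = conditional_sample("generative", x, p, rng)
        np.testing.assert_allclose(y, x, atol=1e-3)


class TestExactUpdates:
    def test_hand_computed_wake_step(self):
        p = RateHMParams(eta=0.1, eta_b=0.1, beta=1.0)
        p.B_G[:] = 0.0
        exact_ws_update("wake", x_sample=[1.0, 0.0], y_sample=[2.0, 0.0], params=p)
        assert p.W_G[0, 0] == pytest.approx(0.2)
        assert p.B_G[0] == pytest.approx(0.2)

    def test_perfect_reconstruction_is_stationary(self):
        p = RateHMParams(W_G=[[0.5, 0.1], [0.2, 0.4]], B_G=[0.3, 0.2], eta=0.1, eta_b=0.1)
        x = np.array([10.0, 20.0])
        y = p.W_G @ x + p.B_G * p.beta
        W_before = p.W_G.copy()
        exact_ws_update("wake", x, y, p)
        np.testing.assert_allclose(p.W_G, W_before, atol=1e-12)

    def test_biases_clipped_at_zero(self):
        p = RateHMParams(B_G=[0.01, 0.01], eta_b=1.0, eta=0.0)
        exact_ws_update("wake", [0.0, 0.0], [0.0, 0.0], p)  # strongly negative error
        assert np.all(p.B_G >= 0)


class TestApproxRule:
    def test_direct_evaluation(self):
        assert approx_delta_update(2.0, 5.0, 0.0, eta=0.1, theta_clip=10.0) == pytest.approx(15.0)

    def test_zero_at_matched_target_and_below_clip(self):
        assert approx_delta_update(3.0, 7.0, 7.0, 0.1, 10.0) == 0.0
        assert approx_delta_update(3.0, 0.0, 30.0, 0.1, 10.0) == 0.0  # T-O <= -theta

    @given(
        I=st.floats(0.0, 50.0),
        T=st.floats(0.0, 60.0),
        O=st.floats(0.0, 60.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_same_sign_as_exact_error_inside_clip_region(self, I, T, O):
        dw = approx_delta_update(I, T, O, eta=0.1, theta_clip=10.0)
        err = T - O
        # guard against float underflow of the eta*I*M*(M+theta) product
        if err > -10.0 and I > 1e-6 and abs(err) > 1e-6:
            assert np.sign(dw) == np.sign(err)


class TestTraining:
    def test_zero_learning_rate_is_a_no_op(self, rng):
        ds = make_dataset("a", 50, rng)
        p = RateHMParams(eta=0.0, eta_b=0.0)
        W_before = p.W_G.copy()
        p, _ = train_rate_hm(ds.samples, unimodal_prior(), 200, rule="exact", rng=rng, params=p)
        np.testing.assert_array_equal(p.W_G, W_before)

    @pytest.mark.parametrize("rule", ["exact", "approx"])
    def test_training_improves_generative_fit(self, rule, rng):
        ds = make_dataset("a", 400, rng)
        prior = unimodal_prior()
        data_hist = Histogram2D.from_samples(ds.samples)
        p0 = RateHMParams(eta=2e-5, eta_b=2e-5)
        d_before = js_divergence(
            Histogram2D.from_samples(generate_samples(p0, prior, 1500, rng)), data_hist
        )
        p, _ = train_rate_hm(ds.samples, prior, 30_000, rule=rule, rng=rng, params=p0)
        d_after = js_divergence(
            Histogram2D.from_samples(generate_samples(p, prior, 1500, rng)), data_hist
        )
        assert d_after < d_before

    def test_divergent_weights_abort_with_diagnostics(self, rng):
        ds = make_dataset("a", 50, rng)
        p = RateHMParams(eta=10.0, eta_b=10.0)
        with pytest.raises(RuntimeError, match="diverged"):
            train_rate_hm(ds.samples, unimodal_prior(), 5000, rule="exact", rng=rng, params=p)

    def test_trained_parameters_round_trip_through_flat_file(self, tmp_path):
        from spikinghm.rate_hm import load_params, save_params

        p = RateHMParams(W_G=[[0.5, 0.2], [0.1, 0.6]], B_G=[0.4, 0.3], beta=20.0)
        save_params(p, tmp_path / "params.txt")
        q = load_params(tmp_path / "params.txt")
        np.testing.assert_allclose(q.W_G, p.W_G)
        np.testing.assert_allclose(q.B_G, p.B_G)
        assert q.beta == p.beta

    def test_bias_weights_never_negative_during_training(self, rng):
        ds = make_dataset("a", 100, rng)
        p = RateHMParams(eta=1e-3, eta_b=1e-3)
        p, _ = train_rate_hm(ds.samples, unimodal_prior(), 2000, rule="approx", rng=rng, params=p)
        assert np.all(p.B_G >= 0) and np.all(p.B_R >= 0)
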