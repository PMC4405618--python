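"""Assembly and phase logic of the spiking Helmholtz machine."""

import numpy as np
import pytest

from spikinghm.data import make_dataset, unimodal_prior
from spikinghm.helmholtz import (
    HIDDEN,
    SENSORY,
    HMConfig,
    PhaseSchedule,
    build_hm_network,
    collect_samples,
    train_wake_sleep,
)


@pytest.fixture(scope="module")
def hm():
    return build_hm_network(HMConfig(), seed=11)


class TestAssembly:
    def test_four_units_in_two_layers(self, hm):
        assert len(SENSORY) == 2 and len(HIDDEN) == 2
        for u in SENSORY + HIDDEN:
            for p in ("T", "O", "M", "D", "I", "OUT", "B"):
                assert hm.net.pool_slice(f"{u}.{p}").stop > 0

    def test_every_interlayer_plastic_pathway_ends_on_an_m_pool(self, hm):
        for proj in hm.net.projections:
            if proj.plastic:
                assert proj.dst.endswith(".M")

    def test_same_seed_gives_identical_network(self):
        a = build_hm_network(HMConfig(), seed=4)
        b = build_hm_network(HMConfig(), seed=4)
        np.testing.assert_array_equal(a.net.syn_post, b.net.syn_post)
        np.testing.assert_array_equal(a.net.syn_w, b.net.syn_w)

    def test_bias_streams_run_at_25_hz(self, hm):
        for u in SENSORY + HIDDEN:
            sl = hm.net.pool_slice(f"{u}.B")
            assert np.all(hm.net.gen_rate[sl] == 25.0)


class TestPhaseSwitching:
    def test_wake_gates_sensory_outputs_to_external_input(self):
        hm = build_hm_network(HMConfig(), seed=5)
        hm.set_phase("wake")
        for u in SENSORY:
            assert np.all(hm.net.syn_gate[hm.net._proj_mask(f"{u}.T", f"{u}.OUT")] == 1.0)
            assert np.all(hm.net.syn_gate[hm.net._proj_mask(f"{u}.O", f"{u}.OUT")] == 0.0)
        for u in HIDDEN:
            assert np.all(hm.net.syn_gate[hm.net._proj_mask(f"{u}.O", f"{u}.OUT")] == 1.0)

    def test_sleep_reverses_the_gates(self):
        hm = build_hm_network(HMConfig(), seed=5)
        hm.set_phase("sleep")
        for u in HIDDEN:
            assert np.all(hm.net.syn_gate[hm.net._proj_mask(f"{u}.T", f"{u}.OUT")] == 1.0)
        for u in SENSORY:
            assert np.all(hm.net.syn_gate[hm.net._proj_mask(f"{u}.O", f"{u}.OUT")] == 1.0)

    def test_phase_application_is_idempotent(self):
        hm = build_hm_network(HMConfig(), seed=5)
        hm.set_phase("wake")
        gates = hm.net.syn_gate.copy()
        learn = hm.net.syn_learn.copy()
        hm.set_phase("wake")
        np.testing.assert_array_equal(hm.net.syn_gate, gates)
        np.testing.assert_array_equal(hm.net.syn_learn, learn)

    def test_only_generative_side_learns_in_wake(self):
        hm = build_hm_network(HMConfig(), seed=5)
        hm.set_phase("wake")
        for src, dst in hm._plastic_pairs("generative"):
            m = hm.net._proj_mask(src, dst)
            assert np.all(hm.net.syn_learn[m & (hm.net.syn_plastic == 1)] == 1)
        for src, dst in hm._plastic_pairs("recognition"):
            m = hm.net._proj_mask(src, dst)
            assert np.all(hm.net.syn_learn[m] == 0)

    def test_gated_synapses_bit_identical_through_ineligible_phase(self):
        hm = build_hm_network(HMConfig(), seed=6)
        hm.set_phase("wake")
        frozen_before = {
            (s, d): hm.net.plastic_weights(s, d)
            for s, d in hm._plastic_pairs("recognition")
        }
        hm.set_drive(rates_y=(25.0, 30.0))
        hm.net.run(3000.0, plasticity_on=True)
        for (s, d), w0 in frozen_before.items():
            np.testing.assert_array_equal(hm.net.plastic_weights(s, d), w0)


class TestSampling:
    def test_generative_samples_shape_and_nonnegative(self):
        hm = build_hm_network(HMConfig(), seed=7)
        s = collect_samples(hm, "generative", 6, unimodal_prior(), sample_ms=200.0, rng=0)
        assert s.shape == (6, 2)
        assert np.all(s >= 0)

    def test_recognition_samples_driven_by_dataset(self):
        hm = build_hm_network(HMConfig(), seed=7)
        ds = make_dataset("a", 10, rng=0)
        s = collect_samples(hm, "recognition", 6, ds, sample_ms=200.0, rng=0)
        assert s.shape == (6, 2)
        assert np.all(s >= 0)

    def test_sample_distribution_stationary_without_plasticity(self):
        from spikinghm.metrics import Histogram2D, js_divergence

        hm = build_hm_network(HMConfig(), seed=8)
        prior = unimodal_prior()
        s = collect_samples(hm, "generative", 80, prior, sample_ms=300.0, rng=1)
        d = js_divergence(
            Histogram2D.from_samples(s[:40], bins=8),
            Histogram2D.from_samples(s[40:], bins=8),
        )
        assert d < 0.1


def test_zero_amplitude_plasticity_leaves_weights_unchanged():
    hm = build_hm_network(HMConfig(eta=0.0), seed=9)
    ds = make_dataset("a", 30, rng=0)
    before = {k: v for k, v in hm.plastic_weight_summary().items()}
    train_wake_sleep(
        hm, ds, unimodal_prior(),
        PhaseSchedule(samples_per_phase=2, sample_ms=100.0, total_s=2.0),
        rng=0, warmup_s=0.0,
    )
    after = hm.plastic_weight_summary()
    assert all(after[k] == before[k] for k in before)


def test_invalid_phase_and_schedule_rejected():
    hm = build_hm_network(HMConfig(), seed=10)
    with pytest.raises(ValueError):
        hm.set_phase("dream")
    with pytest.raises(ValueError):
        PhaseSchedule(samples_per_phase=0)
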