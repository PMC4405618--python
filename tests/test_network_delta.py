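"""Pool networks and the delta-rule microcircuit."""

import numpy as np
import pytest

from spikinghm.delta import (
    DeltaCircuitConfig,
    build_delta_network,
    calibrate_fixed_weights,
    run_delta,
)
from spikinghm.network import PoolSpec, ProjectionSpec, SpikingNetwork
from spikinghm.neurons import ExternalDrive


def two_pool_net(seed=0, g=0.1, delay=1.0, rate=30.0):
    pools = [
        PoolSpec("S", 20, "poisson_generator", rate=rate),
        PoolSpec("P", 20, "RS", external_drive=ExternalDrive(100.0, 0.6)),
    ]
    projs = [ProjectionSpec("S", "P", 0.3, g, "excitatory", delay=delay)]
    return SpikingNetwork(pools, projs, seed=seed)


class TestConnectivity:
    def test_fixed_fan_out_and_equal_weight_split(self):
        net = two_pool_net(g=0.3)
        # every source neuron contacts exactly round(0.3*20)=6 targets at 0.05 nS
        for i in range(20):
            sl = slice(net.out_ptr[i], net.out_ptr[i + 1])
            assert sl.stop - sl.start == 6
            np.testing.assert_allclose(net.syn_w[sl], 0.3 / 6)
            assert len(set(net.syn_post[sl])) == 6

    def test_full_sparsity_is_all_to_all(self):
        pools = [PoolSpec("S", 5, "poisson_generator", rate=10.0), PoolSpec("P", 7, "RS")]
        net = SpikingNetwork(pools, [ProjectionSpec("S", "P", 1.0, 0.7, "excitatory")], seed=0)
        assert net.syn_w.size == 35
        np.testing.assert_allclose(net.syn_w, 0.1)

    def test_seed_determines_adjacency(self):
        a, b, c = two_pool_net(seed=5), two_pool_net(seed=5), two_pool_net(seed=6)
        np.testing.assert_array_equal(a.syn_post, b.syn_post)
        assert not np.array_equal(a.syn_post, c.syn_post)

    def test_no_targets_is_an_error(self):
        pools = [PoolSpec("S", 5, "poisson_generator", rate=1.0), PoolSpec("P", 2, "RS")]
        with pytest.raises(ValueError, match="< 1"):
            SpikingNetwork(pools, [ProjectionSpec("S", "P", 0.1, 1.0)], seed=0)

    def test_mismatched_delays_rejected(self):
        pools = [PoolSpec("S", 5, "poisson_generator", rate=1.0), PoolSpec("P", 5, "RS")]
        projs = [
            ProjectionSpec("S", "P", 1.0, 0.1, delay=1.0),
            ProjectionSpec("P", "P", 1.0, 0.1, delay=2.0),
        ]
        with pytest.raises(ValueError, match="delay"):
            SpikingNetwork(pools, projs, seed=0)


class TestSimulation:
    def test_determinism_under_same_seed(self):
        r1 = two_pool_net(seed=3).run(2000.0)
        r2 = two_pool_net(seed=3).run(2000.0)
        np.testing.assert_array_equal(r1.counts, r2.counts)

    def test_transmission_respects_delay(self):
        # a brief volley of generator spikes may only affect the target's
        # conductance (and hence make it spike) `delay` after the volley
        pools = [
            PoolSpec("S", 1, "poisson_generator", rate=0.0),
            PoolSpec("P", 1, "RS"),
        ]
        net = SpikingNetwork(
            pools, [ProjectionSpec("S", "P", 1.0, 50.0, "excitatory", delay=2.0)], seed=0
        )
        net.set_pool_rate("S", 2000.0)
        burst = net.run(2.0, record_spikes=True).spikes
        net.set_pool_rate("S", 0.0)
        tail = net.run(100.0, record_spikes=True).spikes
        spikes = np.vstack([burst, tail])
        src = spikes[spikes[:, 0] == 0][:, 1]
        dst = spikes[spikes[:, 0] == 1][:, 1]
        assert src.size > 0 and dst.size > 0
        assert dst.min() >= src.min() + 2.0 - 1e-9 - 1e-9

    def test_conductances_never_negative(self):
        net = two_pool_net()
        net.run(1000.0)
        for g in (net.ge1, net.ge2, net.gi, net.gr):
            assert np.all(g >= 0)

    def test_generator_pool_rate_control(self):
        net = two_pool_net(rate=0.0)
        res = net.run(1000.0)
        assert res.pool_rate("S") == 0.0
        net.set_pool_rate("S", 50.0)
        res = net.run(4000.0)
        assert res.pool_rate("S") == pytest.approx(50.0, rel=0.15)
        with pytest.raises(ValueError):
            net.set_pool_rate("P", 10.0)


class TestDeltaCircuit:
    def test_silent_without_any_drive(self):
        cfg = DeltaCircuitConfig(
            drive_o=ExternalDrive(0.0, 0.0), drive_m=ExternalDrive(0.0, 0.0)
        )
        net = build_delta_network(cfg, seed=0)
        rates = run_delta(net, 0.0, 0.0, 1.0, plasticity_on=False)
        assert rates["O"] == pytest.approx(0.0, abs=0.5)

    def test_output_rate_increases_with_plastic_weight(self):
        outs = []
        for w in (0.1, 0.8, 1.6):
            net = build_delta_network(DeltaCircuitConfig(w_start=w), seed=1)
            outs.append(run_delta(net, 20.0, 30.0, 2.0, plasticity_on=False)["O"])
        assert outs[0] < outs[1] < outs[2]

    def test_output_insensitive_to_target_before_training(self):
        outs = []
        for rT in (0.0, 30.0, 60.0):
            net = build_delta_network(DeltaCircuitConfig(w_start=0.6), seed=1)
            outs.append(run_delta(net, 20.0, rT, 2.0, plasticity_on=False)["O"])
        spread = max(outs) - min(outs)
        assert spread < 12.0  # short-timescale independence of the target

    def test_rates_stationary_with_plasticity_off(self):
        net = build_delta_network(DeltaCircuitConfig(w_start=0.6), seed=2)
        first = run_delta(net, 20.0, 30.0, 4.0, plasticity_on=False)
        second = run_delta(net, 20.0, 30.0, 4.0, plasticity_on=False, settle_ms=0.0)
        for p in ("O", "M"):
            assert second[p] == pytest.approx(first[p], abs=4.0)

    def test_plastic_weights_frozen_when_plasticity_off(self):
        net = build_delta_network(DeltaCircuitConfig(w_start=0.6), seed=3)
        w0 = net.plastic_weights("I", "M")
        net.run(2000.0, plasticity_on=False)
        np.testing.assert_array_equal(net.plastic_weights("I", "M"), w0)

    def test_calibration_scores_shipped_conductances(self):
        cfg = DeltaCircuitConfig()
        out = calibrate_fixed_weights(
            cfg, rT_grid=(10.0, 45.0), w_grid=(0.4, 1.2), probe_s=1.0,
            refine_iters=0,
        )
        assert out["score"] >= 0.75  # sign identity holds on the probe grid
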