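"""Single-neuron dynamics, synapse constants and vesicle release."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikinghm.neurons import (
    FS,
    RS,
    ConductanceSet,
    IzhikevichParams,
    NeuronState,
    NumericalBlowupError,
    SynapseConstants,
    VesicleModel,
    decay_conductances,
    deliver_spike,
    nmda_gate,
    step_neuron,
    truncated_release_mean,
)


class TestNmdaGate:
    def test_reference_value(self):
        # direct evaluation of the magnesium-block expression
        assert nmda_gate(0.0, 1.0) == pytest.approx(1.0 / (1.0 + 1.0 / 3.57), rel=1e-12)

    def test_zero_magnesium_removes_block(self):
        for V in (-80.0, -30.0, 0.0, 40.0):
            assert nmda_gate(V, 0.0) == 1.0

    @given(V=st.floats(-100, 100), mg=st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_increasing_in_voltage(self, V, mg):
        g = nmda_gate(V, mg)
        assert 0.0 < g <= 1.0
        assert nmda_gate(V + 1.0, mg) >= g


class TestStepNeuron:
    def test_threshold_crossing_resets_to_c(self):
        state = NeuronState(V=10.0, u=0.0)
        new, spiked = step_neuron(state, ConductanceSet(), params=RS)
        assert spiked
        assert new.V == RS.c
        assert new.u == pytest.approx(0.0 + RS.a * (RS.b * 10.0 - 0.0) * 0.1 + RS.d)

    def test_rest_is_a_fixed_point(self):
        V0 = RS.rest_potential()
        state = NeuronState(V=V0, u=RS.b * V0)
        new, spiked = step_neuron(state, ConductanceSet(), params=RS)
        assert not spiked
        assert new.V == pytest.approx(V0, abs=1e-9)
        assert new.u == pytest.approx(RS.b * V0, abs=1e-9)

    def test_rest_neuron_stays_silent_for_ten_seconds(self):
        V0 = RS.rest_potential()
        state = NeuronState(V=V0, u=RS.b * V0)
        for _ in range(100_000):
            state, spiked = step_neuron(state, ConductanceSet(), params=RS)
            assert not spiked

    @pytest.mark.parametrize("params", [RS, FS], ids=["RS", "FS"])
    def test_fi_curve_monotone_and_roughly_linear(self, params):
        def rate(I_dc):
            state = NeuronState(V=params.rest_potential(), u=params.b * params.rest_potential())
            n = 0
            for _ in range(20_000):  # 2 s at dt=0.1
                state, spiked = step_neuron(state, ConductanceSet(), params=params, I_dc=I_dc)
                n += spiked
            return n / 2.0

        currents = [6.0, 10.0, 14.0, 18.0]
        rates = [rate(I) for I in currents]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        # suprathreshold slope varies by less than a factor of three
        slopes = np.diff(rates) / np.diff(currents)
        assert slopes.max() < 3.0 * max(slopes.min(), 1e-9)

    def test_nonfinite_state_reports_neuron_index(self):
        with pytest.raises(NumericalBlowupError) as exc:
            step_neuron(NeuronState(V=np.nan, u=0.0), ConductanceSet(), neuron_index=7)
        assert exc.value.neuron_index == 7

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            IzhikevichParams(a=-0.1, b=0.2, c=-65, d=8)
        with pytest.raises(ValueError):
            IzhikevichParams(a=0.02, b=0.2, c=10.0, d=8)


class TestVesicleRelease:
    def test_deterministic_release_at_unit_probability(self, rng):
        v = VesicleModel(Nv=10, Pv=1.0)
        assert deliver_spike(2.0, v, rng) == pytest.approx(20.0)

    def test_increment_never_negative(self, rng):
        v = VesicleModel(Nv=4, Pv=0.1)  # mean close to zero, frequent truncation
        draws = np.array([deliver_spike(1.0, v, rng) for _ in range(2000)])
        assert np.all(draws >= 0)

    def test_monte_carlo_mean_matches_truncated_normal_oracle(self, rng):
        v = VesicleModel(Nv=10, Pv=0.5)
        n = 100_000
        f = v.mean + v.std * rng.standard_normal(n)
        draws = np.maximum(f, 0.0)  # same model as deliver_spike with w=1
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - truncated_release_mean(v)) < 3 * se

    def test_negative_weight_rejected(self, rng):
        with pytest.raises(ValueError):
            deliver_spike(-1.0, VesicleModel(), rng)


class TestConductanceDecay:
    def test_closed_form_one_tau(self):
        c = SynapseConstants()
        g = decay_conductances(ConductanceSet(ge1=1.0, ge2=1.0, gi=1.0, gr=1.0), c, dt=c.tau_e1)
        assert g.ge1 == pytest.approx(np.exp(-1.0))
        assert g.gr == pytest.approx(np.exp(-1.0))  # external shares tau_e1

    @given(dt=st.floats(0.01, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_semigroup_property(self, dt):
        c = SynapseConstants()
        g0 = ConductanceSet(ge1=1.3, ge2=0.7, gi=2.1, gr=0.4)
        one = decay_conductances(g0, c, dt)
        two = decay_conductances(decay_conductances(g0, c, dt / 2), c, dt / 2)
        for attr in ("ge1", "ge2", "gi", "gr"):
            assert getattr(two, attr) == pytest.approx(getattr(one, attr), rel=1e-12)

    def test_invalid_constants(self):
        with pytest.raises(ValueError):
            SynapseConstants(tau_e1=-1.0)
        with pytest.raises(ValueError):
            SynapseConstants(Ee=-80.0, Ei=-70.0)
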