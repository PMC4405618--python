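"""Izhikevich point neurons with conductance-based stochastic synapses.

The single-neuron model is the two-variable quadratic integrate-and-fire
variant of Izhikevich (2003),

    dV/dt = 0.04 V^2 + 5 V + 140 - u + I_e + I_i + I_r
    du/dt = a (b V - u)
    if V > 0 mV:  V <- c,  u <- u + d,

integrated with fixed-step forward Euler.  Synaptic input is conductance
based: AMPA (``ge1``), NMDA (``ge2``, voltage gated by the Jahr--Stevens
magnesium block), GABA_A (``gi``) and an external AMPA-like channel
(``gr``) driven by per-neuron Poisson event streams.  Each presynaptic
spike releases a stochastic number of vesicles, modelled by a normal
approximation to a binomial truncated at zero.

Units throughout: membrane potential in mV, time in ms, conductances in
nS, rates in Hz.  The quantities ``u``, ``I`` share the mV/ms scale of the
original dimensionless Izhikevich formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "ConductanceSet",
    "SynapseConstants",
    "VesicleModel",
    "ExternalDrive",
    "NumericalBlowupError",
    "RS",
    "FS",
    "nmda_gate",
    "step_neuron",
    "deliver_spike",
    "decay_conductances",
    "truncated_release_mean",
]


class NumericalBlowupError(RuntimeError):
    """Raised when a neuron's state becomes non-finite during integration."""

    def __init__(self, neuron_index: int = 0):
        self.neuron_index = neuron_index
        super().__init__(f"non-finite membrane state for neuron {neuron_index}")


@dataclass(frozen=True)
class IzhikevichParams:
    """Dynamics parameters ``a, b, c, d`` of the Izhikevich model.

    ``a`` (1/ms) sets the recovery-variable timescale, ``b`` the coupling
    of ``u`` to ``V``, ``c`` (mV) the post-spike reset potential and ``d``
    the post-spike adaptation increment.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.c > 0:
            raise ValueError("reset potential c must be <= 0 mV")

    def rest_potential(self) -> float:
        """Subthreshold rest fixed point with zero synaptic input.

        At rest ``u = bV`` and ``0.04 V^2 + 5V + 140 - bV = 0``; the lower
        root is the stable fixed point.
        """
        b = self.b
        disc = (5.0 - b) ** 2 - 4 * 0.04 * 140.0
        if disc < 0:
            raise ValueError("parameters admit no subthreshold fixed point")
        return (-(5.0 - b) - math.sqrt(disc)) / (2 * 0.04)


#: Regular-spiking (excitatory) preset.
RS = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: Fast-spiking (inhibitory) preset.
FS = IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=2.0)


@dataclass
class NeuronState:
    """Membrane potential ``V`` (mV) and adaptation current ``u``."""

    V: float
    u: float


@dataclass
class ConductanceSet:
    """Summed synaptic conductances (nS) of one neuron.

    ``ge1``: AMPA, ``ge2``: NMDA, ``gi``: GABA_A, ``gr``: external drive
    (AMPA-like, shares the AMPA decay constant).
    """

    ge1: float = 0.0
    ge2: float = 0.0
    gi: float = 0.0
    gr: float = 0.0


@dataclass(frozen=True)
class SynapseConstants:
    """Decay constants (ms), reversal potentials (mV) and magnesium level.

    ``Mg_ext`` (mM) controls the NMDA voltage gate.  The external channel
    ``gr`` decays with the AMPA constant ``tau_e1``.
    """

    tau_e1: float = 5.0
    tau_e2: float = 100.0
    tau_i: float = 10.0
    Ee: float = 0.0
    Ei: float = -70.0
    Mg_ext: float = 1.0

    def __post_init__(self):
        if min(self.tau_e1, self.tau_e2, self.tau_i) <= 0:
            raise ValueError("decay constants must be positive")
        if self.Ee <= self.Ei:
            raise ValueError("Ee must exceed Ei")


@dataclass(frozen=True)
class VesicleModel:
    """Stochastic vesicle release: ``Nv`` release sites, probability ``Pv``.

    The binomial release count is approximated by a normal with mean
    ``Nv*Pv`` and variance ``Nv*Pv*(1-Pv)``, truncated at zero.
    """

    Nv: int = 10
    Pv: float = 0.5

    def __post_init__(self):
        if self.Nv < 1:
            raise ValueError("Nv must be >= 1")
        if not 0.0 <= self.Pv <= 1.0:
            raise ValueError("Pv must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return self.Nv * self.Pv

    @property
    def std(self) -> float:
        return math.sqrt(self.Nv * self.Pv * (1.0 - self.Pv))


@dataclass(frozen=True)
class ExternalDrive:
    """Per-neuron Poisson drive: event rate (Hz) and increment ``w_r`` (nS)."""

    rate: float = 100.0
    w_r: float = 0.5

    def __post_init__(self):
        if self.rate < 0 or self.w_r < 0:
            raise ValueError("rate and w_r must be non-negative")


def nmda_gate(V: float, Mg_ext: float = 1.0) -> float:
    """Voltage dependence of the NMDA conductance (Jahr & Stevens 1990).

    Returns ``1 / (1 + (Mg_ext / 3.57) * exp(-0.062 V))`` in (0, 1].
    """
    if Mg_ext < 0:
        raise ValueError("Mg_ext must be non-negative")
    return 1.0 / (1.0 + (Mg_ext / 3.57) * np.exp(-0.062 * V))


def step_neuron(
    state: NeuronState,
    conductances: ConductanceSet,
    constants: SynapseConstants = SynapseConstants(),
    params: IzhikevichParams = RS,
    dt: float = 0.1,
    I_dc: float = 0.0,
    neuron_index: int = 0,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one forward-Euler step of size ``dt`` (ms).

    Synaptic currents are evaluated at the pre-step potential:
    ``Ie = (ge1 + ge2 * NMDA(V)) (Ee - V)``, ``Ii = gi (Ei - V)``,
    ``Ir = gr (Ee - V)``; ``I_dc`` adds a constant injected current.  A
    spike is registered when the updated potential exceeds 0 mV, upon
    which ``V`` is reset to ``c`` and ``u`` incremented by ``d``.

    Returns the new state and a spike flag.  Raises
    :class:`NumericalBlowupError` if the incoming state is non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    V, u = state.V, state.u
    if not (np.isfinite(V) and np.isfinite(u)):
        raise NumericalBlowupError(neuron_index)
    g = conductances
    Ie = (g.ge1 + g.ge2 * nmda_gate(V, constants.Mg_ext)) * (constants.Ee - V)
    Ii = g.gi * (constants.Ei - V)
    Ir = g.gr * (constants.Ee - V)
    Vn = V + dt * (0.04 * V * V + 5.0 * V + 140.0 - u + Ie + Ii + Ir + I_dc)
    un = u + dt * params.a * (params.b * V - u)
    if Vn > 0.0:
        return NeuronState(V=params.c, u=un + params.d), True
    return NeuronState(V=Vn, u=un), False


def deliver_spike(
    w: float,
    vesicles: VesicleModel,
    rng: np.random.Generator,
) -> float:
    """Conductance increment (nS) caused by one presynaptic spike.

    The released-vesicle count ``f`` is drawn from the normal
    approximation ``N(Nv*Pv, Nv*Pv*(1-Pv))`` truncated at zero; the
    increment is ``w * f >= 0``.  Delivery timing (the projection delay)
    is handled by the network scheduler, not here.
    """
    if w < 0:
        raise ValueError("synaptic weight must be non-negative")
    f = vesicles.mean + vesicles.std * rng.standard_normal()
    return w * max(f, 0.0)


def truncated_release_mean(vesicles: VesicleModel) -> float:
    """Closed-form mean of ``max(f, 0)`` under the normal release model.

    For ``f ~ N(m, s^2)``: ``E[max(f,0)] = m * Phi(m/s) + s * phi(m/s)``.
    Used as the independent oracle for :func:`deliver_spike`.
    """
    m, s = vesicles.mean, vesicles.std
    if s == 0:
        return max(m, 0.0)
    z = m / s
    return m * stats.norm.cdf(z) + s * stats.norm.pdf(z)


def decay_conductances(
    conductances: ConductanceSet,
    constants: SynapseConstants = SynapseConstants(),
    dt: float = 0.1,
) -> ConductanceSet:
    """Exponential decay of all conductance channels over ``dt`` ms.

    Each channel decays as ``g -> g * exp(-dt/tau)`` with its own time
    constant; the external channel shares ``tau_e1``.  Exact (semigroup)
    for any ``dt >= 0``.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return ConductanceSet(
        ge1=conductances.ge1 * math.exp(-dt / constants.tau_e1),
        ge2=conductances.ge2 * math.exp(-dt / constants.tau_e2),
        gi=conductances.gi * math.exp(-dt / constants.tau_i),
        gr=conductances.gr * math.exp(-dt / constants.tau_e1),
    )
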