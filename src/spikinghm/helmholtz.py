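"""The four-unit spiking Helmholtz machine.

Four delta-rule microcircuits ("units") are arranged in two layers —
sensory units ``y1, y2`` and hidden units ``x1, x2``.  Each unit keeps
the T/O/M/D/I pools of the delta circuit (the input pool E is dropped),
and adds

* an *output* pool that broadcasts the unit's realised value and is
  driven, through two switchable projections, either by the external
  input pool T or by the unit's own conditional-sampling pool O;
* an I pool associated with the unit as a *source*: it is driven by the
  unit's output pool and is the presynaptic partner of the plastic
  inhibitory synapses this unit makes onto other units' M pools;
* a bias pool of Poisson generators at ``r_b = 25`` Hz making plastic
  inhibitory synapses onto the unit's own M pool (the bias weights).

Inter-layer connections per (source, destination) pair across layers:
fixed excitation output->M and plastic inhibition I->M.  The balance of
the two encodes the signed weight of the rate model.

Wake phase: sensory T pools carry data samples and drive the sensory
outputs; hidden outputs are O-driven (recognition samples); only the
plastic synapses onto *sensory* M pools (generative side) learn.
Sleep phase: hidden T pools carry prior samples and drive the hidden
outputs; sensory outputs are O-driven (generative fantasies); only the
*hidden*-side plastic synapses learn.  The non-driven layer's T pools
are held at a steady rate.  Switching is synaptic gating (conductance
multiplier 0/1), not rewiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .delta import DEFAULT_CONDUCTANCES, DEFAULT_R_THETA, _make_rule, DeltaCircuitConfig
from .network import PoolSpec, ProjectionSpec, SpikingNetwork
from .neurons import ExternalDrive

__all__ = [
    "HMConfig",
    "PhaseSchedule",
    "SpikingHelmholtzMachine",
    "build_hm_network",
    "train_wake_sleep",
    "collect_samples",
]

SENSORY = ("y1", "y2")
HIDDEN = ("x1", "x2")


@dataclass(frozen=True)
class HMConfig:
    """Architecture and plasticity settings of the spiking machine."""

    conductances: dict = field(default_factory=lambda: dict(DEFAULT_CONDUCTANCES))
    g_output: float = 0.13       # T->output and O->output relay conductance
    g_inter_exc: float = 0.10    # output->M fixed excitation across layers
    g_out_to_i: float = 0.015    # output->I drive of the source-side I pool
    w_start: float = 0.3         # initial plastic total conductance per source
    w_bias_start: float = 0.3
    w_max: float = 0.4           # per-synapse cap; keeps M pools out of the
                                 # silent BCM dead zone (no depression at
                                 # zero post rate)
    r_bias: float = 25.0
    r_ns: float = 40.0           # steady rate of the non-driven T pools
    r_theta: float = DEFAULT_R_THETA
    eta: float = 1e-7
    rule: str = "bcm"
    bcm_tau: float = 50.0
    stdpi_tau1: float = 50.0
    stdpi_tau2: float = 20.0
    n_generators: int = 20
    n_rs: int = 20
    n_fs: int = 10
    n_bias: int = 10
    sparsity: float = 0.3
    use_relay_pool: bool = False  # speculative pass-through pool R
    dt: float = 0.1


@dataclass(frozen=True)
class PhaseSchedule:
    """Wake/sleep alternation: samples per phase and sample duration."""

    samples_per_phase: int = 10
    sample_ms: float = 500.0
    total_s: float = 5000.0

    def __post_init__(self):
        if self.samples_per_phase < 1 or self.sample_ms <= 0 or self.total_s <= 0:
            raise ValueError("invalid schedule")

    @property
    def n_phase_pairs(self) -> int:
        pair_ms = 2 * self.samples_per_phase * self.sample_ms
        return max(1, int(round(self.total_s * 1000.0 / pair_ms)))


class SpikingHelmholtzMachine:
    """Wrapper tying the pool network to the wake-sleep protocol."""

    def __init__(self, cfg: HMConfig = HMConfig(), seed: int = 0):
        self.cfg = cfg
        g = cfg.conductances
        pools, projs = [], []
        for unit in SENSORY + HIDDEN:
            pools += [
                PoolSpec(f"{unit}.T", cfg.n_generators, "poisson_generator", rate=cfg.r_ns),
                PoolSpec(f"{unit}.O", cfg.n_rs, "RS", external_drive=ExternalDrive(100.0, 0.6)),
                PoolSpec(f"{unit}.M", cfg.n_rs, "RS", external_drive=ExternalDrive(100.0, 0.42)),
                PoolSpec(f"{unit}.D", cfg.n_fs, "FS"),
                PoolSpec(f"{unit}.I", cfg.n_fs, "FS"),
                PoolSpec(f"{unit}.OUT", cfg.n_rs, "RS"),
                PoolSpec(f"{unit}.B", cfg.n_bias, "poisson_generator", rate=cfg.r_bias),
            ]
            s = cfg.sparsity
            projs += [
                ProjectionSpec(f"{unit}.T", f"{unit}.O", s, g["TO"], "excitatory"),
                ProjectionSpec(f"{unit}.T", f"{unit}.M", s, g["TM"], "excitatory"),
                ProjectionSpec(f"{unit}.M", f"{unit}.D", s, g["MD"], "excitatory"),
                ProjectionSpec(f"{unit}.D", f"{unit}.O", s, g["DO"], "inhibitory"),
                ProjectionSpec(f"{unit}.OUT", f"{unit}.I", s, cfg.g_out_to_i, "excitatory"),
                ProjectionSpec(f"{unit}.B", f"{unit}.M", s, cfg.w_bias_start, "inhibitory", plastic=True),
                # switchable drivers of the output pool
                ProjectionSpec(f"{unit}.T", f"{unit}.OUT", s, cfg.g_output, "excitatory"),
                ProjectionSpec(f"{unit}.O", f"{unit}.OUT", s, cfg.g_output, "excitatory"),
            ]
            if cfg.use_relay_pool:
                # speculative relay between O and OUT; off by default
                pools.append(PoolSpec(f"{unit}.R", cfg.n_rs, "RS"))
        for src_layer, dst_layer in ((HIDDEN, SENSORY), (SENSORY, HIDDEN)):
            for src in src_layer:
                for dst in dst_layer:
                    projs += [
                        ProjectionSpec(f"{src}.OUT", f"{dst}.M", cfg.sparsity,
                                       cfg.g_inter_exc, "excitatory"),
                        ProjectionSpec(f"{src}.I", f"{dst}.M", cfg.sparsity,
                                       cfg.w_start, "inhibitory", plastic=True),
                    ]
        dummy = DeltaCircuitConfig(
            rule=cfg.rule, r_theta=cfg.r_theta, eta=cfg.eta,
            bcm_tau=cfg.bcm_tau, stdpi_tau1=cfg.stdpi_tau1, stdpi_tau2=cfg.stdpi_tau2,
        )
        self.net = SpikingNetwork(
            pools, projs, rule=_make_rule(dummy), dt=cfg.dt, seed=seed, w_max=cfg.w_max
        )
        self.phase = None
        self.set_phase("wake")

    # -- phase switching ------------------------------------------------
    def _plastic_pairs(self, side: str):
        """(src, dst) names of plastic projections of one side.

        ``side="generative"``: synapses onto sensory M pools (learn in
        wake); ``side="recognition"``: onto hidden M pools (sleep).
        """
        dsts, srcs = (
            (SENSORY, HIDDEN) if side == "generative" else (HIDDEN, SENSORY)
        )
        pairs = [(f"{u}.B", f"{u}.M") for u in dsts]
        pairs += [(f"{s}.I", f"{d}.M") for s in srcs for d in dsts]
        return pairs

    def set_phase(self, phase: str):
        """Reconfigure gates, steady drives and plasticity eligibility.

        Idempotent; does not touch generator rates used for the driven
        layer (those are set per sample).
        """
        if phase not in ("wake", "sleep"):
            raise ValueError("phase must be 'wake' or 'sleep'")
        driven, undriven = (SENSORY, HIDDEN) if phase == "wake" else (HIDDEN, SENSORY)
        for u in driven:   # outputs follow the external input
            self.net.set_gate(f"{u}.T", f"{u}.OUT", True)
            self.net.set_gate(f"{u}.O", f"{u}.OUT", False)
        for u in undriven:  # outputs follow the conditional sampler
            self.net.set_gate(f"{u}.T", f"{u}.OUT", False)
            self.net.set_gate(f"{u}.O", f"{u}.OUT", True)
            self.net.set_pool_rate(f"{u}.T", self.cfg.r_ns)
        learn_side = "generative" if phase == "wake" else "recognition"
        freeze_side = "recognition" if phase == "wake" else "generative"
        for src, dst in self._plastic_pairs(learn_side):
            self.net.set_learn(src, dst, True)
        for src, dst in self._plastic_pairs(freeze_side):
            self.net.set_learn(src, dst, False)
        self.phase = phase

    def set_drive(self, rates_y=None, rates_x=None):
        """Set the T-pool rates of the sensory and/or hidden layers (Hz)."""
        if rates_y is not None:
            for u, r in zip(SENSORY, rates_y):
                self.net.set_pool_rate(f"{u}.T", float(max(r, 0.0)))
        if rates_x is not None:
            for u, r in zip(HIDDEN, rates_x):
                self.net.set_pool_rate(f"{u}.T", float(max(r, 0.0)))

    def equilibrate(self, dataset, prior, duration_s: float = 50.0, rng=None):
        """Clamped warm-up bringing every plastic weight to its balance point.

        Both layers' output pools are temporarily driven externally
        (sensory T pools with data samples, hidden T pools with prior
        draws) while *all* plastic synapses learn, so each M pool
        settles at the BCM fixed point under realistic stream rates.
        Starting wake-sleep proper from this mutually consistent state
        prevents the two phases from training each side against the
        other side's degenerate output statistics.  Ends in the wake
        configuration.
        """
        rng = np.random.default_rng(rng)
        data = dataset.samples if hasattr(dataset, "samples") else np.asarray(dataset)
        draw_prior = prior.sample if hasattr(prior, "sample") else prior
        for u in SENSORY + HIDDEN:
            self.net.set_gate(f"{u}.T", f"{u}.OUT", True)
            self.net.set_gate(f"{u}.O", f"{u}.OUT", False)
        for side in ("generative", "recognition"):
            for src, dst in self._plastic_pairs(side):
                self.net.set_learn(src, dst, True)
        for _ in range(max(1, int(duration_s * 2))):
            self.set_drive(
                rates_y=data[rng.integers(len(data))], rates_x=draw_prior(rng)
            )
            self.net.run(500.0, plasticity_on=True)
        self.phase = None
        self.set_phase("wake")

    def output_rates(self, result, layer: str) -> np.ndarray:
        units = SENSORY if layer == "sensory" else HIDDEN
        return np.array([result.pool_rate(f"{u}.OUT") for u in units])

    def plastic_weight_summary(self) -> dict:
        out = {}
        for side in ("generative", "recognition"):
            for src, dst in self._plastic_pairs(side):
                out[f"{src}->{dst}"] = float(self.net.plastic_weights(src, dst).mean())
        return out


def build_hm_network(cfg: HMConfig = HMConfig(), seed: int = 0) -> SpikingHelmholtzMachine:
    """Construct the two-layer, four-unit machine (deterministic per seed)."""
    return SpikingHelmholtzMachine(cfg, seed=seed)


def train_wake_sleep(
    hm: SpikingHelmholtzMachine,
    dataset,
    prior,
    schedule: PhaseSchedule = PhaseSchedule(),
    rng=None,
    log_weights_every: int = 0,
    warmup_s: float = 50.0,
):
    """Wake-sleep training per the phase schedule.

    A clamped warm-up of ``warmup_s`` seconds (see
    :meth:`SpikingHelmholtzMachine.equilibrate`; 0 disables it) is
    followed by alternating phases: each wake phase presents
    ``samples_per_phase`` consecutive data samples (wrapping around the
    dataset), each held for ``sample_ms``; each sleep phase presents as
    many prior draws.  Returns a list of plastic-weight summaries (one
    per ``log_weights_every`` phase pairs) for diagnostics.
    """
    rng = np.random.default_rng(rng)
    if warmup_s > 0:
        hm.equilibrate(dataset, prior, warmup_s, rng)
    data = dataset.samples if hasattr(dataset, "samples") else np.asarray(dataset)
    draw_prior = prior.sample if hasattr(prior, "sample") else prior
    logs = []
    data_pos = 0
    for pair in range(schedule.n_phase_pairs):
        hm.set_phase("wake")
        for _ in range(schedule.samples_per_phase):
            hm.set_drive(rates_y=data[data_pos % len(data)])
            data_pos += 1
            hm.net.run(schedule.sample_ms, plasticity_on=True)
        hm.set_phase("sleep")
        for _ in range(schedule.samples_per_phase):
            hm.set_drive(rates_x=draw_prior(rng))
            hm.net.run(schedule.sample_ms, plasticity_on=True)
        if log_weights_every and (pair + 1) % log_weights_every == 0:
            logs.append(hm.plastic_weight_summary())
    return logs


def collect_samples(
    hm: SpikingHelmholtzMachine,
    mode: str,
    n_samples: int,
    source,
    sample_ms: float = 500.0,
    rng=None,
) -> np.ndarray:
    """Sample the trained machine with plasticity off.

    ``mode="generative"``: drive the hidden T pools from ``source``
    (a prior) in the sleep configuration and read the sensory output
    pools.  ``mode="recognition"``: drive the sensory T pools from
    ``source`` (a dataset or (N, 2) array) in the wake configuration
    and read the hidden output pools.  Returns an (n_samples, 2) array
    of mean output rates, one row per ``sample_ms`` window.
    """
    rng = np.random.default_rng(rng)
    out = np.empty((n_samples, 2))
    if mode == "generative":
        hm.set_phase("sleep")
        draw = source.sample if hasattr(source, "sample") else source
        for i in range(n_samples):
            hm.set_drive(rates_x=draw(rng))
            res = hm.net.run(sample_ms, plasticity_on=False)
            out[i] = hm.output_rates(res, "sensory")
    elif mode == "recognition":
        hm.set_phase("wake")
        data = source.samples if hasattr(source, "samples") else np.asarray(source)
        for i in range(n_samples):
            hm.set_drive(rates_y=data[i % len(data)])
            res = hm.net.run(sample_ms, plasticity_on=False)
            out[i] = hm.output_rates(res, "hidden")
    else:
        raise ValueError("mode must be 'generative' or 'recognition'")
    return out
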