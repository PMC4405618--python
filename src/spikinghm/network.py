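"""Pool-structured spiking networks over the numba simulation engine.

A network is a set of homogeneous neuron *pools* (regular-spiking RS,
fast-spiking FS, or Poisson generators) connected by directed sparse
*projections*.  Every neuron in a source pool contacts the same number
of neurons in the destination pool (``round(sparsity * size(dst))``,
drawn without replacement), and the fixed total conductance per source
neuron is split equally across its contacts.  Transmission is delayed
by a single network-wide delay and subject to stochastic vesicle
release.  A projection can be *plastic* (its weights driven by the
configured Spiking BCM or STDPi rule), *gated* (conductance multiplier
toggled 0/1 for phase switching) and *eligible* or not for learning.

Simulation state persists across :meth:`SpikingNetwork.run` calls, so
protocols are written as sequences of runs with rate/gate changes in
between.  All randomness derives from the seed given at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine
from .neurons import (
    FS,
    RS,
    ExternalDrive,
    IzhikevichParams,
    NumericalBlowupError,
    SynapseConstants,
    VesicleModel,
)
from .plasticity import SpikingBCMParams, STDPiParams

__all__ = ["PoolSpec", "ProjectionSpec", "SpikingNetwork", "SimResult"]

_CELL_KINDS = ("RS", "FS", "poisson_generator")


@dataclass(frozen=True)
class PoolSpec:
    """A homogeneous pool: name, size, cell kind and optional drives.

    ``rate`` sets the event rate of a Poisson-generator pool;
    ``external_drive`` attaches an independent nonspecific Poisson input
    to every neuron of an RS/FS pool.
    """

    name: str
    size: int
    cell_kind: str = "RS"
    rate: float = 0.0
    external_drive: ExternalDrive | None = None

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("pool size must be >= 1")
        if self.cell_kind not in _CELL_KINDS:
            raise ValueError(f"cell_kind must be one of {_CELL_KINDS}")


@dataclass(frozen=True)
class ProjectionSpec:
    """A directed pool-to-pool projection.

    ``total_conductance`` (nS) is the summed weight of the contacts made
    by each source neuron; each of its ``round(sparsity * size(dst))``
    contacts receives an equal share.  ``sign`` selects the conductance
    channel (excitatory AMPA+NMDA or inhibitory GABA_A).
    """

    src: str
    dst: str
    sparsity: float = 0.3
    total_conductance: float = 0.0
    sign: str = "excitatory"
    plastic: bool = False
    delay: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")
        if self.total_conductance < 0:
            raise ValueError("total_conductance must be non-negative")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")


@dataclass
class SimResult:
    """Spike counts per neuron over one run, with pool-rate helpers."""

    counts: np.ndarray
    duration_ms: float
    network: "SpikingNetwork"
    spikes: np.ndarray | None = None  # (n, 2) [neuron, time_ms] if recorded

    def pool_rate(self, name: str) -> float:
        """Mean firing rate (Hz) of a pool over the run."""
        sl = self.network.pool_slice(name)
        return float(self.counts[sl].sum() / (sl.stop - sl.start) / (self.duration_ms / 1000.0))


class SpikingNetwork:
    """A runnable pool network; see the module docstring.

    Parameters
    ----------
    pools, projections:
        The architecture.  Pool names must be unique; projections refer
        to pools by name and must all share one transmission delay.
    rule:
        :class:`SpikingBCMParams` or :class:`STDPiParams` applied to all
        plastic projections.
    dt:
        Integration step (ms).
    seed:
        Master seed; connectivity and every subsequent run derive from
        it deterministically.
    """

    def __init__(
        self,
        pools: list[PoolSpec],
        projections: list[ProjectionSpec],
        rule=None,
        dt: float = 0.1,
        seed: int = 0,
        constants: SynapseConstants = SynapseConstants(),
        vesicles: VesicleModel = VesicleModel(),
        nmda_frac: float = 0.5,
        w_max: float = np.inf,
        rs_params: IzhikevichParams = RS,
        fs_params: IzhikevichParams = FS,
    ):
        if len({p.name for p in pools}) != len(pools):
            raise ValueError("pool names must be unique")
        delays = {p.delay for p in projections}
        if len(delays) > 1:
            raise ValueError("all projections must share one delay")
        self.delay = delays.pop() if delays else 1.0
        if self.delay <= 0:
            raise ValueError("delay must be positive")
        self.dt = dt
        self.constants = constants
        self.vesicles = vesicles
        self.nmda_frac = nmda_frac
        self.w_max = float(w_max)
        self.rule = rule if rule is not None else SpikingBCMParams(A=0.0, r_theta=30.0)
        self.pools = {p.name: p for p in pools}
        self.projections = list(projections)
        self._seedseq = np.random.SeedSequence(seed)
        self._run_counter = 0

        # ---- neuron arrays
        N = sum(p.size for p in pools)
        self.n_neurons = N
        self._slices = {}
        self.kind = np.zeros(N, np.int8)
        self.pa = np.empty(N)
        self.pb = np.empty(N)
        self.pc = np.empty(N)
        self.pd = np.empty(N)
        self.gen_rate = np.zeros(N)
        self.ext_rate = np.zeros(N)
        self.ext_w = np.zeros(N)
        self.I_dc = np.zeros(N)
        off = 0
        for p in pools:
            sl = slice(off, off + p.size)
            self._slices[p.name] = sl
            if p.cell_kind == "poisson_generator":
                self.kind[sl] = 1
                self.gen_rate[sl] = p.rate
                self.pa[sl], self.pb[sl], self.pc[sl], self.pd[sl] = 1.0, 0.0, -65.0, 0.0
            else:
                prm = rs_params if p.cell_kind == "RS" else fs_params
                self.pa[sl], self.pb[sl] = prm.a, prm.b
                self.pc[sl], self.pd[sl] = prm.c, prm.d
            if p.external_drive is not None:
                self.ext_rate[sl] = p.external_drive.rate
                self.ext_w[sl] = p.external_drive.w_r
            off += p.size
        rest = np.array([
            IzhikevichParams(self.pa[i], self.pb[i], self.pc[i], self.pd[i]).rest_potential()
            if self.kind[i] == 0 else -65.0
            for i in range(N)
        ])
        self.V = rest.copy()
        self.u = self.pb * rest
        self.ge1 = np.zeros(N)
        self.ge2 = np.zeros(N)
        self.gi = np.zeros(N)
        self.gr = np.zeros(N)
        self.tr1 = np.zeros(N)
        self.tr2 = np.zeros(N)

        # ---- connectivity (deterministic under the seed)
        conn_rng = np.random.default_rng(self._seedseq.spawn(1)[0])
        pre_list, post_list, w_list, inh_list, plast_list, proj_id = [], [], [], [], [], []
        for pid, proj in enumerate(self.projections):
            if proj.src not in self.pools or proj.dst not in self.pools:
                raise ValueError(f"projection references unknown pool: {proj}")
            src_sl, dst_sl = self._slices[proj.src], self._slices[proj.dst]
            n_dst = dst_sl.stop - dst_sl.start
            k = int(round(proj.sparsity * n_dst))
            if k < 1:
                raise ValueError(
                    f"projection {proj.src}->{proj.dst}: sparsity*size(dst) < 1"
                )
            w = proj.total_conductance / k
            for i in range(src_sl.start, src_sl.stop):
                targets = conn_rng.choice(n_dst, size=k, replace=False) + dst_sl.start
                for t in np.sort(targets):
                    pre_list.append(i)
                    post_list.append(int(t))
                    w_list.append(w)
                    inh_list.append(1 if proj.sign == "inhibitory" else 0)
                    plast_list.append(1 if proj.plastic else 0)
                    proj_id.append(pid)
        order = np.lexsort((np.arange(len(pre_list)), np.array(pre_list)))
        self.syn_pre = np.array(pre_list, np.int64)[order]
        self.syn_post = np.array(post_list, np.int64)[order]
        self.syn_w = np.array(w_list, float)[order]
        self.syn_inh = np.array(inh_list, np.int8)[order]
        self.syn_plastic = np.array(plast_list, np.int8)[order]
        self.syn_proj = np.array(proj_id, np.int32)[order]
        self.syn_gate = np.ones(self.syn_w.size)
        self.syn_learn = self.syn_plastic.copy().astype(np.int8)
        self.out_ptr = np.searchsorted(self.syn_pre, np.arange(N + 1)).astype(np.int64)
        plastic_idx = np.flatnonzero(self.syn_plastic == 1).astype(np.int64)
        post_of_plastic = self.syn_post[plastic_idx]
        in_order = np.argsort(post_of_plastic, kind="stable")
        self.in_syn = plastic_idx[in_order]
        self.in_ptr = np.searchsorted(
            post_of_plastic[in_order], np.arange(N + 1)
        ).astype(np.int64)

        self.delay_steps = max(1, int(round(self.delay / dt)))
        self.ring = np.zeros((self.delay_steps, N), np.uint8)
        self.ring_pos = np.zeros(1, np.int64)
        self.time_ms = 0.0

    # ------------------------------------------------------------------
    def pool_slice(self, name: str) -> slice:
        return self._slices[name]

    def set_pool_rate(self, name: str, rate_hz: float):
        """Set the event rate of a Poisson-generator pool (Hz)."""
        if rate_hz < 0:
            raise ValueError("rate must be non-negative")
        sl = self._slices[name]
        if np.any(self.kind[sl] != 1):
            raise ValueError(f"pool {name!r} is not a generator pool")
        self.gen_rate[sl] = rate_hz

    def _proj_mask(self, src: str, dst: str) -> np.ndarray:
        pid = [
            i for i, p in enumerate(self.projections) if p.src == src and p.dst == dst
        ]
        if not pid:
            raise KeyError(f"no projection {src}->{dst}")
        return np.isin(self.syn_proj, pid)

    def set_gate(self, src: str, dst: str, active: bool):
        """Activate/inactivate a projection (synaptic gating, not rewiring)."""
        self.syn_gate[self._proj_mask(src, dst)] = 1.0 if active else 0.0

    def set_learn(self, src: str, dst: str, eligible: bool):
        """Mark a plastic projection (in)eligible for weight updates."""
        m = self._proj_mask(src, dst)
        self.syn_learn[m] = np.where(
            self.syn_plastic[m] == 1, np.int8(1 if eligible else 0), np.int8(0)
        )

    def plastic_weights(self, src: str, dst: str) -> np.ndarray:
        """Copy of the plastic weights of one projection."""
        m = self._proj_mask(src, dst) & (self.syn_plastic == 1)
        return self.syn_w[m].copy()

    def set_plastic_weights(self, src: str, dst: str, value):
        m = self._proj_mask(src, dst) & (self.syn_plastic == 1)
        self.syn_w[m] = value

    # ------------------------------------------------------------------
    def run(
        self,
        duration_ms: float,
        plasticity_on: bool = True,
        record_spikes: bool = False,
        max_recorded: int = 2_000_000,
    ) -> SimResult:
        """Advance the simulation by ``duration_ms`` and return counts."""
        n_steps = int(round(duration_ms / self.dt))
        rule = self.rule
        if isinstance(rule, SpikingBCMParams):
            code, A, r_theta, Am, Ap = _engine.RULE_BCM, rule.A, rule.r_theta, 0.0, 0.0
            kern = rule.kernel
            k1, k2 = 1000.0 / kern.tau, 0.0
            d1, d2 = np.exp(-self.dt / kern.tau), 1.0
        elif isinstance(rule, STDPiParams):
            code, A, r_theta, Am, Ap = _engine.RULE_STDPI, 0.0, 0.0, rule.Am, rule.Ap
            kern = rule.kernel
            k1 = k2 = 1000.0 / (kern.tau1 - kern.tau2)
            d1, d2 = np.exp(-self.dt / kern.tau1), np.exp(-self.dt / kern.tau2)
        else:
            raise TypeError("rule must be SpikingBCMParams or STDPiParams")
        seed = int(self._seedseq.spawn(1)[0].generate_state(1, np.uint32)[0] // 2)
        self._run_counter += 1
        counts = np.zeros(self.n_neurons, np.int64)
        cap = max_recorded if record_spikes else 0
        rec_neuron = np.empty(cap, np.int32)
        rec_step = np.empty(cap, np.int32)
        rec_n = np.zeros(1, np.int64)
        err, idx = _engine.run_steps(
            n_steps, self.dt, seed,
            self.kind, self.pa, self.pb, self.pc, self.pd,
            self.V, self.u, self.ge1, self.ge2, self.gi, self.gr,
            self.gen_rate, self.ext_rate, self.ext_w, self.I_dc,
            self.out_ptr, self.syn_pre, self.syn_post, self.syn_w,
            self.syn_inh, self.syn_plastic, self.syn_gate, self.syn_learn,
            self.in_ptr, self.in_syn,
            self.tr1, self.tr2,
            self.constants.tau_e1, self.constants.tau_e2, self.constants.tau_i,
            self.constants.Ee, self.constants.Ei, self.constants.Mg_ext,
            self.nmda_frac,
            self.vesicles.mean, self.vesicles.std,
            code, A, r_theta, Am, Ap,
            k1, k2, d1, d2,
            self.w_max,
            self.delay_steps, self.ring, self.ring_pos,
            1 if plasticity_on else 0,
            counts, rec_neuron, rec_step, rec_n,
        )
        if err == _engine.ERR_BLOWUP:
            raise NumericalBlowupError(int(idx))
        spikes = None
        if record_spikes:
            n = int(rec_n[0])
            spikes = np.column_stack(
                [rec_neuron[:n], self.time_ms + rec_step[:n] * self.dt]
            ).astype(float)
        self.time_ms += n_steps * self.dt
        return SimResult(counts=counts, duration_ms=n_steps * self.dt,
                         network=self, spikes=spikes)
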