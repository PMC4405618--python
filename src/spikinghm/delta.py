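"""The spiking delta-rule microcircuit.

One Helmholtz-machine unit is a microcircuit of six pools wired so
that a BCM-type plasticity rule on the inhibitory I->M synapses
realises the error-correcting delta rule on the unit's output rate:

* ``E`` (input) and ``T`` (target) are Poisson-generator pools;
* ``O`` (output, RS) carries the unit's value as its mean rate;
* ``M`` (comparison, RS) receives target excitation, input excitation
  and the plastic inhibition, and projects through the inhibitory
  relay ``D`` (FS) onto ``O``;
* ``I`` (FS) is driven by the input pool and is the presynaptic
  partner of the plastic synapses.

The fixed conductances are arranged so that (i) the direct T->O
excitation is cancelled by the indirect T->M->D->O inhibition, making
``rO`` insensitive to ``rT`` on short timescales, and (ii) the sign of
``rM - r_theta`` matches the sign of ``rT - rO``.  Under these
constraints the BCM drift ``dw/dt ~ rI rM (rM - r_theta)`` has the
sign of the delta rule ``eta rI (rT - rO)``, so training pulls ``rO``
toward ``rT``.  The shipped conductances were obtained with
:func:`calibrate_fixed_weights` (grid search plus coordinate
refinement); they can be recalibrated for other pool sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import PoolSpec, ProjectionSpec, SpikingNetwork
from .neurons import ExternalDrive
from .plasticity import SpikingBCMParams, STDPiParams, match_amplitudes

__all__ = [
    "DeltaCircuitConfig",
    "build_delta_network",
    "run_delta",
    "calibrate_fixed_weights",
    "delta_experiment",
    "DEFAULT_CONDUCTANCES",
]

#: Fixed conductances (nS per presynaptic neuron) of the microcircuit,
#: from the shipped calibration at the default pool sizes and drives.
DEFAULT_CONDUCTANCES = {
    "TO": 0.18,
    "TM": 0.09,
    "EM": 0.15,
    "EI": 0.05,
    "MD": 0.04,
    "DO": 1.8,
}

#: Default BCM threshold rate (Hz) targeted by the calibration.
DEFAULT_R_THETA = 30.0

#: Default learning-rate amplitude (nS per Hz^2 per event) giving
#: convergence within tens of seconds of training.
DEFAULT_ETA = 2e-6


@dataclass(frozen=True)
class DeltaCircuitConfig:
    """Sizes, drives and plasticity configuration of one circuit."""

    n_generators: int = 20
    n_rs: int = 20
    n_fs: int = 10
    sparsity: float = 0.3
    conductances: dict = field(default_factory=lambda: dict(DEFAULT_CONDUCTANCES))
    drive_o: ExternalDrive = ExternalDrive(100.0, 0.6)
    drive_m: ExternalDrive = ExternalDrive(100.0, 0.42)
    r_theta: float = DEFAULT_R_THETA
    eta: float = DEFAULT_ETA
    rule: str = "bcm"
    bcm_tau: float = 50.0
    stdpi_tau1: float = 50.0
    stdpi_tau2: float = 20.0
    w_start: float = 0.6
    w_max: float = 4.0
    dt: float = 0.1


def _make_rule(cfg: DeltaCircuitConfig):
    bcm, stdpi = match_amplitudes(
        cfg.eta, cfg.r_theta, cfg.bcm_tau, cfg.stdpi_tau1, cfg.stdpi_tau2
    )
    if cfg.rule == "bcm":
        return bcm
    if cfg.rule == "stdpi":
        return stdpi
    raise ValueError("rule must be 'bcm' or 'stdpi'")


def build_delta_network(cfg: DeltaCircuitConfig = DeltaCircuitConfig(), seed: int = 0) -> SpikingNetwork:
    """Construct one delta-rule circuit (deterministic under ``seed``).

    The plastic I->M projection starts with per-source total
    conductance ``w_start``; all other projections are fixed.
    """
    g = cfg.conductances
    pools = [
        PoolSpec("E", cfg.n_generators, "poisson_generator", rate=20.0),
        PoolSpec("T", cfg.n_generators, "poisson_generator", rate=20.0),
        PoolSpec("O", cfg.n_rs, "RS", external_drive=cfg.drive_o),
        PoolSpec("M", cfg.n_rs, "RS", external_drive=cfg.drive_m),
        PoolSpec("D", cfg.n_fs, "FS"),
        PoolSpec("I", cfg.n_fs, "FS"),
    ]
    s = cfg.sparsity
    projs = [
        ProjectionSpec("T", "O", s, g["TO"], "excitatory"),
        ProjectionSpec("T", "M", s, g["TM"], "excitatory"),
        ProjectionSpec("E", "M", s, g["EM"], "excitatory"),
        ProjectionSpec("E", "I", s, g["EI"], "excitatory"),
        ProjectionSpec("M", "D", s, g["MD"], "excitatory"),
        ProjectionSpec("D", "O", s, g["DO"], "inhibitory"),
        ProjectionSpec("I", "M", s, cfg.w_start, "inhibitory", plastic=True),
    ]
    return SpikingNetwork(
        pools, projs, rule=_make_rule(cfg), dt=cfg.dt, seed=seed, w_max=cfg.w_max
    )


def run_delta(
    network: SpikingNetwork,
    rE: float,
    rT: float,
    duration_s: float,
    plasticity_on: bool,
    settle_ms: float = 500.0,
):
    """Run the circuit at fixed input/target rates and read pool rates.

    Returns a dict of mean pool rates over the measurement window
    (after a settling period during which plasticity follows the same
    on/off setting).  With plasticity off the plastic weights are
    frozen exactly.
    """
    if rE < 0 or rT < 0:
        raise ValueError("rates must be non-negative")
    network.set_pool_rate("E", rE)
    network.set_pool_rate("T", rT)
    if settle_ms > 0:
        network.run(settle_ms, plasticity_on=plasticity_on)
    res = network.run(duration_s * 1000.0, plasticity_on=plasticity_on)
    return {p: res.pool_rate(p) for p in ("E", "T", "O", "M", "D", "I")}


def calibrate_fixed_weights(
    cfg: DeltaCircuitConfig,
    rT_grid=(0.0, 15.0, 30.0, 45.0, 60.0),
    w_grid=(0.2, 0.6, 1.0, 1.6),
    seed: int = 0,
    probe_s: float = 1.5,
    refine_iters: int = 2,
    refine_factors=(0.8, 1.25),
    keys=("DO", "TO"),
) -> dict:
    """Coordinate refinement of the fixed conductances.

    Scores a conductance set by the fraction of probe points
    (``rT_grid`` x ``w_grid``) on which ``sign(rM - r_theta) ==
    sign(rT - rO)``, requiring additionally that ``rO`` increases with
    the plastic weight.  Starting from ``cfg.conductances``, each key
    in ``keys`` is scaled by the candidate factors and the best scoring
    set is kept.  Deterministic given ``seed`` and the grids.  Returns
    the refined conductance dict with the achieved score under
    ``"score"``.
    """

    def score(g):
        agree = 0
        total = 0
        mono_ok = True
        for rT in rT_grid:
            prev_o = -np.inf
            for w in w_grid:
                c2 = DeltaCircuitConfig(
                    **{**cfg.__dict__, "conductances": dict(g), "w_start": w}
                )
                net = build_delta_network(c2, seed=seed)
                rates = run_delta(net, 20.0, rT, probe_s, plasticity_on=False)
                total += 1
                if (rates["M"] - cfg.r_theta) * (rT - rates["O"]) > 0:
                    agree += 1
                if rates["O"] < prev_o - 3.0:  # allow sampling noise
                    mono_ok = False
                prev_o = rates["O"]
        frac = agree / total
        return frac if mono_ok else frac - 1.0

    best = dict(cfg.conductances)
    best_score = score(best)
    for _ in range(refine_iters):
        improved = False
        for key in keys:
            for f in refine_factors:
                cand = dict(best)
                cand[key] = best[key] * f
                sc = score(cand)
                if sc > best_score:
                    best, best_score, improved = cand, sc, True
        if not improved:
            break
    out = dict(best)
    out["score"] = best_score
    return out


def delta_experiment(
    rule: str,
    rT_grid,
    w_start_grid,
    n_instantiations: int,
    train_duration_s: float = 50.0,
    test_duration_s: float = 5.0,
    rE: float = 20.0,
    cfg: DeltaCircuitConfig | None = None,
    seed: int = 0,
    log_weights: bool = True,
):
    """Train a grid of structurally identical circuits and measure tracking.

    For every (``rT``, ``w_start``) cell and every connectivity
    instantiation, a fresh circuit is trained at fixed ``rE`` and
    ``rT`` for ``train_duration_s``, then tested with plasticity off.
    Returns a dict with the pre- and post-training output rates, the
    per-``rT`` mean absolute deviation ``|rT - rO|`` (averaged over
    ``w_start`` and instantiations), and per-cell mean plastic-weight
    trajectories sampled once per second.
    """
    if cfg is None:
        cfg = DeltaCircuitConfig()
    rT_grid = np.asarray(rT_grid, dtype=float)
    w_grid = np.asarray(w_start_grid, dtype=float)
    if rT_grid.size == 0 or w_grid.size == 0:
        raise ValueError("grids must be non-empty")
    shape = (rT_grid.size, w_grid.size, n_instantiations)
    rO_pre = np.zeros(shape)
    rO_post = np.zeros(shape)
    n_chunks = max(1, int(round(train_duration_s)))
    w_traj = np.zeros(shape + (n_chunks + 1,)) if log_weights else None
    for a, rT in enumerate(rT_grid):
        for b, w0 in enumerate(w_grid):
            for k in range(n_instantiations):
                c2 = DeltaCircuitConfig(
                    **{**cfg.__dict__, "rule": rule, "w_start": float(w0)}
                )
                net = build_delta_network(c2, seed=seed + 1000 * k)
                rates = run_delta(net, rE, rT, test_duration_s, plasticity_on=False)
                rO_pre[a, b, k] = rates["O"]
                net.set_pool_rate("E", rE)
                net.set_pool_rate("T", rT)
                if log_weights:
                    w_traj[a, b, k, 0] = net.plastic_weights("I", "M").mean()
                chunk_ms = train_duration_s * 1000.0 / n_chunks
                for c in range(n_chunks):
                    net.run(chunk_ms, plasticity_on=True)
                    if log_weights:
                        w_traj[a, b, k, c + 1] = net.plastic_weights("I", "M").mean()
                rates = run_delta(net, rE, rT, test_duration_s, plasticity_on=False)
                rO_post[a, b, k] = rates["O"]
    dev_pre = np.mean(np.abs(rT_grid[:, None, None] - rO_pre), axis=(1, 2))
    dev_post = np.mean(np.abs(rT_grid[:, None, None] - rO_post), axis=(1, 2))
    return {
        "rT_grid": rT_grid,
        "w_start_grid": w_grid,
        "rO_pre": rO_pre,
        "rO_post": rO_post,
        "deviation_pre": dev_pre,
        "deviation_post": dev_post,
        "weight_traj": w_traj,
    }
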