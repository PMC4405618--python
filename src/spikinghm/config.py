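"""Experiment configuration, seeding and orchestration.

An :class:`ExperimentConfig` names a protocol, the rule/dataset/prior
choice and any parameter overrides, plus a master seed.  Every random
draw inside a run comes from a named substream spawned from that seed,
so the same config and seed reproduce byte-identical result tables.
``run_experiment`` dispatches to the library and writes CSV results
together with the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as data_mod
from . import metrics
from .delta import DeltaCircuitConfig, delta_experiment
from .rate_hm import RateHMParams, generate_samples, recognize_samples, train_rate_hm

__all__ = ["ExperimentConfig", "load_config", "run_experiment", "seed_stream"]

_PROTOCOLS = (
    "delta",
    "rate_generative",
    "rate_decoding",
    "rate_reward",
    "plasticity_surface",
    "tau2_delta",
    "sleep_improvement",
    "hm_generative",
)

_REQUIRED = ("name", "protocol", "seed")


@dataclass
class ExperimentConfig:
    """A fully specified, reproducible experiment."""

    name: str
    protocol: str
    seed: int
    rule: str = "bcm"
    dataset: str = "a"
    prior: str = ""  # empty: the conventional prior for the dataset
    n_phases: int = 50_000
    n_samples: int = 2000
    train_duration_s: float = 20.0
    rt_grid: tuple = (10.0, 30.0, 50.0)
    w_start_grid: tuple = (0.3, 0.6, 1.0)
    n_instantiations: int = 1
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.protocol not in _PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; choose from {_PROTOCOLS}"
            )

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML/JSON config file.

    Missing required keys raise a ``ValueError`` naming the key;
    unknown keys raise as well (typo protection).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    for key in _REQUIRED:
        if key not in raw:
            raise ValueError(f"missing required config key: {key!r}")
    valid = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw = dict(raw)
    for tup_key in ("rt_grid", "w_start_grid"):
        if tup_key in raw:
            raw[tup_key] = tuple(raw[tup_key])
    return ExperimentConfig(**raw)


def seed_stream(master_seed: int, component: str) -> np.random.Generator:
    """Named, reproducible substream of the master seed."""
    h = np.frombuffer(component.encode(), dtype=np.uint8).sum()
    ss = np.random.SeedSequence([int(master_seed), int(h)], spawn_key=(len(component),))
    return np.random.default_rng(ss)


def _dataset_and_prior(cfg: ExperimentConfig, rng):
    ds = data_mod.make_dataset(cfg.dataset, cfg.n_samples, rng)
    prior = (
        data_mod.default_prior_for(cfg.dataset)
        if not cfg.prior
        else getattr(data_mod, f"{cfg.prior}_prior")()
    )
    return ds, prior


def run_experiment(cfg: ExperimentConfig, out_dir) -> dict:
    """Execute the named protocol and write results under ``out_dir``.

    Returns a summary dict (also serialised to ``summary.json``); the
    resolved config is written alongside every output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.resolved()}

    if cfg.protocol == "delta":
        res = delta_experiment(
            cfg.rule,
            cfg.rt_grid,
            cfg.w_start_grid,
            cfg.n_instantiations,
            train_duration_s=cfg.train_duration_s,
            seed=cfg.seed,
        )
        df = pd.DataFrame(
            {
                "rT": res["rT_grid"],
                "deviation_pre": res["deviation_pre"],
                "deviation_post": res["deviation_post"],
            }
        )
        df.to_csv(out / "deviation.csv", index=False)
        summary["mean_deviation_post"] = float(res["deviation_post"].mean())
        summary["mean_deviation_pre"] = float(res["deviation_pre"].mean())

    elif cfg.protocol == "rate_generative":
        rng = seed_stream(cfg.seed, "data")
        ds, prior = _dataset_and_prior(cfg, rng)
        params, _ = train_rate_hm(
            ds.samples, prior, cfg.n_phases, rule=cfg.rule if cfg.rule in ("exact", "approx") else "approx",
            rng=seed_stream(cfg.seed, "train"),
        )
        gen = generate_samples(params, prior, cfg.n_samples, seed_stream(cfg.seed, "test"))
        d = metrics.js_divergence(
            metrics.Histogram2D.from_samples(gen),
            metrics.Histogram2D.from_samples(ds.samples),
        )
        pd.DataFrame(gen, columns=["y1", "y2"]).to_csv(out / "generative_samples.csv", index=False)
        summary["js_divergence"] = d

    elif cfg.protocol == "rate_decoding":
        rng = seed_stream(cfg.seed, "data")
        ds = data_mod.make_dataset("o", cfg.n_samples, rng)
        prior = data_mod.line_prior()
        params, _ = train_rate_hm(
            ds.samples, prior, cfg.n_phases, rule="approx",
            rng=seed_stream(cfg.seed, "train"),
        )
        x = recognize_samples(params, ds.samples, seed_stream(cfg.seed, "test"))
        c_hat = metrics.decode_position(x, "decoding")
        dev = metrics.mean_deviation(c_hat, ds.labels)
        pd.DataFrame({"C": ds.labels, "C_hat": c_hat}).to_csv(out / "decoding.csv", index=False)
        summary["mean_deviation"] = dev

    elif cfg.protocol == "rate_reward":
        r1 = float(cfg.overrides.get("r1", 0.5))
        spec = metrics.RewardSpec(r1=r1, r2=1.0 - r1)
        rng = seed_stream(cfg.seed, "data")
        ds = data_mod.make_dataset("r", cfg.n_samples, rng)
        prior = data_mod.reward_prior(spec.r1, spec.r2)
        params, _ = train_rate_hm(
            ds.samples, prior, cfg.n_phases, rule="approx",
            rng=seed_stream(cfg.seed, "train"),
        )
        x = recognize_samples(params, ds.samples, seed_stream(cfg.seed, "test"))
        c_hat = metrics.decode_position(x, "reward")
        fit = metrics.fit_logistic(ds.labels, c_hat > 0)
        res = metrics.reward_analysis(c_hat, ds.labels, spec, fit)
        summary.update({"mu": fit.mu, "s": fit.s, **res})
        pd.DataFrame({"C": ds.labels, "C_hat": c_hat}).to_csv(out / "reward.csv", index=False)

    elif cfg.protocol == "plasticity_surface":
        from .plasticity import match_amplitudes, rule_surface

        bcm, stdpi = match_amplitudes(1e-4, 30.0, stdpi_tau2=float(cfg.overrides.get("tau2", 20.0)))
        rule = bcm if cfg.rule == "bcm" else stdpi
        rates = np.asarray(cfg.rt_grid, dtype=float)
        mean, sem = rule_surface(rule, rates, rates, duration=cfg.train_duration_s,
                                 rng=seed_stream(cfg.seed, "surface"))
        rows = [
            {"r_pre": rp, "r_post": rq, "dwdt_mean": mean[i, j], "dwdt_sem": sem[i, j]}
            for i, rp in enumerate(rates)
            for j, rq in enumerate(rates)
        ]
        pd.DataFrame(rows).to_csv(out / "surface.csv", index=False)
        summary["max_abs_dwdt"] = float(np.abs(mean).max())

    elif cfg.protocol == "tau2_delta":
        from .metrics import tau2_sweep

        tau2_values = tuple(cfg.overrides.get("tau2_values", (1.0, 10.0, 30.0)))

        def experiment(tau2, seed):
            res = delta_experiment(
                "stdpi", cfg.rt_grid, cfg.w_start_grid, 1,
                train_duration_s=cfg.train_duration_s,
                cfg=DeltaCircuitConfig(stdpi_tau2=tau2),
                seed=cfg.seed + seed,
            )
            return float(res["deviation_post"].mean())

        mean, sem = tau2_sweep(tau2_values, experiment, cfg.n_instantiations)
        pd.DataFrame(
            {"tau2_ms": tau2_values, "deviation_mean": mean, "deviation_sem": sem}
        ).to_csv(out / "tau2_sweep.csv", index=False)
        summary["deviation_by_tau2"] = dict(zip(map(float, tau2_values), map(float, mean)))

    elif cfg.protocol == "sleep_improvement":
        from .metrics import sleep_improvement_experiment

        rng = seed_stream(cfg.seed, "data")
        ds = data_mod.make_dataset("o", cfg.n_samples, rng)
        checkpoints = tuple(cfg.overrides.get("checkpoints", (8000, 60_000)))
        params = RateHMParams(
            Sigma=float(cfg.overrides.get("sigma2", 9.0)) * np.eye(2),
            eta=3e-5, eta_b=3e-5, W_R=0.05 * np.eye(2),
        )
        rows = sleep_improvement_experiment(
            ds, data_mod.line_prior(), checkpoints,
            rng=seed_stream(cfg.seed, "train"), params=params,
            sleep_phases=int(cfg.overrides.get("sleep_phases", 10_000)),
        )
        pd.DataFrame(rows, columns=["checkpoint", "dev_before", "dev_after"]).to_csv(
            out / "sleep_improvement.csv", index=False
        )
        summary["improvements"] = [float(b - a) for _, b, a in rows]

    elif cfg.protocol == "hm_generative":
        from .helmholtz import HMConfig, PhaseSchedule, build_hm_network, collect_samples, train_wake_sleep

        rng = seed_stream(cfg.seed, "data")
        ds = data_mod.make_dataset(cfg.dataset, 500, rng)
        scale = 3.0 if cfg.rule == "stdpi" else 1.0
        prior = data_mod.default_prior_for(cfg.dataset, scale)
        hm = build_hm_network(HMConfig(rule=cfg.rule), seed=cfg.seed)
        train_wake_sleep(
            hm, ds, prior,
            PhaseSchedule(total_s=float(cfg.overrides.get("total_s", 450.0))),
            rng=seed_stream(cfg.seed, "train"),
        )
        gen = collect_samples(
            hm, "generative", min(cfg.n_samples, 2000), prior,
            rng=seed_stream(cfg.seed, "test"),
        )
        pd.DataFrame(gen, columns=["y1", "y2"]).to_csv(out / "generative_samples.csv", index=False)
        summary["js_divergence"] = metrics.js_divergence(
            metrics.Histogram2D.from_samples(gen),
            metrics.Histogram2D.from_samples(ds.samples),
        )

    (out / "config.yaml").write_text(yaml.safe_dump(cfg.resolved()))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
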