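"""Spike-driven plasticity rules and artificial spike-train experiments.

Two rules adjust an inhibitory synaptic weight so that, for Poisson
pre-/post-synaptic activity, the expected drift follows the rate-based
BCM form ``dw/dt = eta * r_pre * r_post * (r_post - r_theta)``:

* **Spiking BCM** — at every *pre*-synaptic spike,
  ``w += A * r_post_hat * (r_post_hat - r_theta)``, with the
  post-synaptic rate estimated by an exponential-kernel trace.  Nothing
  happens at post-synaptic spikes.
* **STDPi** (spike-timing-dependent plasticity of inhibition) — at
  pre-synaptic spikes ``w -= Am * r_post_hat``; at post-synaptic spikes
  ``w += Ap * r_pre_hat * r_post_hat``, with both rates estimated by
  difference-of-exponential traces.

Weights are clipped at zero.  Traces are read just before the
triggering spike's own contribution is added.

For independent Poisson trains the STDPi drift is exactly
``r_pre * r_post * (Ap * r_post - Am)``; the Spiking BCM drift is
``A * r_pre * r_post * (r_post + k2 - r_theta)`` where
``k2 = integral kappa^2`` is the trace's variance-per-rate (the
quadratic term of a *single* trace is biased upward by its variance).
:func:`match_amplitudes` accounts for both facts so that the two rules
realise the same effective BCM threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .kernels import KernelSpec, trace_at_times

__all__ = [
    "SpikingBCMParams",
    "STDPiParams",
    "CorrelatedTrainSpec",
    "bcm_on_pre",
    "stdpi_update",
    "match_amplitudes",
    "expected_poisson_dwdt",
    "measure_dwdt",
    "rule_surface",
    "correlated_trains",
    "nullcline_crossings",
    "stationary_post_rate",
]


@dataclass(frozen=True)
class SpikingBCMParams:
    """Amplitude ``A`` and threshold rate ``r_theta`` (Hz) of Spiking BCM."""

    A: float
    r_theta: float
    kernel: KernelSpec = KernelSpec("exponential", tau=50.0)

    def __post_init__(self):
        if self.r_theta <= 0:
            raise ValueError("r_theta must be positive")


@dataclass(frozen=True)
class STDPiParams:
    """Depression (``Am``) and potentiation (``Ap``) amplitudes of STDPi."""

    Am: float
    Ap: float
    kernel: KernelSpec = KernelSpec("diff_of_exponentials", tau1=50.0, tau2=20.0)

    def __post_init__(self):
        if self.Am < 0 or self.Ap < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class CorrelatedTrainSpec:
    """Parameters of the correlated pre/post artificial spike trains.

    The pre train is homogeneous Poisson at ``r_pre``; the post train is
    inhomogeneous Poisson with intensity
    ``max(0, r_base + dr * sum_i exp(-(t - t_i)/tau_r))`` where ``t_i``
    are the pre-spike times.  Negative ``dr`` makes the post train dip
    after each pre spike (the regime created by an inhibitory synapse).
    """

    r_pre: float = 30.0
    r_base: float = 30.0
    dr: float = -30.0
    tau_r: float = 10.0
    duration: float = 100.0  # seconds

    def __post_init__(self):
        if self.duration <= 0 or self.tau_r <= 0:
            raise ValueError("duration and tau_r must be positive")


def bcm_on_pre(w: float, r_post_hat: float, p: SpikingBCMParams) -> float:
    """Spiking BCM update applied at one pre-synaptic spike."""
    if w < 0:
        raise ValueError("weight must be non-negative")
    return max(0.0, w + p.A * r_post_hat * (r_post_hat - p.r_theta))


def stdpi_update(
    event: str, w: float, r_pre_hat: float, r_post_hat: float, p: STDPiParams
) -> float:
    """STDPi update at one ``"pre"`` or ``"post"`` synaptic event."""
    if w < 0:
        raise ValueError("weight must be non-negative")
    if event == "pre":
        return max(0.0, w - p.Am * r_post_hat)
    if event == "post":
        return max(0.0, w + p.Ap * r_pre_hat * r_post_hat)
    raise ValueError("event must be 'pre' or 'post'")


def match_amplitudes(
    eta: float,
    r_theta: float,
    bcm_tau: float = 50.0,
    stdpi_tau1: float = 50.0,
    stdpi_tau2: float = 20.0,
) -> tuple[SpikingBCMParams, STDPiParams]:
    """Parameter sets under which both rules realise the same BCM drift.

    Targets ``dw/dt = eta * r_pre * r_post * (r_post - r_theta)`` for
    independent Poisson trains.  ``Ap = eta`` and ``Am = eta * r_theta``
    make STDPi exact.  The Spiking BCM threshold parameter is set to
    ``r_theta + 1/(2 tau)`` to cancel the variance bias of squaring a
    single trace, so its *effective* threshold is ``r_theta`` as well.
    The correspondence is verified empirically in the test suite rather
    than assumed.
    """
    bcm_kernel = KernelSpec("exponential", tau=bcm_tau)
    bcm = SpikingBCMParams(
        A=eta, r_theta=r_theta + bcm_kernel.sq_integral, kernel=bcm_kernel
    )
    stdpi = STDPiParams(
        Am=eta * r_theta,
        Ap=eta,
        kernel=KernelSpec("diff_of_exponentials", tau1=stdpi_tau1, tau2=stdpi_tau2),
    )
    return bcm, stdpi


def expected_poisson_dwdt(r_pre: float, r_post: float, rule) -> float:
    """Closed-form expected drift (weight units per second) for
    independent Poisson pre/post trains — the analytic oracle for
    :func:`measure_dwdt`."""
    if isinstance(rule, SpikingBCMParams):
        k2 = rule.kernel.sq_integral
        return rule.A * r_pre * r_post * (r_post + k2 - rule.r_theta)
    if isinstance(rule, STDPiParams):
        return r_pre * r_post * (rule.Ap * r_post - rule.Am)
    raise TypeError("rule must be SpikingBCMParams or STDPiParams")


def measure_dwdt(pre_times, post_times, rule, duration_s: float) -> float:
    """Net drift of a synapse driven by given spike trains (per second).

    Accumulates the raw rule increments without the zero floor (the
    floor is a property of an actual synapse, not of the drift being
    measured), divided by the train duration in seconds.  Times in ms.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    total = 0.0
    if isinstance(rule, SpikingBCMParams):
        r_post = trace_at_times(post, rule.kernel, pre)
        total = float(np.sum(rule.A * r_post * (r_post - rule.r_theta)))
    elif isinstance(rule, STDPiParams):
        r_post_at_pre = trace_at_times(post, rule.kernel, pre)
        total -= rule.Am * float(np.sum(r_post_at_pre))
        r_pre_at_post = trace_at_times(pre, rule.kernel, post)
        r_post_at_post = trace_at_times(post, rule.kernel, post)
        total += rule.Ap * float(np.sum(r_pre_at_post * r_post_at_post))
    else:
        raise TypeError("rule must be SpikingBCMParams or STDPiParams")
    return total / duration_s


def _poisson_train(rate_hz: float, duration_ms: float, rng) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def rule_surface(
    rule,
    rates_pre,
    rates_post,
    duration: float = 60.0,
    reps: int = 3,
    rng=None,
):
    """Mean drift ``dw/dt`` over a grid of uncorrelated Poisson rates.

    Simulates ``reps`` independent pre/post Poisson train pairs per
    (``r_pre``, ``r_post``) cell for ``duration`` seconds each and
    applies the rule.  Returns ``(mean, sem)`` arrays of shape
    ``(len(rates_pre), len(rates_post))``.
    """
    rng = np.random.default_rng(rng)
    rates_pre = np.asarray(rates_pre, dtype=float)
    rates_post = np.asarray(rates_post, dtype=float)
    if np.any(rates_pre < 0) or np.any(rates_post < 0):
        raise ValueError("rates must be non-negative")
    positive = rates_pre[rates_pre > 0]
    if positive.size and duration * positive.min() < 1:
        warnings.warn("duration too short for one expected pre spike")
    mean = np.zeros((rates_pre.size, rates_post.size))
    sem = np.zeros_like(mean)
    dur_ms = duration * 1000.0
    for i, rp in enumerate(rates_pre):
        for j, rq in enumerate(rates_post):
            vals = np.array(
                [
                    measure_dwdt(
                        _poisson_train(rp, dur_ms, rng),
                        _poisson_train(rq, dur_ms, rng),
                        rule,
                        duration,
                    )
                    for _ in range(reps)
                ]
            )
            mean[i, j] = vals.mean()
            sem[i, j] = vals.std(ddof=1) / np.sqrt(reps) if reps > 1 else np.nan
    return mean, sem


def correlated_trains(spec: CorrelatedTrainSpec, rng=None, dt: float = 0.1):
    """Generate a correlated pre/post spike-train pair.

    The post intensity is computed on a ``dt``-ms grid by exponential
    filtering of the pre train (one kick of height ``dr`` decaying with
    ``tau_r`` per pre spike) and the post train is drawn as a Bernoulli
    approximation of the inhomogeneous Poisson process (valid for rates
    well below ``1/dt``).

    Returns ``(pre_times, post_times, mean_intensity)`` with times in ms
    and the time-averaged post intensity in Hz.
    """
    rng = np.random.default_rng(rng)
    dur_ms = spec.duration * 1000.0
    n_bins = int(round(dur_ms / dt))
    pre = _poisson_train(spec.r_pre, dur_ms, rng)
    bins = np.zeros(n_bins)
    idx = np.minimum((pre / dt).astype(np.int64), n_bins - 1)
    np.add.at(bins, idx, 1.0)
    decay = np.exp(-dt / spec.tau_r)
    kicks = lfilter([1.0], [1.0, -decay], bins)
    intensity = np.maximum(0.0, spec.r_base + spec.dr * kicks)
    post_mask = rng.random(n_bins) < intensity * dt / 1000.0
    post = (np.flatnonzero(post_mask) + 0.5) * dt
    return pre, post, float(intensity.mean())


def nullcline_crossings(rates_post, dwdt_row) -> list[float]:
    """Post-rates where a drift profile crosses zero (linear interpolation).

    ``dwdt_row`` is the drift along increasing ``rates_post`` at fixed
    ``r_pre``.  Zero entries count as crossings at their own rate.
    """
    rates_post = np.asarray(rates_post, dtype=float)
    row = np.asarray(dwdt_row, dtype=float)
    out = []
    for k in range(row.size - 1):
        a, b = row[k], row[k + 1]
        if a == 0.0:
            out.append(float(rates_post[k]))
        elif a * b < 0:
            frac = a / (a - b)
            out.append(float(rates_post[k] + frac * (rates_post[k + 1] - rates_post[k])))
    if row.size and row[-1] == 0.0:
        out.append(float(rates_post[-1]))
    return out


def stationary_post_rate(
    rule,
    r_pre: float,
    r_base_grid,
    rng=None,
    correlation: CorrelatedTrainSpec | None = None,
    duration: float = 100.0,
    reps: int = 2,
) -> float:
    """Post rate at which the mean drift vanishes (``dw/dt = 0`` nullcline).

    Scans ``r_base_grid``; for each base rate, generates trains (either
    uncorrelated Poisson, or correlated per ``correlation`` with its
    ``r_base`` replaced) and measures the mean drift.  Returns the post
    rate of the first zero crossing, interpolated linearly.
    """
    rng = np.random.default_rng(rng)
    post_rates, drifts = [], []
    for r_base in r_base_grid:
        vals, rates = [], []
        for _ in range(reps):
            if correlation is None:
                dur_ms = duration * 1000.0
                pre = _poisson_train(r_pre, dur_ms, rng)
                post = _poisson_train(r_base, dur_ms, rng)
                rates.append(r_base)
                vals.append(measure_dwdt(pre, post, rule, duration))
            else:
                spec = CorrelatedTrainSpec(
                    r_pre=r_pre,
                    r_base=r_base,
                    dr=correlation.dr,
                    tau_r=correlation.tau_r,
                    duration=duration,
                )
                pre, post, mean_rate = correlated_trains(spec, rng)
                rates.append(mean_rate)
                vals.append(measure_dwdt(pre, post, rule, duration))
        post_rates.append(float(np.mean(rates)))
        drifts.append(float(np.mean(vals)))
    crossings = nullcline_crossings(post_rates, drifts)
    if not crossings:
        raise RuntimeError("no nullcline crossing inside the scanned range")
    return crossings[0]
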