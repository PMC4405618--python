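"""Spike-train filtering kernels and online rate traces.

A rate trace is a causal, kernel-filtered view of a spike train,

    r_hat(t) = sum_j kappa(t - t_j),

with a kernel that is zero for ``t < 0`` and integrates to exactly one
(over time in seconds), so the trace of a Poisson train is an unbiased
estimate of its rate in Hz.  Two kernel families are supported:

* ``exponential``: ``kappa(t) = (1/tau) exp(-t/tau)`` — used by the
  Spiking BCM rule;
* ``diff_of_exponentials``: ``kappa(t) = (exp(-t/tau1) - exp(-t/tau2))
  / (tau1 - tau2)`` — used by STDPi.  ``tau2`` shapes an initial dip
  that de-emphasises the most recent spikes.

Time constants are stored in ms; trace values are in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["KernelSpec", "RateTrace", "trace_value", "trace_at_times"]


@dataclass(frozen=True)
class KernelSpec:
    """Shape of the rate-estimation kernel.

    Parameters
    ----------
    kind:
        ``"exponential"`` or ``"diff_of_exponentials"``.
    tau:
        Decay constant (ms) of the exponential kernel.
    tau1, tau2:
        Slow and fast constants (ms) of the difference kernel; requires
        ``tau1 > tau2 > 0`` (equal constants are degenerate).
    """

    kind: str = "exponential"
    tau: float = 50.0
    tau1: float = 50.0
    tau2: float = 20.0

    def __post_init__(self):
        if self.kind == "exponential":
            if self.tau <= 0:
                raise ValueError("tau must be positive")
        elif self.kind == "diff_of_exponentials":
            if not (self.tau1 > self.tau2 > 0):
                raise ValueError("need tau1 > tau2 > 0")
        else:
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    def __call__(self, t):
        """Kernel value at lag ``t`` (ms), in Hz (i.e. 1/s)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "exponential":
            v = np.where(t >= 0, 1000.0 / self.tau * np.exp(-t / self.tau), 0.0)
        else:
            v = np.where(
                t >= 0,
                1000.0 / (self.tau1 - self.tau2)
                * (np.exp(-t / self.tau1) - np.exp(-t / self.tau2)),
                0.0,
            )
        return v if v.ndim else float(v)

    @property
    def sq_integral(self) -> float:
        """``integral kappa(t)^2 dt`` in Hz.

        Equals ``1/(2 tau)`` for the exponential kernel and
        ``1/(2 (tau1 + tau2))`` for the difference kernel (with taus in
        seconds).  This is the variance-per-rate of the trace and enters
        the expected drift of quadratic plasticity rules.
        """
        if self.kind == "exponential":
            return 1000.0 / (2.0 * self.tau)
        return 1000.0 / (2.0 * (self.tau1 + self.tau2))


@njit(cache=True)
def _exp_sums(src, query, tau):
    """sum over src spikes t_j < t_q of exp(-(t_q - t_j)/tau), per query."""
    out = np.zeros(query.size)
    state = 0.0
    j = 0
    t_last = 0.0
    for k in range(query.size):
        tq = query[k]
        while j < src.size and src[j] < tq:
            state = state * np.exp(-(src[j] - t_last) / tau) + 1.0
            t_last = src[j]
            j += 1
        out[k] = state * np.exp(-(tq - t_last) / tau)
    return out


def trace_at_times(spike_times, kernel: KernelSpec, query_times):
    """Trace of ``spike_times`` evaluated at each query time (Hz).

    Spikes exactly at a query time are excluded (the trace is read "just
    before" the event), which prevents a spike from interacting with its
    own kernel contribution.  Both time arrays must be sorted.
    """
    src = np.ascontiguousarray(spike_times, dtype=float)
    query = np.ascontiguousarray(query_times, dtype=float)
    if np.any(np.diff(src) < 0) or np.any(np.diff(query) < 0):
        raise ValueError("spike and query times must be sorted")
    if kernel.kind == "exponential":
        return 1000.0 / kernel.tau * _exp_sums(src, query, kernel.tau)
    s1 = _exp_sums(src, query, kernel.tau1)
    s2 = _exp_sums(src, query, kernel.tau2)
    return 1000.0 / (kernel.tau1 - kernel.tau2) * (s1 - s2)


def trace_value(spike_times, kernel: KernelSpec, t: float) -> float:
    """Direct evaluation of ``sum_j kappa(t - t_j)`` at a single time.

    Reference implementation by explicit summation; the event-driven
    path (:func:`trace_at_times`, :class:`RateTrace`) must agree with it
    to 1e-9 relative error.
    """
    times = np.asarray(spike_times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    if times.size == 0:
        return 0.0
    return float(np.sum(kernel(t - times)))


class RateTrace:
    """Event-driven online rate estimate of a single spike train.

    Maintains the exponential components of the kernel so that
    ``value(t)`` equals :func:`trace_value` up to floating-point error
    with O(1) work per event.
    """

    def __init__(self, kernel: KernelSpec):
        self.kernel = kernel
        self._s1 = 0.0  # slow (or only) component
        self._s2 = 0.0  # fast component (difference kernel only)
        self._t = 0.0

    @property
    def last_update(self) -> float:
        return self._t

    def _decay_to(self, t: float):
        if t < self._t:
            raise ValueError("time must not run backwards")
        dt = t - self._t
        if self.kernel.kind == "exponential":
            self._s1 *= np.exp(-dt / self.kernel.tau)
        else:
            self._s1 *= np.exp(-dt / self.kernel.tau1)
            self._s2 *= np.exp(-dt / self.kernel.tau2)
        self._t = t

    def value(self, t: float) -> float:
        """Trace value (Hz) at time ``t`` (ms), before any spike at ``t``."""
        self._decay_to(t)
        if self.kernel.kind == "exponential":
            return 1000.0 / self.kernel.tau * self._s1
        return 1000.0 / (self.kernel.tau1 - self.kernel.tau2) * (self._s1 - self._s2)

    def add_spike(self, t: float):
        """Register a spike at time ``t`` (ms)."""
        self._decay_to(t)
        self._s1 += 1.0
        if self.kernel.kind != "exponential":
            self._s2 += 1.0
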