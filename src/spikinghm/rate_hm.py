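"""Rate-based (computational) Helmholtz machine with wake-sleep learning.

The generative model maps two hidden activities ``x`` to two observed
activities ``y`` through a truncated-Gaussian conditional,

    y | x  ~  TruncNorm(W_G x + B_G beta, Sigma),

truncated to the non-negative orthant (activities are firing rates);
the recognition model is the mirror image,

    x | y  ~  TruncNorm(W_R y + B_R beta, Sigma).

``beta`` is a fixed bias activity and ``Sigma`` a fixed covariance;
only the weights ``W_G, W_R`` and the non-negative biases ``B_G, B_R``
are learned, by alternating wake phases (data -> recognition -> adapt
generative side) and sleep phases (prior -> generative -> adapt
recognition side).  Two update rules are provided: the exact delta rule
and the clipped quadratic approximation that the spiking plasticity
rules realise (``delta_w = eta * I * M * (M + theta)`` with
``M = max(T - O, -theta)``).

This model is the fast reference against which the spiking network
implementation is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "RateHMParams",
    "TruncatedGaussian",
    "sample_truncated_gaussian",
    "conditional_sample",
    "exact_ws_update",
    "approx_delta_update",
    "train_rate_hm",
    "generate_samples",
    "recognize_samples",
    "save_params",
    "load_params",
]


@dataclass
class RateHMParams:
    """Learnable and fixed parameters of the two-by-two machine.

    ``W_G, W_R`` are 2x2 weight matrices (unconstrained), ``B_G, B_R``
    non-negative bias weights, ``beta`` the fixed bias activity (Hz),
    ``Sigma`` the fixed conditional covariance (Hz^2), ``eta``/``eta_b``
    the weight/bias learning rates and ``theta_clip`` the clipping
    threshold (Hz) of the approximate rule.
    """

    W_G: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    W_R: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    B_G: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    B_R: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    beta: float = 25.0
    Sigma: np.ndarray = field(default_factory=lambda: 25.0 * np.eye(2))
    eta: float = 1e-4
    eta_b: float = 1e-4
    theta_clip: float = 10.0

    def __post_init__(self):
        self.W_G = np.asarray(self.W_G, dtype=float).copy()
        self.W_R = np.asarray(self.W_R, dtype=float).copy()
        self.B_G = np.asarray(self.B_G, dtype=float).copy()
        self.B_R = np.asarray(self.B_R, dtype=float).copy()
        self.Sigma = np.asarray(self.Sigma, dtype=float).copy()
        if np.any(self.B_G < 0) or np.any(self.B_R < 0):
            raise ValueError("bias weights must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not np.allclose(self.Sigma, self.Sigma.T) or np.any(
            np.linalg.eigvalsh(self.Sigma) <= 0
        ):
            raise ValueError("Sigma must be symmetric positive definite")
        if self.theta_clip <= 0:
            raise ValueError("theta_clip must be positive")

    def copy(self) -> "RateHMParams":
        return RateHMParams(
            W_G=self.W_G,
            W_R=self.W_R,
            B_G=self.B_G,
            B_R=self.B_R,
            beta=self.beta,
            Sigma=self.Sigma,
            eta=self.eta,
            eta_b=self.eta_b,
            theta_clip=self.theta_clip,
        )


@dataclass(frozen=True)
class TruncatedGaussian:
    """A multivariate normal restricted to the non-negative orthant.

    The normaliser ``Z`` is never needed for sampling (done by
    rejection) and is not computed.
    """

    mu: np.ndarray
    Sigma: np.ndarray


def sample_truncated_gaussian(mu, Sigma, rng, batch: int = 128) -> np.ndarray:
    """One draw from ``N(mu, Sigma)`` conditioned on all components >= 0.

    Rejection sampling in batches.  Raises if the empirical acceptance
    rate falls below 1e-6 (pathological mean far inside the negative
    orthant).
    """
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    chol = np.linalg.cholesky(Sigma)
    tried = 0
    while True:
        z = mu + rng.standard_normal((batch, mu.size)) @ chol.T
        ok = np.all(z >= 0, axis=1)
        if np.any(ok):
            return z[np.argmax(ok)]
        tried += batch
        if tried > 2e6:
            raise RuntimeError(
                f"truncated-Gaussian acceptance rate below 1e-6 for mu={mu}"
            )


def _sample_truncnorm_diag(mu, sigma, rng) -> np.ndarray:
    """Vector draw with independent components, truncated at 0 each.

    Inverse-CDF sampling; exact and loop-free, used on the hot path of
    training (the model covariance is diagonal by default).
    """
    lo = special.ndtr(-mu / sigma)
    u = lo + (1.0 - lo) * rng.random(mu.shape)
    return np.maximum(0.0, mu + sigma * special.ndtri(u))


def conditional_sample(direction: str, inp, params: RateHMParams, rng) -> np.ndarray:
    """Sample one layer conditioned on the other.

    ``direction="generative"`` draws ``y ~ TruncNorm(W_G x + B_G beta,
    Sigma)`` from hidden input ``x``; ``direction="recognition"`` draws
    ``x ~ TruncNorm(W_R y + B_R beta, Sigma)`` from observed input ``y``.
    """
    inp = np.asarray(inp, dtype=float)
    if np.any(inp < 0):
        raise ValueError("input activities must be non-negative")
    if direction == "generative":
        mean = params.W_G @ inp + params.B_G * params.beta
    elif direction == "recognition":
        mean = params.W_R @ inp + params.B_R * params.beta
    else:
        raise ValueError("direction must be 'generative' or 'recognition'")
    diag = np.diag(params.Sigma)
    if np.count_nonzero(params.Sigma - np.diag(diag)) == 0:
        return _sample_truncnorm_diag(mean, np.sqrt(diag), rng)
    return sample_truncated_gaussian(mean, params.Sigma, rng)


def exact_ws_update(phase: str, x_sample, y_sample, params: RateHMParams) -> RateHMParams:
    """One exact wake-sleep (delta-rule) update, in place.

    Wake adjusts the generative side from the reconstruction error
    ``y - (W_G x + B_G beta)``; sleep adjusts the recognition side from
    ``x - (W_R y + B_R beta)``.  Biases are clipped at zero.
    """
    x = np.asarray(x_sample, dtype=float)
    y = np.asarray(y_sample, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("samples must be non-negative")
    if phase == "wake":
        err = y - (params.W_G @ x + params.B_G * params.beta)
        params.W_G += params.eta * np.outer(err, x)
        params.B_G = np.maximum(0.0, params.B_G + params.eta_b * err)
    elif phase == "sleep":
        err = x - (params.W_R @ y + params.B_R * params.beta)
        params.W_R += params.eta * np.outer(err, y)
        params.B_R = np.maximum(0.0, params.B_R + params.eta_b * err)
    else:
        raise ValueError("phase must be 'wake' or 'sleep'")
    return params


def approx_delta_update(I, T, O, eta: float, theta_clip: float):
    """Clipped quadratic approximation of the delta rule.

    ``delta_w = eta * I * M * (M + theta)`` with
    ``M = max(T - O, -theta)``: same sign as the exact error whenever
    the error exceeds ``-theta``, zero below.  This is the rate-level
    abstraction of the BCM-type spiking plasticity.  Scalar or
    elementwise on arrays.
    """
    if theta_clip <= 0:
        raise ValueError("theta_clip must be positive")
    M = np.maximum(np.asarray(T, dtype=float) - np.asarray(O, dtype=float), -theta_clip)
    return eta * np.asarray(I, dtype=float) * M * (M + theta_clip)


def _approx_side_update(params: RateHMParams, W, B, inp, target):
    out = W @ inp + B * params.beta
    M = np.maximum(target - out, -params.theta_clip)
    q = M * (M + params.theta_clip)
    W += params.eta * np.outer(q, inp)
    np.maximum(0.0, B + params.eta_b * q, out=B)


def train_rate_hm(
    dataset,
    prior,
    n_phases: int,
    rule: str = "exact",
    rng=None,
    params: RateHMParams | None = None,
    weight_bound: float = 1e3,
    log_every: int = 0,
):
    """Wake-sleep training of the rate model.

    Alternates ``n_phases`` wake phases (one data sample each, taken
    successively and in order, wrapping around) with ``n_phases`` sleep
    phases (one prior draw each).  ``rule`` selects the exact delta rule
    or the clipped quadratic approximation.  ``prior`` must expose
    ``sample(rng)`` or be a callable ``rng -> 2-vector``.

    Returns ``(params, log)`` where ``log`` is a list of
    ``(phase_index, ||W_G||, ||W_R||, wake reconstruction error)`` rows
    recorded every ``log_every`` phases (0 disables logging).  Aborts
    with a diagnostic if a weight norm exceeds ``weight_bound``.
    """
    data = np.asarray(dataset, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("dataset must be a non-empty (N, 2) array")
    if rule not in ("exact", "approx"):
        raise ValueError("rule must be 'exact' or 'approx'")
    rng = np.random.default_rng(rng)
    params = RateHMParams() if params is None else params
    draw_prior = prior.sample if hasattr(prior, "sample") else prior
    log = []
    n_data = data.shape[0]
    for n in range(n_phases):
        # --- wake: observe data, infer hidden cause, adapt generative side
        y = data[n % n_data]
        x = conditional_sample("recognition", y, params, rng)
        if rule == "exact":
            exact_ws_update("wake", x, y, params)
        else:
            _approx_side_update(params, params.W_G, params.B_G, x, y)
        # --- sleep: fantasise from the prior, adapt recognition side
        x_s = np.maximum(0.0, np.asarray(draw_prior(rng), dtype=float))
        y_s = conditional_sample("generative", x_s, params, rng)
        if rule == "exact":
            exact_ws_update("sleep", x_s, y_s, params)
        else:
            _approx_side_update(params, params.W_R, params.B_R, y_s, x_s)
        nG = np.linalg.norm(params.W_G)
        if nG > weight_bound or np.linalg.norm(params.W_R) > weight_bound:
            raise RuntimeError(
                f"weights diverged at phase {n}: |W_G|={nG:.3g}, "
                f"|W_R|={np.linalg.norm(params.W_R):.3g}"
            )
        if log_every and n % log_every == 0:
            err = y - (params.W_G @ x + params.B_G * params.beta)
            log.append((n, nG, float(np.linalg.norm(params.W_R)), float(np.linalg.norm(err))))
    return params, log


def save_params(params: RateHMParams, path):
    """Serialise trained parameters to a flat key-value text file."""
    lines = []
    for key in ("W_G", "W_R", "B_G", "B_R", "Sigma"):
        arr = getattr(params, key)
        for idx, v in np.ndenumerate(arr):
            lines.append(f"{key}{list(idx)}={float(v)!r}")
    for key in ("beta", "eta", "eta_b", "theta_clip"):
        lines.append(f"{key}={getattr(params, key)!r}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def load_params(path) -> RateHMParams:
    """Inverse of :func:`save_params`."""
    from pathlib import Path

    p = RateHMParams()
    for line in Path(path).read_text().splitlines():
        key, _, val = line.partition("=")
        if "[" in key:
            name, idx = key.split("[", 1)
            idx = tuple(int(t) for t in idx.rstrip("]").split(","))
            getattr(p, name)[idx] = float(val)
        elif key:
            setattr(p, key, float(val))
    return p


def generate_samples(params: RateHMParams, prior, n: int, rng=None) -> np.ndarray:
    """Draw ``n`` observed-layer samples from the generative model."""
    rng = np.random.default_rng(rng)
    draw_prior = prior.sample if hasattr(prior, "sample") else prior
    out = np.empty((n, 2))
    for i in range(n):
        x = np.maximum(0.0, np.asarray(draw_prior(rng), dtype=float))
        out[i] = conditional_sample("generative", x, params, rng)
    return out


def recognize_samples(params: RateHMParams, data, rng=None) -> np.ndarray:
    """Hidden-layer samples inferred from each row of ``data``."""
    rng = np.random.default_rng(rng)
    data = np.asarray(data, dtype=float)
    out = np.empty_like(data)
    for i in range(data.shape[0]):
        out[i] = conditional_sample("recognition", data[i], params, rng)
    return out
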