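"""Synthetic training datasets and prior distributions.

All training data are two-dimensional firing-rate vectors (Hz).  The
named datasets follow the study design of the evaluation battery:

* ``a``–``e``: unimodal truncated Gaussians (some rotated, i.e. with
  correlated components; ``e`` is anti-correlated, the hardest case for
  a network whose plastic synapses are purely inhibitory);
* ``f``–``i``: bimodal mixtures of two unskewed truncated Gaussians;
* ``o``: uniform line with truncated-Gaussian noise, labelled by the
  line position ``C`` in [0, 1] — the decoding task;
* ``r``: noise-free uniform line labelled by ``C`` in [-1, 1] — the
  biased-reward task.

Priors (over the hidden layer) come in three families: unimodal,
bimodal (optionally reward-weighted) and uniform line.  Dataset means
are kept at or above 15 Hz because the plasticity rules are least
accurate at low rates; this is asserted at generation time.

All generators are deterministic under a fixed seed; datasets are meant
to be generated once and reused across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledDataset",
    "CovarianceBuilder",
    "PriorSpec",
    "make_gaussian_dataset",
    "make_line_dataset",
    "make_dataset",
    "sample_prior",
    "unimodal_prior",
    "bimodal_prior",
    "reward_prior",
    "line_prior",
    "DATASET_NAMES",
    "default_prior_for",
]

#: Decoding line in both data and hidden space: (15,15) + C*(15,15), C in [0,1].
LINE_ORIGIN = np.array([15.0, 15.0])
LINE_DIRECTION = np.array([15.0, 15.0])
#: Reward data line: (25,25) + C*(-10,10), C in [-1,1].  The reward decode
#: acts on *hidden* samples via the prior geometry (see `reward_prior`).
REWARD_CENTER = np.array([25.0, 25.0])
REWARD_DIRECTION = np.array([-10.0, 10.0])

MIN_MEAN_RATE = 15.0


@dataclass
class LabeledDataset:
    """N x 2 rate samples with optional scalar position labels."""

    samples: np.ndarray
    labels: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be (N, 2)")
        if np.any(self.samples < 0):
            raise ValueError("rate samples must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if self.labels.shape[0] != self.samples.shape[0]:
                raise ValueError("labels must match samples")

    def __len__(self):
        return self.samples.shape[0]


@dataclass(frozen=True)
class CovarianceBuilder:
    """Rotated diagonal covariance: ``R(theta) diag(rho1^2, rho2^2) R(theta)^T``.

    ``rho1, rho2`` are axis standard deviations (Hz), ``theta_rot`` the
    rotation angle in radians.
    """

    rho1: float
    rho2: float
    theta_rot: float = 0.0

    def __post_init__(self):
        if self.rho1 <= 0 or self.rho2 <= 0:
            raise ValueError("axis spreads must be positive")

    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta_rot), np.sin(self.theta_rot)
        return np.array([[c, -s], [s, c]])

    def cov(self) -> np.ndarray:
        R = self.rotation()
        return R @ np.diag([self.rho1**2, self.rho2**2]) @ R.T


def _truncated_mvn(mu, cov, n, rng) -> np.ndarray:
    """n rejection-sampled draws of N(mu, cov) restricted to >= 0."""
    mu = np.asarray(mu, dtype=float)
    out = np.empty((0, 2))
    tries = 0
    while out.shape[0] < n:
        batch = rng.multivariate_normal(mu, cov, size=max(n, 64))
        out = np.vstack([out, batch[np.all(batch >= 0, axis=1)]])
        tries += max(n, 64)
        if tries > 1e7 and out.shape[0] == 0:
            raise RuntimeError(f"pathological truncation for mu={mu}")
    return out[:n]


def make_gaussian_dataset(kind, params, N, rng=None) -> LabeledDataset:
    """Unimodal or bimodal truncated-Gaussian dataset.

    ``kind="unimodal"``: ``params = (mu, CovarianceBuilder)``.
    ``kind="bimodal"``: ``params = ((mu_a, cov_a), (mu_b, cov_b))`` with
    unrotated covariance builders and equal mixture weights.
    """
    rng = np.random.default_rng(rng)
    if kind == "unimodal":
        mu, cb = params
        _check_mean(mu)
        samples = _truncated_mvn(mu, cb.cov(), N, rng)
    elif kind == "bimodal":
        (mu_a, cb_a), (mu_b, cb_b) = params
        _check_mean(mu_a), _check_mean(mu_b)
        pick = rng.random(N) < 0.5
        samples = np.empty((N, 2))
        samples[pick] = _truncated_mvn(mu_a, cb_a.cov(), int(pick.sum()), rng)
        samples[~pick] = _truncated_mvn(mu_b, cb_b.cov(), int(N - pick.sum()), rng)
    else:
        raise ValueError("kind must be 'unimodal' or 'bimodal'")
    return LabeledDataset(samples)


def _check_mean(mu):
    if np.any(np.asarray(mu) < MIN_MEAN_RATE):
        raise ValueError(
            f"dataset means must stay at or above {MIN_MEAN_RATE} Hz, got {mu}"
        )


def make_line_dataset(task: str, N: int, rng=None, noise_rho: float = 3.0) -> LabeledDataset:
    """Uniform-line dataset for the decoding (``o``) or reward (``r``) task.

    ``o``: ``C ~ U[0, 1]``, ``y = (15,15) + C (15,15)`` plus isotropic
    truncated-Gaussian noise of spread ``noise_rho``; labelled by ``C``.
    ``r``: ``C ~ U[-1, 1]``, ``y = (25,25) + C (-10,10)`` exactly on the
    line; labelled by ``C``.
    """
    rng = np.random.default_rng(rng)
    if task == "decoding":
        C = rng.uniform(0.0, 1.0, size=N)
        base = LINE_ORIGIN + np.outer(C, LINE_DIRECTION)
        cov = np.diag([noise_rho**2, noise_rho**2])
        samples = np.empty((N, 2))
        for i in range(N):  # per-point rejection keeps each sample >= 0
            samples[i] = _truncated_mvn(base[i], cov, 1, rng)[0]
    elif task == "reward":
        C = rng.uniform(-1.0, 1.0, size=N)
        samples = REWARD_CENTER + np.outer(C, REWARD_DIRECTION)
    else:
        raise ValueError("task must be 'decoding' or 'reward'")
    return LabeledDataset(samples, labels=C)


@dataclass(frozen=True)
class PriorSpec:
    """Hidden-layer prior distribution.

    ``family`` is one of ``"unimodal"``, ``"bimodal"`` or
    ``"uniform_line"``.  ``components`` holds ``(mu, CovarianceBuilder)``
    pairs (Gaussian families) or ``(origin, direction, lo, hi)`` for the
    line family.  ``weights`` are the mixture weights; for the reward
    task they are proportional to the two reward values.  ``scale``
    multiplies every drawn rate (used to give STDPi networks a
    higher-rate prior).
    """

    family: str
    components: tuple
    weights: tuple = (1.0,)
    scale: float = 1.0

    def __post_init__(self):
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng) -> np.ndarray:
        return sample_prior(self, rng)


def sample_prior(prior: PriorSpec, rng) -> np.ndarray:
    """One non-negative hidden-layer rate vector drawn from the prior."""
    rng = np.random.default_rng(rng)
    if prior.family in ("unimodal", "bimodal"):
        idx = rng.choice(len(prior.components), p=np.asarray(prior.weights))
        mu, cb = prior.components[idx]
        return prior.scale * _truncated_mvn(mu, cb.cov(), 1, rng)[0]
    if prior.family == "uniform_line":
        origin, direction, lo, hi = prior.components[0]
        C = rng.uniform(lo, hi)
        return prior.scale * (np.asarray(origin) + C * np.asarray(direction))
    raise ValueError(f"unknown prior family {prior.family!r}")


def unimodal_prior(scale: float = 1.0) -> PriorSpec:
    """Single truncated Gaussian centred mid-range."""
    return PriorSpec(
        "unimodal",
        components=((np.array([25.0, 25.0]), CovarianceBuilder(8.0, 8.0)),),
        weights=(1.0,),
        scale=scale,
    )


def bimodal_prior(scale: float = 1.0) -> PriorSpec:
    """Equal mixture of two well-separated truncated Gaussians."""
    return PriorSpec(
        "bimodal",
        components=(
            (np.array([15.0, 35.0]), CovarianceBuilder(4.0, 4.0)),
            (np.array([35.0, 15.0]), CovarianceBuilder(4.0, 4.0)),
        ),
        weights=(0.5, 0.5),
        scale=scale,
    )


def reward_prior(r1: float, r2: float, scale: float = 1.0) -> PriorSpec:
    """Bimodal prior with modes weighted in proportion ``r1 : r2``.

    The modes sit at the ends of the reward decode line (hidden decode
    ``C_hat = (-x1 + x2)/25``, so the modes map to ``C_hat = +-1``).
    """
    if r1 < 0 or r2 < 0 or r1 + r2 <= 0:
        raise ValueError("rewards must be non-negative and not both zero")
    w1 = r1 / (r1 + r2)
    return PriorSpec(
        "bimodal",
        components=(
            (np.array([10.0, 35.0]), CovarianceBuilder(4.0, 4.0)),
            (np.array([35.0, 10.0]), CovarianceBuilder(4.0, 4.0)),
        ),
        weights=(w1, 1.0 - w1),
        scale=scale,
    )


def line_prior(scale: float = 1.0) -> PriorSpec:
    """Uniform line prior matching the decoding projection
    ``C_hat = ((x1-15)+(x2-15))/30`` on [0, 1]."""
    return PriorSpec(
        "uniform_line",
        components=((LINE_ORIGIN, LINE_DIRECTION, 0.0, 1.0),),
        weights=(1.0,),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Named dataset registry

_UNIMODAL = {
    "a": (np.array([25.0, 25.0]), CovarianceBuilder(6.0, 6.0)),
    "b": (np.array([20.0, 35.0]), CovarianceBuilder(8.0, 3.0)),
    "c": (np.array([35.0, 20.0]), CovarianceBuilder(3.0, 8.0)),
    "d": (np.array([30.0, 30.0]), CovarianceBuilder(8.0, 3.0, np.pi / 4)),
    "e": (np.array([30.0, 30.0]), CovarianceBuilder(8.0, 3.0, -np.pi / 4)),
}
_BIMODAL = {
    "f": (
        (np.array([20.0, 20.0]), CovarianceBuilder(4.0, 4.0)),
        (np.array([40.0, 40.0]), CovarianceBuilder(4.0, 4.0)),
    ),
    "g": (
        (np.array([20.0, 40.0]), CovarianceBuilder(4.0, 4.0)),
        (np.array([40.0, 20.0]), CovarianceBuilder(4.0, 4.0)),
    ),
    "h": (
        (np.array([15.0, 25.0]), CovarianceBuilder(4.0, 4.0)),
        (np.array([40.0, 35.0]), CovarianceBuilder(4.0, 4.0)),
    ),
    "i": (
        (np.array([25.0, 15.0]), CovarianceBuilder(4.0, 4.0)),
        (np.array([30.0, 45.0]), CovarianceBuilder(4.0, 4.0)),
    ),
}

DATASET_NAMES = tuple("abcdefghi") + ("o", "r")


def make_dataset(name: str, N: int = 2000, rng=None) -> LabeledDataset:
    """Generate one of the named datasets ``a``–``i``, ``o`` or ``r``."""
    rng = np.random.default_rng(rng)
    if name in _UNIMODAL:
        ds = make_gaussian_dataset("unimodal", _UNIMODAL[name], N, rng)
    elif name in _BIMODAL:
        ds = make_gaussian_dataset("bimodal", _BIMODAL[name], N, rng)
    elif name == "o":
        ds = make_line_dataset("decoding", N, rng)
    elif name == "r":
        ds = make_line_dataset("reward", N, rng)
    else:
        raise ValueError(f"unknown dataset {name!r}")
    ds.name = name
    return ds


def default_prior_for(name: str, scale: float = 1.0) -> PriorSpec:
    """The prior family conventionally paired with a named dataset."""
    if name in _UNIMODAL:
        return unimodal_prior(scale)
    if name in _BIMODAL:
        return bimodal_prior(scale)
    if name == "o":
        return line_prior(scale)
    if name == "r":
        return reward_prior(0.5, 0.5, scale)
    raise ValueError(f"unknown dataset {name!r}")
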