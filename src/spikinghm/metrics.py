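"""Quantitative evaluation: divergences, decoding, psychometrics, reward.

The generative tests compare rate distributions through 40 x 40
histograms over [0, 60] Hz per axis using the base-2 Jensen--Shannon
divergence (0 for identical distributions, 1 for disjoint support).
The recognition tests decode a scalar position from hidden-layer
samples by projecting onto the prior line, score it by root-mean-square
deviation, and — for the two-alternative reward task — fit a logistic
psychometric function to extract a decision threshold ``mu`` and noise
scale ``s``, which are compared against the reward-maximising threshold
computed by quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.integrate import quad
from scipy.spatial.distance import jensenshannon

__all__ = [
    "Histogram2D",
    "LogisticFit",
    "RewardSpec",
    "FitFailure",
    "js_divergence",
    "match_test",
    "decode_position",
    "mean_deviation",
    "fit_logistic",
    "r_logistic",
    "optimal_threshold",
    "reward_analysis",
    "iqr_keep_mask",
    "sleep_improvement_experiment",
    "tau2_sweep",
]


class FitFailure(RuntimeError):
    """Raised when the psychometric fit is ill-posed (e.g. separation)."""


@dataclass
class Histogram2D:
    """Normalised 40 x 40 rate histogram on [0, 60] Hz per axis.

    Samples outside the range are clipped into the edge bins so that
    the histogram keeps unit mass and divergences stay bounded.
    """

    mass: np.ndarray
    bins: int = 40
    range_hz: tuple = (0.0, 60.0)

    @classmethod
    def from_samples(cls, samples, bins: int = 40, range_hz=(0.0, 60.0)):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] == 0:
            raise ValueError("need a non-empty (N, 2) sample array")
        lo, hi = range_hz
        eps = (hi - lo) * 1e-9
        clipped = np.clip(samples, lo, hi - eps)
        counts, _, _ = np.histogram2d(
            clipped[:, 0], clipped[:, 1], bins=bins, range=[[lo, hi], [lo, hi]]
        )
        return cls(mass=counts / counts.sum(), bins=bins, range_hz=range_hz)

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.bins, self.bins):
            raise ValueError("mass must be (bins, bins)")


def js_divergence(P, Q) -> float:
    """Base-2 Jensen--Shannon divergence between two normalised histograms.

    ``D = 1/2 KL(P || M) + 1/2 KL(Q || M)`` with ``M = (P + Q)/2`` and
    the convention ``0 log 0 = 0``; lies in [0, 1].
    """
    p = P.mass if isinstance(P, Histogram2D) else np.asarray(P, dtype=float)
    q = Q.mass if isinstance(Q, Histogram2D) else np.asarray(Q, dtype=float)
    if not (math.isclose(p.sum(), 1.0, abs_tol=1e-8) and math.isclose(q.sum(), 1.0, abs_tol=1e-8)):
        raise ValueError("histograms must be normalised")
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p.ravel(), q.ravel(), base=2) ** 2)


def match_test(samples_by_instance, datasets):
    """Best-match analysis of generative models against candidate datasets.

    Parameters
    ----------
    samples_by_instance:
        List over model instances; each entry maps dataset name -> the
        generative samples of the model *trained on that dataset*.
    datasets:
        Mapping dataset name -> training samples.  At least two
        candidates are required.

    Returns a dict with:

    ``matches``
        (instance, dataset) boolean matrix: the model's generative
        distribution was closest (minimum JS divergence, ties broken
        toward the lowest dataset index) to its own training dataset.
    ``confusion``
        Square matrix against the *population-average* generative
        distribution per dataset: entry (i, j) counts instances trained
        on dataset i whose model best matched the average distribution
        of dataset j.
    ``D_net``
        Per-instance mean divergence between each trained model and its
        training dataset.
    ``D_pop``
        Mean of ``D_net`` across instances.
    """
    names = list(datasets)
    if len(names) < 2:
        raise ValueError("need at least two candidate datasets")
    data_hists = {n: Histogram2D.from_samples(datasets[n]) for n in names}
    model_hists = [
        {n: Histogram2D.from_samples(inst[n]) for n in names}
        for inst in samples_by_instance
    ]
    n_inst = len(model_hists)
    matches = np.zeros((n_inst, len(names)), dtype=bool)
    D_net = np.zeros(n_inst)
    for i, hists in enumerate(model_hists):
        divs_own = []
        for j, n in enumerate(names):
            d = [js_divergence(hists[n], data_hists[m]) for m in names]
            matches[i, j] = int(np.argmin(d)) == j
            divs_own.append(d[j])
        D_net[i] = float(np.mean(divs_own))
    # population-average generative distribution per training dataset
    avg = {
        n: Histogram2D(
            mass=np.mean([h[n].mass for h in model_hists], axis=0)
        )
        for n in names
    }
    confusion = np.zeros((len(names), len(names)), dtype=int)
    for hists in model_hists:
        for j, n in enumerate(names):
            d = [js_divergence(hists[n], avg[m]) for m in names]
            confusion[j, int(np.argmin(d))] += 1
    return {
        "matches": matches,
        "confusion": confusion,
        "D_net": D_net,
        "D_pop": float(D_net.mean()),
        "names": names,
    }


def decode_position(x, task: str):
    """Project hidden-layer samples onto the prior line.

    ``task="decoding"``: ``C_hat = ((x1 - 15) + (x2 - 15)) / 30``;
    ``task="reward"``: ``C_hat = (-x1 + x2) / 25``.  Accepts a single
    2-vector or an (N, 2) array.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("rates must be non-negative")
    x1, x2 = x[..., 0], x[..., 1]
    if task == "decoding":
        out = ((x1 - 15.0) + (x2 - 15.0)) / 30.0
    elif task == "reward":
        out = (-x1 + x2) / 25.0
    else:
        raise ValueError("task must be 'decoding' or 'reward'")
    return float(out) if out.ndim == 0 else out


def mean_deviation(C_hat, C) -> float:
    """Root-mean-square deviation between decoded and true positions."""
    C_hat = np.asarray(C_hat, dtype=float)
    C = np.asarray(C, dtype=float)
    if C_hat.size == 0 or C_hat.shape != C.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((C_hat - C) ** 2)))


@dataclass(frozen=True)
class LogisticFit:
    """Psychometric parameters: decision threshold ``mu`` (position
    units) and internal noise scale ``s > 0``."""

    mu: float
    s: float

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("s must be positive")

    def prob(self, C):
        return 1.0 / (1.0 + np.exp(-(np.asarray(C, dtype=float) - self.mu) / self.s))


def fit_logistic(C, responses) -> LogisticFit:
    """Maximum-likelihood logistic fit of per-trial binary responses.

    Fits ``P(respond positive | C) = 1 / (1 + exp(-(C - mu)/s))``.
    Raises :class:`FitFailure` when the responses are one-sided or
    completely separated along ``C`` (the MLE then diverges).
    """
    C = np.asarray(C, dtype=float)
    r = np.asarray(responses, dtype=bool)
    if C.shape != r.shape or C.size < 2:
        raise ValueError("need matching C and response arrays")
    if r.all() or (~r).all():
        raise FitFailure("responses contain a single outcome")
    if C[r].min() > C[~r].max():
        raise FitFailure("complete separation: MLE does not exist")

    def nll(theta):
        mu, log_s = theta
        z = (C - mu) / np.exp(log_s)
        # log(1 + e^-z) stable via logaddexp
        return float(np.sum(np.logaddexp(0.0, -z)) + np.sum(z[~r]))

    x0 = np.array([float(np.median(C)), np.log(max(np.std(C), 1e-3))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    if not res.success:
        raise FitFailure(f"logistic fit failed: {res.message}")
    return LogisticFit(mu=float(res.x[0]), s=float(np.exp(res.x[1])))


@dataclass(frozen=True)
class RewardSpec:
    """Reward values of the two choices, constrained to sum to one."""

    r1: float
    r2: float

    def __post_init__(self):
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("rewards must be non-negative")
        if not math.isclose(self.r1 + self.r2, 1.0, abs_tol=1e-9):
            raise ValueError("r1 + r2 must equal 1")


def r_logistic(mu: float, s: float, r1: float, r2: float) -> float:
    """Expected reward of a logistic-noise decoder with threshold ``mu``.

    The position ``C`` is uniform on [-1, 1]; the internal estimate is
    ``C`` plus logistic noise of scale ``s``; choosing "positive" when
    the estimate exceeds ``mu`` earns ``r1`` if ``C > 0`` and choosing
    "negative" earns ``r2`` if ``C < 0``.  Evaluated by adaptive
    quadrature (relative tolerance 1e-8).  As ``s -> 0`` at ``mu = 0``
    this approaches ``(r1 + r2)/2``.
    """
    if s <= 0:
        raise ValueError("s must be positive")

    from scipy.special import expit

    def p_pos(C):  # P(estimate > mu | C)
        return expit((C - mu) / s)

    a = quad(lambda C: p_pos(C), 0.0, 1.0, epsrel=1e-8)[0]
    b = quad(lambda C: 1.0 - p_pos(C), -1.0, 0.0, epsrel=1e-8)[0]
    return 0.5 * r1 * a + 0.5 * r2 * b


def optimal_threshold(s: float, r1: float, r2: float) -> float:
    """Threshold maximising :func:`r_logistic` over [-1, 1]."""
    res = optimize.minimize_scalar(
        lambda mu: -r_logistic(mu, s, r1, r2), bounds=(-1.0, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def reward_analysis(decisions, labels, spec: RewardSpec, fit: LogisticFit):
    """Empirical and model-based reward summary for one model.

    ``decisions`` are decoded positions ``C_hat`` (their sign is the
    choice), ``labels`` the true positions.  The Helmholtz machine has
    a label-swap symmetry, so the decode is flipped in sign if that
    increases the empirical reward.  Returns a dict with the empirical
    reward ``R``, the optimal threshold ``mu_opt`` for the fitted noise
    ``s``, the corresponding maximum ``R_max``, and the floor
    ``R_min = max(r1, r2)/2`` attained by always taking the richer
    choice.
    """
    C_hat = np.asarray(decisions, dtype=float)
    C = np.asarray(labels, dtype=float)
    if fit.s <= 0:
        raise ValueError("noise scale must be positive")

    def emp(ch):
        return float(
            np.mean(spec.r1 * ((ch > 0) & (C > 0)) + spec.r2 * ((ch < 0) & (C < 0)))
        )

    R = emp(C_hat)
    flipped = emp(-C_hat)
    if flipped > R:
        R = flipped
    mu_opt = optimal_threshold(fit.s, spec.r1, spec.r2)
    return {
        "R": R,
        "mu_opt": mu_opt,
        "R_max": r_logistic(mu_opt, fit.s, spec.r1, spec.r2),
        "R_min": max(spec.r1, spec.r2) / 2.0,
    }


def iqr_keep_mask(thresholds) -> np.ndarray:
    """Mask of models whose decision threshold is inside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` (the rest are discarded from
    population statistics as non-converged)."""
    t = np.asarray(thresholds, dtype=float)
    q1, q3 = np.percentile(t, [25, 75])
    iqr = q3 - q1
    return (t >= q1 - 1.5 * iqr) & (t <= q3 + 1.5 * iqr)


def sleep_improvement_experiment(
    dataset,
    prior,
    checkpoints,
    rng=None,
    params=None,
    rule: str = "approx",
    sleep_phases: int = 4000,
    n_eval: int = 500,
    task: str = "decoding",
    decode_from: str = "mean",
):
    """Effect of prolonged sleep at successive points during training.

    Trains the rate model on a labelled line dataset with a slow
    learning rate; at each checkpoint (phase count) the state is
    cloned, sleep-only updates are run to convergence of the
    recognition weights, and the decoding mean deviation of the slept
    clone is compared with the un-slept one.  Returns a list of
    ``(checkpoint, dev_before, dev_after)`` rows; the improvement is
    ``dev_before - dev_after``.

    ``decode_from="mean"`` decodes from the recognition conditional
    mean (a variance-reduced readout of recognition-weight quality);
    ``"sample"`` decodes from recognition samples as in the behavioural
    tests.
    """
    from .rate_hm import RateHMParams, conditional_sample, train_rate_hm, recognize_samples

    rng = np.random.default_rng(rng)
    params = RateHMParams(eta=2e-5, eta_b=2e-5) if params is None else params
    data = dataset.samples if hasattr(dataset, "samples") else np.asarray(dataset)
    labels = dataset.labels
    results = []
    done = 0
    for cp in sorted(checkpoints):
        params, _ = train_rate_hm(
            data, prior, cp - done, rule=rule, rng=rng, params=params
        )
        done = cp

        def dev(p):
            idx = rng.choice(len(data), size=min(n_eval, len(data)), replace=False)
            if decode_from == "mean":
                x = np.maximum(0.0, data[idx] @ p.W_R.T + p.B_R * p.beta)
            else:
                x = recognize_samples(p, data[idx], rng)
            return mean_deviation(decode_position(x, task), labels[idx])

        before = dev(params)
        clone = params.copy()
        # sleep-only: fantasise and adapt the recognition side to
        # convergence; the learning rate is annealed across blocks so the
        # recognition weights settle onto the (frozen) generative model
        draw_prior = prior.sample if hasattr(prior, "sample") else prior
        from .rate_hm import exact_ws_update, _approx_side_update

        n_blocks = 5
        base_eta, base_eta_b = clone.eta, clone.eta_b
        for block in range(n_blocks):
            clone.eta = base_eta / 2**block
            clone.eta_b = base_eta_b / 2**block
            for _ in range(max(1, sleep_phases // n_blocks)):
                x_s = np.maximum(0.0, np.asarray(draw_prior(rng), dtype=float))
                y_s = conditional_sample("generative", x_s, clone, rng)
                if rule == "exact":
                    exact_ws_update("sleep", x_s, y_s, clone)
                else:
                    _approx_side_update(clone, clone.W_R, clone.B_R, y_s, x_s)
        clone.eta, clone.eta_b = base_eta, base_eta_b
        results.append((cp, before, dev(clone)))
    return results


def tau2_sweep(tau2_values, experiment, n_instantiations: int, tau1: float = 50.0):
    """Run ``experiment(tau2, seed)`` over a grid of kernel dips.

    ``experiment`` returns a scalar performance figure; the sweep
    returns ``(mean, sem)`` arrays over ``n_instantiations`` seeds per
    ``tau2``.  Requesting ``tau2 >= tau1`` is rejected (the
    difference-of-exponentials kernel is degenerate there).
    """
    tau2_values = np.asarray(tau2_values, dtype=float)
    if np.any(tau2_values >= tau1):
        raise ValueError("tau2 must be strictly below tau1")
    mean = np.zeros(tau2_values.size)
    sem = np.zeros(tau2_values.size)
    for k, tau2 in enumerate(tau2_values):
        vals = np.array([experiment(float(tau2), seed) for seed in range(n_instantiations)])
        mean[k] = vals.mean()
        sem[k] = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
    return mean, sem
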