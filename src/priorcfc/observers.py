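"""Generative decision and confidence models for the two-interval task.

All six observers share the same first-order machinery (except the efficient
coding observer, which uses its own encoding stage): on each interval an
internal signal ``r ~ Normal(theta, sigma_l)`` is combined with a
two-component Gaussian-mixture prior over motion directions, and the choice
("orange" vs "blue") follows whichever side of the reference carries more
posterior mass inside the allowed decision region [-90, +90] deg.

The models differ only in the confidence read-out:

``bayes``
    Posterior probability of the chosen color (between 0.5 and 1).
``dist``
    Distance from a single posterior sample to the reference (criterion),
    the sample constrained to the chosen side.
``dp``
    Decoupled Prior: the Bayesian read-out recomputed with the likelihood SD
    scaled by ``w``, so the prior is over- (w > 1) or under-weighted (w < 1)
    at the confidence stage only.
``pce``
    Prior-congruent evidence: |cos(theta_r - theta_P)|, the motion component
    along the prior-preferred orthogonal direction, ignoring the posterior.
``wppce``
    Weighted mixture (1 - alpha) * BPE + alpha * PCE.
``ec``
    Efficient coding: the likelihood itself is shaped by the prior through
    the cumulative-prior mapping to a homogeneous sensory space, then the
    Bayesian read-out is applied to the resulting grid posterior.

The posterior algebra is closed form (mixture of truncated Gaussians); the
test-suite checks it against brute-force quadrature.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .geometry import (
    BiasDirection,
    Condition,
    DECISION_REGION_DEG,
    PreferredDirections,
    preferred_directions,
)

__all__ = [
    "ModelTag",
    "ObserverParams",
    "PosteriorSummary",
    "ConfidenceValue",
    "TrialRecord",
    "posterior_masses",
    "posterior_choice_probabilities",
    "decision_threshold",
    "perceptual_decision",
    "confidence_bayesian",
    "confidence_distance_to_criterion",
    "sample_posterior_side",
    "confidence_decoupled_prior",
    "confidence_pce",
    "confidence_wppce",
    "EfficientCodingEncoder",
    "ec_likelihood",
    "confidence_forced_choice",
    "simulate_trials",
    "simulate_trial",
]

_REGION = DECISION_REGION_DEG
_EC_DOMAIN = (-180.0, 180.0)
_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(x, loc, scale):
    z = (x - loc) / scale
    return np.exp(-0.5 * z * z) / (_SQRT_2PI * scale)


class ModelTag(str, enum.Enum):
    BAYES = "bayes"
    DIST = "dist"
    DP = "dp"
    PCE = "pce"
    WPPCE = "wppce"
    EC = "ec"


# number of free parameters entering AIC/BIC, including first-order ones
MODEL_N_PARAMS = {
    ModelTag.BAYES: 2,
    ModelTag.DIST: 2,
    ModelTag.PCE: 2,
    ModelTag.DP: 3,
    ModelTag.WPPCE: 3,
    ModelTag.EC: 3,
}


@dataclass(frozen=True)
class ObserverParams:
    """Generative or fitted observer parameters.

    ``sigma_p`` and ``sigma_l`` (degrees) are the prior-component and
    likelihood SDs shared by the Bayesian family.  ``w`` (Decoupled Prior),
    ``alpha`` (WPPCE) and the sensory-space SDs ``sigma_n``/``sigma_t``
    (efficient coding; units of the cumulative-prior mapping, so on [0, 1])
    are model specific and ignored elsewhere.
    """

    sigma_p: float = 30.0
    sigma_l: float = 15.0
    w: float = 1.0
    alpha: float = 0.0
    sigma_n: float = 0.1
    sigma_t: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_p <= 0 or self.sigma_l <= 0:
            raise ValueError("sigma_p and sigma_l must be positive")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.sigma_n <= 0 or self.sigma_t <= 0:
            raise ValueError("sigma_n and sigma_t must be positive")


@dataclass(frozen=True)
class PosteriorSummary:
    """Closed-form summary of the truncated-mixture posterior at signal r."""

    p_orange: float
    p_blue: float
    normalizer: float
    component_weights: tuple[float, ...]
    component_means: tuple[float, ...]
    component_sd: float


@dataclass(frozen=True)
class ConfidenceValue:
    value: float
    scale: str  # posterior_prob | distance_deg | pce_unit | mixed


@dataclass(frozen=True)
class TrialRecord:
    """One confidence forced-choice trial (two intervals)."""

    stimuli: tuple
    responses: tuple[int, int]  # 1 = Blue, 0 = Orange
    confidence_choice: int  # 1 or 2
    rts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    confidences: tuple[float, float] = field(default=(np.nan, np.nan))


def _component_means(
    directions: PreferredDirections, single_gaussian: bool
) -> np.ndarray:
    if single_gaussian:
        return np.array([directions.mu_orth1], dtype=float)
    return np.array([directions.mu_orth1, directions.mu_orth2], dtype=float)


def posterior_masses(
    r,
    sigma_p: float,
    sigma_l: float,
    directions: PreferredDirections,
    single_gaussian: bool = False,
):
    """Unnormalized posterior mass on the orange side, blue side and total.

    Vectorized over ``r``.  Each mixture component k contributes evidence
    weight ``0.5 * N(r; mu_k, sigma_p^2 + sigma_l^2)``; the within-component
    posterior is Gaussian with precision-weighted mean and common SD
    ``(sigma_p^-2 + sigma_l^-2)^(-1/2)``, truncated to the decision region.

    ``directions`` may also be an array of component means whose last axis
    indexes components and whose leading axes broadcast against ``r[..., None]``
    (used by the vectorized likelihood machinery).
    """
    r = np.asarray(r, dtype=float)
    if isinstance(directions, PreferredDirections):
        mus = _component_means(directions, single_gaussian)
    else:
        mus = np.asarray(directions, dtype=float)
    var_sum = sigma_p**2 + sigma_l**2
    post_var = 1.0 / (1.0 / sigma_p**2 + 1.0 / sigma_l**2)
    post_sd = np.sqrt(post_var)

    # shape: (..., n_components)
    rr = r[..., None]
    weight = 0.5 * _norm_pdf(rr, mus, np.sqrt(var_sum))
    post_mean = post_var * (mus / sigma_p**2 + rr / sigma_l**2)

    lo = ndtr((-_REGION - post_mean) / post_sd)
    mid = ndtr((0.0 - post_mean) / post_sd)
    hi = ndtr((_REGION - post_mean) / post_sd)

    mass_orange = np.sum(weight * (mid - lo), axis=-1)
    mass_blue = np.sum(weight * (hi - mid), axis=-1)
    total = mass_orange + mass_blue
    return mass_orange, mass_blue, total


def posterior_choice_probabilities(
    r: float,
    params: ObserverParams,
    directions: PreferredDirections,
    likelihood_sd: float | None = None,
    single_gaussian: bool = False,
) -> PosteriorSummary:
    """Normalized posterior choice probabilities at internal signal ``r``.

    ``likelihood_sd`` overrides ``params.sigma_l`` (the Decoupled Prior rule
    passes ``w * sigma_l``).  Raises if the posterior mass inside the
    decision region is numerically zero.
    """
    sigma_l = params.sigma_l if likelihood_sd is None else likelihood_sd
    mo, mb, total = posterior_masses(
        r, params.sigma_p, sigma_l, directions, single_gaussian
    )
    if not total > np.finfo(float).tiny:
        raise FloatingPointError(
            "degenerate posterior: no mass inside the decision region"
        )
    mus = _component_means(directions, single_gaussian)
    var_sum = params.sigma_p**2 + sigma_l**2
    post_var = 1.0 / (1.0 / params.sigma_p**2 + 1.0 / sigma_l**2)
    weights = 0.5 * stats.norm.pdf(r, loc=mus, scale=np.sqrt(var_sum))
    weights = weights / weights.sum()
    means = post_var * (mus / params.sigma_p**2 + r / sigma_l**2)
    return PosteriorSummary(
        p_orange=float(mo / total),
        p_blue=float(mb / total),
        normalizer=float(total),
        component_weights=tuple(weights),
        component_means=tuple(means),
        component_sd=float(np.sqrt(post_var)),
    )


def decision_threshold(
    sigma_p: float,
    sigma_l: float,
    directions: PreferredDirections,
    single_gaussian: bool = False,
) -> float:
    """Internal-signal level r* at which the two choices are equally likely.

    The posterior blue probability is strictly increasing in r, so the
    decision rule "choose blue iff p_blue > p_orange" is equivalent to
    "choose blue iff r > r*"; the first-order psychometric function is then
    the cumulative normal ``P(Blue | theta) = Phi((theta - r*) / sigma_l)``.
    """
    from scipy.optimize import brentq

    def imbalance(r):
        mo, mb, total = posterior_masses(
            r, sigma_p, sigma_l, directions, single_gaussian
        )
        # normalize so the sign survives evidence-weight underflow far out
        return (mb - mo) / np.maximum(total, np.finfo(float).tiny)

    # locate a sign change on a coarse scan, then refine; if the imbalance
    # never crosses zero the threshold saturates at the bracket edge (the
    # prior decides regardless of the signal)
    grid = np.linspace(-300.0, 300.0, 601)
    vals = imbalance(grid)
    signs = np.sign(vals)
    crossings = np.nonzero(np.diff(signs) > 0)[0]
    if len(crossings) == 0:
        return -300.0 if vals[len(vals) // 2] >= 0 else 300.0
    i = crossings[0]
    if signs[i] == 0:
        return float(grid[i])
    return float(
        brentq(lambda r: float(imbalance(r)), grid[i], grid[i + 1], xtol=1e-10)
    )


def perceptual_decision(summary: PosteriorSummary, rng: np.random.Generator) -> int:
    """1 = Blue iff p_blue > p_orange; exact ties broken by a fair coin."""
    if summary.p_blue > summary.p_orange:
        return 1
    if summary.p_blue < summary.p_orange:
        return 0
    return int(rng.random() < 0.5)


def confidence_bayesian(summary: PosteriorSummary, choice: int) -> ConfidenceValue:
    """Posterior probability of the chosen color; lies in [0.5, 1]."""
    value = summary.p_blue if choice == 1 else summary.p_orange
    return ConfidenceValue(float(value), "posterior_prob")


def sample_posterior_side(
    summary: PosteriorSummary,
    choice: int,
    u_component: float,
    u_trunc: float,
) -> float:
    """Inverse-CDF sample from the posterior truncated to the chosen side.

    ``u_component`` selects the mixture component (by its mass on the chosen
    side) and ``u_trunc`` locates the sample within the truncated component;
    driving both from unit uniforms keeps the draw reproducible and smooth
    in the parameters.
    """
    a, b = (0.0, _REGION) if choice == 1 else (-_REGION, 0.0)
    s = summary.component_sd
    means = np.asarray(summary.component_means)
    w = np.asarray(summary.component_weights)
    lo = stats.norm.cdf((a - means) / s)
    hi = stats.norm.cdf((b - means) / s)
    side_mass = w * (hi - lo)
    total = side_mass.sum()
    if not total > np.finfo(float).tiny:
        raise FloatingPointError("no posterior mass on the chosen side")
    cum = np.cumsum(side_mass / total)
    k = int(np.searchsorted(cum, u_component))
    k = min(k, len(means) - 1)
    p = lo[k] + u_trunc * (hi[k] - lo[k])
    return float(means[k] + s * stats.norm.ppf(p))


def confidence_distance_to_criterion(
    summary: PosteriorSummary, choice: int, rng: np.random.Generator
) -> ConfidenceValue:
    """|posterior sample - criterion|, the sample on the chosen side."""
    r_c = sample_posterior_side(summary, choice, rng.random(), rng.random())
    return ConfidenceValue(abs(r_c), "distance_deg")


def confidence_decoupled_prior(
    r: float,
    params: ObserverParams,
    directions: PreferredDirections,
    choice: int,
) -> ConfidenceValue:
    """Bayesian read-out with the likelihood SD inflated to w * sigma_l.

    Unlike the Bayesian rule this may fall below 0.5 (the re-weighted
    posterior can disagree with the perceptual decision).
    """
    summary = posterior_choice_probabilities(
        r, params, directions, likelihood_sd=params.w * params.sigma_l
    )
    value = summary.p_blue if choice == 1 else summary.p_orange
    return ConfidenceValue(float(value), "posterior_prob")


def confidence_pce(theta_r: float, theta_p: float) -> ConfidenceValue:
    """Prior-congruent evidence |cos(theta_r - theta_p)| (degrees in)."""
    value = abs(np.cos(np.deg2rad(theta_r - theta_p)))
    return ConfidenceValue(float(value), "pce_unit")


def confidence_wppce(bpe: float, pce: float, alpha: float) -> ConfidenceValue:
    """Weighted combination (1 - alpha) * BPE + alpha * PCE."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return ConfidenceValue(float((1.0 - alpha) * bpe + alpha * pce), "mixed")


class EfficientCodingEncoder:
    """Prior-shaped sensory encoding after the Wei-Stocker scheme.

    The condition's mixture prior, renormalized over [-180, 180), defines a
    cumulative mapping F from physical direction to a homogeneous sensory
    space on [0, 1] in which Fisher information is uniform.  A measurement
    is ``m ~ Normal(F(theta) + eps_T, sigma_n)`` with transduction jitter
    ``eps_T ~ Normal(0, sigma_t)``.  Decoding inverts the mapping on a grid:
    the likelihood in physical space is the normal density of m at F(theta),
    which is narrower where the prior is denser.
    """

    def __init__(
        self,
        sigma_p: float,
        sigma_n: float,
        sigma_t: float,
        condition: Condition,
        bias_direction: BiasDirection = BiasDirection.NONE,
        grid_step: float = 0.1,
    ) -> None:
        self.sigma_p = float(sigma_p)
        self.sigma_n = float(sigma_n)
        self.sigma_t = float(sigma_t)
        self.directions = preferred_directions(condition, bias_direction)
        lo, hi = _EC_DOMAIN
        self._mus = np.array([self.directions.mu_orth1, self.directions.mu_orth2])
        # total prior mass on the domain (no wrapping; sigma_p << domain)
        self._z = float(
            np.sum(
                0.5
                * (ndtr((hi - self._mus) / sigma_p) - ndtr((lo - self._mus) / sigma_p))
            )
        )
        # decision grid: cell centers over [-90, 90]
        n = int(round(2 * _REGION / grid_step))
        edges = np.linspace(-_REGION, _REGION, n + 1)
        self.theta_grid = 0.5 * (edges[:-1] + edges[1:])
        self._grid_prior = self.prior_pdf(self.theta_grid)
        self._grid_F = self.cumulative_prior(self.theta_grid)
        self._blue_mask = self.theta_grid > 0.0

    def prior_pdf(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        dens = 0.5 * (
            _norm_pdf(theta, self._mus[0], self.sigma_p)
            + _norm_pdf(theta, self._mus[1], self.sigma_p)
        )
        return dens / self._z

    def cumulative_prior(self, theta) -> np.ndarray:
        """F(theta): prior CDF over the domain, mapping to [0, 1]."""
        theta = np.asarray(theta, dtype=float)
        lo = _EC_DOMAIN[0]
        cum = 0.5 * (
            ndtr((theta[..., None] - self._mus) / self.sigma_p)
            - ndtr((lo - self._mus) / self.sigma_p)
        ).sum(axis=-1)
        return cum / self._z

    def sample_measurement(self, theta_true, rng: np.random.Generator) -> np.ndarray:
        theta_true = np.asarray(theta_true, dtype=float)
        eps_t = rng.normal(0.0, self.sigma_t, size=theta_true.shape)
        noise = rng.normal(0.0, self.sigma_n, size=theta_true.shape)
        return self.cumulative_prior(theta_true) + eps_t + noise

    def likelihood(self, m: float, theta_grid: np.ndarray | None = None) -> np.ndarray:
        """Unnormalized likelihood L(theta) = N(m; F(theta), sigma_n)."""
        F = self._grid_F if theta_grid is None else self.cumulative_prior(theta_grid)
        return stats.norm.pdf(m, loc=F, scale=self.sigma_n)

    def p_blue(self, m) -> np.ndarray:
        """Posterior blue probability for measurement(s) m (grid decoding)."""
        m = np.atleast_1d(np.asarray(m, dtype=float))
        like = _norm_pdf(m[:, None], self._grid_F[None, :], self.sigma_n)
        post = like * self._grid_prior[None, :]
        total = post.sum(axis=1)
        if np.any(total <= np.finfo(float).tiny):
            raise FloatingPointError("degenerate EC posterior on the decision region")
        return post[:, self._blue_mask].sum(axis=1) / total

    def p_blue_fast(self, m) -> np.ndarray:
        """p_blue(m) via a cached monotone interpolation table.

        The table spans the reachable measurement range at a resolution of
        sigma_n / 20, ample for the smooth monotone p_blue curve.
        """
        if not hasattr(self, "_tbl"):
            pad = 8.0 * (self.sigma_n + self.sigma_t) + 0.1
            lo = float(self._grid_F[0]) - pad
            hi = float(self._grid_F[-1]) + pad
            n = int(min(max(2001, (hi - lo) / (self.sigma_n / 20.0)), 20001))
            grid = np.linspace(lo, hi, n)
            self._tbl = (grid, self.p_blue(grid))
        grid, vals = self._tbl
        return np.interp(np.asarray(m, dtype=float), grid, vals)

    def decision_threshold_m(self) -> float:
        """Measurement level m* with equal posterior mass on both sides.

        p_blue(m) is increasing in m (F is monotone), so the decision is
        "blue iff m > m*" and the choice probability given theta is
        ``1 - Phi((m* - F(theta)) / sqrt(sigma_n^2 + sigma_t^2))``.
        """
        from scipy.optimize import brentq

        f0 = self.cumulative_prior(np.array([0.0]))[0]
        lo = f0 - 8 * self.sigma_n - 0.5
        hi = f0 + 8 * self.sigma_n + 0.5

        def imbalance(m: float) -> float:
            return float(self.p_blue(m)[0] - 0.5)

        if imbalance(lo) >= 0:
            return lo
        if imbalance(hi) <= 0:
            return hi
        return float(brentq(imbalance, lo, hi, xtol=1e-12))

    def p_blue_given_theta(self, theta) -> np.ndarray:
        m_star = self.decision_threshold_m()
        total_sd = np.hypot(self.sigma_n, self.sigma_t)
        F = self.cumulative_prior(np.atleast_1d(np.asarray(theta, dtype=float)))
        return 1.0 - stats.norm.cdf((m_star - F) / total_sd)


def ec_likelihood(
    theta_true: float,
    params: ObserverParams,
    prior_spec: tuple[Condition, BiasDirection],
    theta_grid: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One simulated EC measurement's likelihood over ``theta_grid``.

    Warns if the grid is too coarse to resolve the induced likelihood
    (fewer than ~20 points per SD of the mapped measurement noise).
    """
    import warnings

    enc = EfficientCodingEncoder(
        params.sigma_p, params.sigma_n, params.sigma_t, *prior_spec
    )
    F = enc.cumulative_prior(np.asarray(theta_grid, dtype=float))
    dF = np.gradient(F, np.asarray(theta_grid, dtype=float))
    # physical-space width of the likelihood ~ sigma_n / F'(theta)
    width = params.sigma_n / np.maximum(dF.max(), np.finfo(float).tiny)
    step = float(np.median(np.diff(theta_grid)))
    if width / step < 20:
        warnings.warn(
            "theta_grid too coarse to resolve the EC likelihood", stacklevel=2
        )
    m = float(enc.sample_measurement(np.asarray(theta_true, dtype=float), rng))
    return stats.norm.pdf(m, loc=F, scale=params.sigma_n)


def confidence_forced_choice(
    conf1: ConfidenceValue, conf2: ConfidenceValue, rng: np.random.Generator
) -> int:
    """Interval (1 or 2) with the larger confidence; ties by fair coin."""
    if conf1.scale != conf2.scale:
        raise ValueError(
            f"confidence scales differ: {conf1.scale!r} vs {conf2.scale!r}"
        )
    if conf1.value > conf2.value:
        return 1
    if conf1.value < conf2.value:
        return 2
    return 1 if rng.random() < 0.5 else 2


# ---------------------------------------------------------------------------
# trial simulation


def _draw_trial_noise(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Fixed block of random draws per trial, model independent.

    Every model consumes the same layout so that observers whose rules
    coincide (e.g. Decoupled Prior at w = 1 and the Bayesian observer)
    produce bitwise-identical trials under a shared seed.
    """
    return {
        "z": rng.standard_normal((n, 2)),  # signal / neural noise
        "eps_t": rng.standard_normal((n, 2)),  # EC transduction jitter
        "u_comp": rng.random((n, 2)),  # dist-model component pick
        "u_trunc": rng.random((n, 2)),  # dist-model truncated sample
        "u_tie": rng.random((n, 3)),  # decision x2 + cfc tie coins
        "z_rt": rng.standard_normal((n, 3)),  # log-normal reaction times
    }


def _interval_confidence(
    model: ModelTag,
    r: float,
    choice: int,
    params: ObserverParams,
    directions: PreferredDirections,
    summary: PosteriorSummary,
    noise: dict[str, np.ndarray],
    i: int,
    j: int,
) -> ConfidenceValue:
    if model is ModelTag.BAYES:
        return confidence_bayesian(summary, choice)
    if model is ModelTag.DIST:
        r_c = sample_posterior_side(
            summary, choice, noise["u_comp"][i, j], noise["u_trunc"][i, j]
        )
        return ConfidenceValue(abs(r_c), "distance_deg")
    if model is ModelTag.DP:
        return confidence_decoupled_prior(r, params, directions, choice)
    if model is ModelTag.PCE:
        return confidence_pce(r, directions.mu_orth1)
    if model is ModelTag.WPPCE:
        bpe = confidence_bayesian(summary, choice).value
        pce = confidence_pce(r, directions.mu_orth1).value
        v = confidence_wppce(bpe, pce, params.alpha)
        return ConfidenceValue(v.value, "mixed")
    raise ValueError(f"unhandled model {model}")


def simulate_trials(
    pairs,
    model_tag: ModelTag | str,
    params: ObserverParams,
    rng: np.random.Generator,
    rt_median: float = 0.8,
    rt_sigma_log: float = 0.4,
) -> list[TrialRecord]:
    """Simulate a list of confidence forced-choice trials.

    ``pairs`` is a sequence of (StimulusSpec, StimulusSpec).  The random
    stream layout is identical for every model tag (a fixed block of draws
    per trial), which makes identity reductions exact under a shared seed.
    """
    model = ModelTag(model_tag)
    pairs = list(pairs)
    n = len(pairs)
    noise = _draw_trial_noise(n, rng)
    rts = rt_median * np.exp(rt_sigma_log * noise["z_rt"])

    encoders: dict[tuple, EfficientCodingEncoder] = {}

    records: list[TrialRecord] = []
    for i, pair in enumerate(pairs):
        responses = []
        confs: list[ConfidenceValue] = []
        for j, stim in enumerate(pair):
            directions = preferred_directions(stim.condition, stim.bias_direction)
            if model is ModelTag.EC:
                key = (stim.condition, stim.bias_direction)
                if key not in encoders:
                    encoders[key] = EfficientCodingEncoder(
                        params.sigma_p,
                        params.sigma_n,
                        params.sigma_t,
                        stim.condition,
                        stim.bias_direction,
                    )
                enc = encoders[key]
                m = (
                    float(enc.cumulative_prior(np.array([stim.theta]))[0])
                    + params.sigma_t * noise["eps_t"][i, j]
                    + params.sigma_n * noise["z"][i, j]
                )
                pb = float(enc.p_blue(m)[0])
                if pb > 0.5:
                    choice = 1
                elif pb < 0.5:
                    choice = 0
                else:
                    choice = int(noise["u_tie"][i, j] < 0.5)
                conf = ConfidenceValue(max(pb, 1.0 - pb), "posterior_prob")
            else:
                r = stim.theta + params.sigma_l * noise["z"][i, j]
                summary = posterior_choice_probabilities(r, params, directions)
                if summary.p_blue > summary.p_orange:
                    choice = 1
                elif summary.p_blue < summary.p_orange:
                    choice = 0
                else:
                    choice = int(noise["u_tie"][i, j] < 0.5)
                conf = _interval_confidence(
                    model, r, choice, params, directions, summary, noise, i, j
                )
            responses.append(choice)
            confs.append(conf)

        if confs[0].value > confs[1].value:
            cfc = 1
        elif confs[0].value < confs[1].value:
            cfc = 2
        else:
            cfc = 1 if noise["u_tie"][i, 2] < 0.5 else 2
        records.append(
            TrialRecord(
                stimuli=tuple(pair),
                responses=(responses[0], responses[1]),
                confidence_choice=cfc,
                rts=tuple(rts[i]),
                confidences=(confs[0].value, confs[1].value),
            )
        )
    return records


def simulate_trial(
    pair,
    model_tag: ModelTag | str,
    params: ObserverParams,
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate a single trial (see :func:`simulate_trials`)."""
    return simulate_trials([pair], model_tag, params, rng)[0]


def first_order_choice_function(
    model_tag: ModelTag | str,
    params: ObserverParams,
    condition: Condition,
    bias_direction: BiasDirection = BiasDirection.NONE,
    single_gaussian: bool = False,
):
    """Exact P('Blue' | theta) for an observer in a given condition.

    For the Bayesian-family observers the decision rule reduces to a signal
    threshold r*, so the choice probability is the cumulative normal
    ``Phi((theta - r*) / sigma_l)``.  The efficient coding observer's
    threshold lives in the sensory (cumulative-prior) space instead.
    Returns a vectorized callable over theta.
    """
    model = ModelTag(model_tag)
    if model is ModelTag.EC:
        enc = EfficientCodingEncoder(
            params.sigma_p, params.sigma_n, params.sigma_t, condition, bias_direction
        )
        return enc.p_blue_given_theta
    directions = preferred_directions(condition, bias_direction)
    r_star = decision_threshold(
        params.sigma_p, params.sigma_l, directions, single_gaussian
    )

    def p_blue(theta):
        theta = np.asarray(theta, dtype=float)
        return stats.norm.cdf((theta - r_star) / params.sigma_l)

    return p_blue
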