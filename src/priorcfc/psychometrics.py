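"""Psychometric fitting and descriptive confidence-bias analyses.

The first-order analyses fit cumulative-normal psychometric functions
``P('Blue') = Phi((theta - mu) / sigma)`` to binary choice data by maximum
likelihood (no lapse parameter).  The confidence-bias analysis is
non-parametric with respect to the observer models: for every
cross-condition pair of stimulus settings it compares the rate of choosing
the Bias-condition interval as more confident against the difference in
logit-transformed choice rates between the conditions, and summarizes the
relationship with another cumulative-normal fit whose PSE measures the
confidence bias after first-order performance differences are accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "SymmetricBiasFit",
    "ConfidenceBiasFit",
    "ExclusionReport",
    "fit_cumulative_normal",
    "fit_symmetric_bias",
    "apply_exclusions",
    "confidence_bias_points",
    "nonparametric_confidence_bias",
]

MAX_RT_S = 8.0  # any decision slower than this is discarded
MIN_MOTION_RT_S = 0.1  # motion decisions faster than this are discarded

_SIGMA_BOUNDS = (1e-3, 1e4)


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-normal fit: P(response) = Phi((x - mu) / sigma)."""

    mu: float
    sigma: float
    n_trials: int
    log_likelihood: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return stats.norm.cdf((np.asarray(x, dtype=float) - self.mu) / self.sigma)

    def quantile(self, p: float) -> float:
        """Stimulus level at which the response probability equals p."""
        return float(self.mu + self.sigma * stats.norm.ppf(p))


@dataclass(frozen=True)
class SymmetricBiasFit:
    """Joint fit of a single symmetric bias magnitude across bias directions.

    Blue-bias trials follow ``Phi((theta + mu_bias) / sigma_bias)`` (the PSE
    is shifted to -mu_bias) and orange-bias trials its mirror
    ``Phi((theta - mu_bias) / sigma_bias)``; the No-Bias condition is fit
    separately as a baseline.
    """

    mu_bias: float
    sigma_bias: float
    mu_nobias: float
    sigma_nobias: float
    log_likelihood: float
    n_trials: int


@dataclass(frozen=True)
class ConfidenceBiasFit:
    """Cumulative-normal fit of P('Bias') against cp_diff.

    ``mu_cb`` is the PSE in logit-difference units; a negative PSE means the
    Bias-condition interval is chosen as more confident even when its choice
    rates are *less* extreme, i.e. a confidence bias favoring the Bias
    condition.  ``p_bias_at_zero`` is the predicted P('Bias') at matched
    choice rates (cp_diff = 0).
    """

    mu_cb: float
    sigma_cb: float
    p_bias_at_zero: float
    n_pairs: int
    n_trials: int
    points: pd.DataFrame


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_slow_rt: int
    n_fast_rt: int
    n_bias_check: int
    n_kept: int
    flagged_settings: tuple


def _bernoulli_nll(mu: float, log_sigma: float, x, y, weights) -> float:
    sigma = np.exp(log_sigma)
    p = stats.norm.cdf((x - mu) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(weights * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def fit_cumulative_normal(
    levels, binary_responses, weights=None, mu_starts=(-30.0, 0.0, 30.0)
) -> PsychometricFit:
    """ML fit of Phi((x - mu) / sigma) to Bernoulli data.

    Deterministic given the data: a small multi-start over ``mu`` guards
    against local optima.  Complete separation drives sigma to its lower
    bound; the fit is then flagged as non-converged and returned with the
    boundary estimates.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(binary_responses, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if x.size < 2 or len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct stimulus levels")
    if y.min() == y.max():
        raise ValueError("need both response types represented")

    spread = max(np.std(x), 1.0)
    best = None
    for mu0 in mu_starts:
        res = optimize.minimize(
            lambda v: _bernoulli_nll(v[0], v[1], x, y, w),
            x0=[mu0, np.log(spread)],
            method="L-BFGS-B",
            bounds=[(-720, 720), (np.log(_SIGMA_BOUNDS[0]), np.log(_SIGMA_BOUNDS[1]))],
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], float(np.exp(best.x[1]))
    # complete separation drives sigma toward 0 and the deviance toward 0;
    # either symptom marks a boundary (non-identified) fit
    at_boundary = (
        sigma <= _SIGMA_BOUNDS[0] * 1.01
        or sigma >= _SIGMA_BOUNDS[1] * 0.99
        or abs(mu) >= 719
        or best.fun < 1e-3
    )
    return PsychometricFit(
        mu=float(mu),
        sigma=sigma,
        n_trials=int(round(w.sum())),
        log_likelihood=-float(best.fun),
        converged=bool(best.success and not at_boundary),
    )


def fit_symmetric_bias(decisions: pd.DataFrame) -> SymmetricBiasFit:
    """Fit one symmetric bias magnitude for the Bias condition.

    ``decisions`` holds one row per motion-direction decision with columns
    ``condition`` ('Bias'/'NoBias'), ``bias_direction``, ``theta``,
    ``response`` (1 = Blue).
    """
    nb = decisions[decisions["condition"] == "NoBias"]
    bias = decisions[decisions["condition"] == "Bias"]
    if nb.empty or bias.empty:
        raise ValueError("need trials from both conditions")
    for direction in ("blue", "orange"):
        if not (bias["bias_direction"] == direction).any():
            raise ValueError(f"no {direction}-bias trials present")

    nb_fit = fit_cumulative_normal(nb["theta"], nb["response"])

    sign = np.where(bias["bias_direction"].to_numpy() == "blue", 1.0, -1.0)
    theta = bias["theta"].to_numpy(dtype=float)
    resp = bias["response"].to_numpy(dtype=float)

    def nll(v):
        mu_b, log_sigma = v
        sigma = np.exp(log_sigma)
        # blue bias: PSE at -mu_b; orange bias: PSE at +mu_b
        p = stats.norm.cdf((theta + sign * mu_b) / sigma)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(resp * np.log(p) + (1 - resp) * np.log1p(-p)))

    best = None
    for mu0 in (0.0, 10.0, 25.0):
        res = optimize.minimize(
            nll,
            x0=[mu0, np.log(max(np.std(theta), 5.0))],
            method="L-BFGS-B",
            bounds=[(-360, 360), (np.log(1e-3), np.log(1e4))],
        )
        if best is None or res.fun < best.fun:
            best = res
    return SymmetricBiasFit(
        mu_bias=float(best.x[0]),
        sigma_bias=float(np.exp(best.x[1])),
        mu_nobias=nb_fit.mu,
        sigma_nobias=nb_fit.sigma,
        log_likelihood=-float(best.fun) + nb_fit.log_likelihood,
        n_trials=len(decisions),
    )


def _setting_key(row, interval: int) -> tuple:
    return (
        row[f"int{interval}_condition"],
        row[f"int{interval}_targeted_p_blue"],
    )


def apply_exclusions(
    trials: pd.DataFrame, selected_levels: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the pre-registered trial- and setting-level exclusion rules.

    Trials with any reaction time above 8 s, or a motion-decision reaction
    time below 100 ms, are removed.  If ``selected_levels`` is given (columns
    ``observer_id``, ``condition``, ``targeted_p_blue``, ``theta``), settings
    for which the calibrated No-Bias |theta| is not strictly more extreme
    than the Bias |theta| at the same targeted rate lack the basic bias
    effect, and trials presenting that Bias setting are removed.
    """
    for col in ("rt1", "rt2", "rt_conf"):
        if col not in trials.columns:
            raise ValueError(f"missing reaction-time column {col!r}")

    slow = (
        (trials["rt1"] > MAX_RT_S)
        | (trials["rt2"] > MAX_RT_S)
        | (trials["rt_conf"] > MAX_RT_S)
    )
    fast = (trials["rt1"] < MIN_MOTION_RT_S) | (trials["rt2"] < MIN_MOTION_RT_S)
    keep = ~(slow | fast)

    flagged: list[tuple] = []
    n_bias_check = 0
    if selected_levels is not None:
        for (obs, target), grp in selected_levels.groupby(
            ["observer_id", "targeted_p_blue"]
        ):
            nb = grp[grp["condition"] == "NoBias"]
            b = grp[grp["condition"] == "Bias"]
            if nb.empty or b.empty:
                continue
            if abs(float(nb["theta"].iloc[0])) <= abs(float(b["theta"].iloc[0])):
                flagged.append((obs, "Bias", target))
        if flagged:
            flag_set = set(flagged)
            hit = trials.apply(
                lambda row: (row["observer_id"], *_setting_key(row, 1)) in flag_set
                or (row["observer_id"], *_setting_key(row, 2)) in flag_set,
                axis=1,
            )
            n_bias_check = int((keep & hit).sum())
            keep &= ~hit

    report = ExclusionReport(
        n_input=len(trials),
        n_slow_rt=int(slow.sum()),
        n_fast_rt=int((fast & ~slow).sum()),
        n_bias_check=n_bias_check,
        n_kept=int(keep.sum()),
        flagged_settings=tuple(flagged),
    )
    return trials[keep].reset_index(drop=True), report


def _haldane_rate(successes: int, n: int) -> float:
    """Empirical rate with the Haldane-Anscombe continuity correction."""
    if n == 0:
        return 0.5
    if successes == 0 or successes == n:
        return (successes + 0.5) / (n + 1.0)
    return successes / n


def confidence_bias_points(trials: pd.DataFrame) -> pd.DataFrame:
    """Per setting-pair logit choice-rate differences and P('Bias') rates.

    Only cross-condition trials enter.  For each of the (up to 16) pairs of
    a Bias and a No-Bias setting: each condition's rate of choosing its
    expected color is logit transformed and differenced (``cp_diff``), and
    paired with the rate of choosing the Bias-condition interval as the more
    confident one.
    """
    cross = trials[trials["int1_condition"] != trials["int2_condition"]]
    rows = []
    for _, grp in cross.groupby(
        [
            "int1_condition",
            "int1_targeted_p_blue",
            "int2_condition",
            "int2_targeted_p_blue",
        ],
        sort=True,
    ):
        first = grp.iloc[0]
        bias_iv = 1 if first["int1_condition"] == "Bias" else 2
        nb_iv = 3 - bias_iv
        rows.append(_pair_point(grp, bias_iv, nb_iv))
    pts = pd.DataFrame(rows)
    if pts.empty:
        return pts
    # merge the two interval orders of the same unordered setting pair
    agg = (
        pts.groupby(["bias_target", "nobias_target"], sort=True)
        .apply(_merge_orders, include_groups=False)
        .reset_index()
    )
    return agg


def _pair_point(grp: pd.DataFrame, bias_iv: int, nb_iv: int) -> dict:
    n = len(grp)
    bias_target = float(grp.iloc[0][f"int{bias_iv}_targeted_p_blue"])
    nb_target = float(grp.iloc[0][f"int{nb_iv}_targeted_p_blue"])
    bias_resp = grp[f"response{bias_iv}"].to_numpy()
    nb_resp = grp[f"response{nb_iv}"].to_numpy()
    # expected color: blue if the setting targets P('Blue') > 0.5
    k_bias = int(bias_resp.sum()) if bias_target > 0.5 else int(n - bias_resp.sum())
    k_nb = int(nb_resp.sum()) if nb_target > 0.5 else int(n - nb_resp.sum())
    k_conf = int((grp["confidence_choice"] == bias_iv).sum())
    return {
        "bias_target": bias_target,
        "nobias_target": nb_target,
        "n": n,
        "k_bias_pref": k_bias,
        "k_nb_pref": k_nb,
        "k_choose_bias": k_conf,
    }


def _merge_orders(grp: pd.DataFrame) -> pd.Series:
    n = int(grp["n"].sum())
    rate_b = _haldane_rate(int(grp["k_bias_pref"].sum()), n)
    rate_nb = _haldane_rate(int(grp["k_nb_pref"].sum()), n)
    cp_diff = float(np.log(rate_b / (1 - rate_b)) - np.log(rate_nb / (1 - rate_nb)))
    k_conf = int(grp["k_choose_bias"].sum())
    return pd.Series(
        {
            "n": n,
            "cp_diff": cp_diff,
            "k_choose_bias": k_conf,
            "p_choose_bias": k_conf / n if n else np.nan,
        }
    )


def nonparametric_confidence_bias(trials: pd.DataFrame) -> ConfidenceBiasFit:
    """Cumulative-normal fit of P('Bias') against the logit rate difference.

    A PSE below zero indicates a confidence bias favoring the Bias
    condition: the Bias interval is still preferred when its first-order
    choice rates are matched to (cp_diff = 0) or less extreme than the
    No-Bias interval's.  Pairs are weighted by their trial counts through
    the Bernoulli likelihood.
    """
    if "observer_id" in trials.columns and trials["observer_id"].nunique() > 1:
        pts = pd.concat(
            [
                confidence_bias_points(g)
                for _, g in trials.groupby("observer_id", sort=True)
            ],
            ignore_index=True,
        )
    else:
        pts = confidence_bias_points(trials)
    if pts.empty:
        raise ValueError("no cross-condition trials to analyze")

    x = pts["cp_diff"].to_numpy(dtype=float)
    k = pts["k_choose_bias"].to_numpy(dtype=float)
    n = pts["n"].to_numpy(dtype=float)

    def nll(v):
        mu, log_sigma = v
        p = stats.norm.cdf((x - mu) / np.exp(log_sigma))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    best = None
    for mu0 in (-2.0, 0.0, 2.0):
        res = optimize.minimize(
            nll,
            x0=[mu0, 0.0],
            method="L-BFGS-B",
            bounds=[(-50, 50), (np.log(1e-3), np.log(1e3))],
        )
        if best is None or res.fun < best.fun:
            best = res
    mu_cb = float(best.x[0])
    sigma_cb = float(np.exp(best.x[1]))
    return ConfidenceBiasFit(
        mu_cb=mu_cb,
        sigma_cb=sigma_cb,
        p_bias_at_zero=float(stats.norm.cdf(-mu_cb / sigma_cb)),
        n_pairs=len(pts),
        n_trials=int(n.sum()),
        points=pts,
    )
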