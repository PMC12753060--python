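"""Study-shaped synthetic datasets: designs, calibration, trial tables.

The generator reproduces the experimental design: eight stimulus settings
(four per condition, targeting choice rates of 0.15, 0.35, 0.65 and 0.85),
all 28 unordered pairings of distinct settings, counterbalanced interval
orders, and per-block balancing of line-orientation sign and color-side
placement.  With the study's 24 repetitions per pair this yields 672
confidence forced-choice trials per observer.

Stimulus levels can either be supplied directly or calibrated the way the
study calibrated them: an accelerated stochastic approximation (ASA)
staircase run on the simulated observer itself, followed by a
cumulative-normal fit and quantile selection.

Reaction times are drawn log-normal purely so that downstream exclusion
filters can be exercised; they carry no scientific content.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import observers
from .geometry import (
    BiasDirection,
    Condition,
    DECISION_REGION_DEG,
    LINE_ORIENTATIONS_DEG,
    StimulusSpec,
)
from .observers import ModelTag, ObserverParams
from .psychometrics import PsychometricFit, fit_cumulative_normal

__all__ = [
    "DEFAULT_TARGETS",
    "TrialDesign",
    "ASAConfig",
    "StaircaseRun",
    "build_trial_design",
    "run_asa_staircase",
    "select_stimulus_levels",
    "calibrate_settings",
    "ideal_stimulus_levels",
    "simulate_dataset",
    "selected_levels_table",
    "write_dataset",
    "read_dataset",
]

DEFAULT_TARGETS = (0.15, 0.35, 0.65, 0.85)

#: (condition, bias_direction) of the three interleaved staircase procedures
PROCEDURES = (
    (Condition.NO_BIAS, BiasDirection.NONE),
    (Condition.BIAS, BiasDirection.BLUE),
    (Condition.BIAS, BiasDirection.ORANGE),
)


@dataclass(frozen=True)
class TrialDesign:
    """A fully scheduled list of confidence forced-choice trials."""

    trials: tuple  # tuple of (StimulusSpec, StimulusSpec)
    orange_ccw: tuple  # per-trial color-side flag
    repetitions: int
    settings: tuple

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ASAConfig:
    """Accelerated stochastic approximation staircase settings.

    The update is Kesten-style accelerated stochastic approximation: on
    trial n the level moves by ``-step * (response - target)`` with
    ``step = step_c / n`` until the first response reversal and
    ``step = step_c / (2 + n_shifts)`` afterwards, where ``n_shifts`` counts
    reversals, so the approach is fast from the start level and the steps
    shrink only once the staircase brackets its threshold.
    """

    n_trials: int = 80
    step_c: float = 40.0
    start_level: float = 40.0
    targets: tuple[float, ...] = (0.25, 0.75)
    staircases_per_target: int = 2


@dataclass(frozen=True)
class StaircaseRun:
    levels: np.ndarray
    responses: np.ndarray
    target: float
    clipped: bool


def _validate_settings(settings) -> tuple[list, list]:
    nobias = [s for s in settings if s.condition is Condition.NO_BIAS]
    bias = [s for s in settings if s.condition is Condition.BIAS]
    if len(nobias) != 4 or len(bias) != 4:
        raise ValueError("need exactly 4 settings per condition")
    for s in bias:
        if s.targeted_p_blue is None:
            continue
        expected = (
            {0.65, 0.85} if s.bias_direction is BiasDirection.BLUE else {0.15, 0.35}
        )
        if s.targeted_p_blue not in expected:
            raise ValueError(
                f"{s.bias_direction.value}-bias setting targets {s.targeted_p_blue}, "
                f"expected one of {sorted(expected)}"
            )
    return nobias, bias


def build_trial_design(
    settings, repetitions: int, rng: np.random.Generator
) -> TrialDesign:
    """Schedule all pairings of the eight settings into balanced blocks.

    Every unordered pair of distinct settings (28 of them) appears
    ``repetitions`` times, split evenly between the two interval orders.
    Each 56-trial block presents every ordered pair once, with half the
    trials tilted clockwise / counterclockwise and half with orange
    counterclockwise of the reference; line-tilt magnitudes are drawn from
    the non-cardinal set {10, ..., 80} deg.
    """
    settings = tuple(settings)
    _validate_settings(settings)
    if repetitions < 2 or repetitions % 2:
        raise ValueError(
            "repetitions must be an even count >= 2 so both interval orders "
            "can be counterbalanced"
        )
    pairs = [
        (settings[i], settings[j])
        for i in range(len(settings))
        for j in range(i + 1, len(settings))
    ]
    assert len(pairs) == 28

    trials: list[tuple[StimulusSpec, StimulusSpec]] = []
    orange_ccw: list[bool] = []
    n_blocks = repetitions // 2
    for _ in range(n_blocks):
        block = [(a, b) for a, b in pairs] + [(b, a) for a, b in pairs]
        order = rng.permutation(len(block))
        half = len(block) // 2
        cw_signs = np.array([1.0] * half + [-1.0] * half)
        color_flags = np.array([True] * half + [False] * half)
        rng.shuffle(cw_signs)
        rng.shuffle(color_flags)
        tilts = rng.choice(LINE_ORIENTATIONS_DEG, size=len(block))
        for t, idx in enumerate(order):
            a, b = block[idx]
            tilt = float(cw_signs[t] * tilts[t])
            trials.append(
                (
                    dataclasses.replace(a, line_orientation=tilt),
                    dataclasses.replace(b, line_orientation=tilt),
                )
            )
            orange_ccw.append(bool(color_flags[t]))
    return TrialDesign(
        trials=tuple(trials),
        orange_ccw=tuple(orange_ccw),
        repetitions=repetitions,
        settings=settings,
    )


def run_asa_staircase(
    model_tag: ModelTag | str,
    params: ObserverParams,
    config: ASAConfig,
    rng: np.random.Generator,
) -> dict[tuple[Condition, BiasDirection], list[StaircaseRun]]:
    """Run the three interleaved staircase procedures on a simulated observer.

    Each procedure (No-Bias, blue-bias, orange-bias) runs
    ``staircases_per_target`` staircases per target probability, querying
    the observer's exact first-order psychometric function for each binary
    response.  Levels are clipped to the decision region and flagged if the
    clip engages.  ``model_tag`` may also be a callable ``p_blue(theta)``,
    used for all three procedures (handy for synthetic response rules).
    """
    out: dict[tuple[Condition, BiasDirection], list[StaircaseRun]] = {}
    for condition, bias_direction in PROCEDURES:
        if callable(model_tag):
            p_blue = model_tag
        else:
            p_blue = observers.first_order_choice_function(
                model_tag, params, condition, bias_direction
            )
        runs: list[StaircaseRun] = []
        for target in config.targets:
            for _ in range(config.staircases_per_target):
                start = config.start_level if target > 0.5 else -config.start_level
                levels = np.empty(config.n_trials)
                responses = np.empty(config.n_trials, dtype=int)
                level = start
                n_shifts = 0
                prev = None
                clipped = False
                for t in range(config.n_trials):
                    levels[t] = level
                    resp = int(
                        rng.random() < float(np.asarray(p_blue(level)).ravel()[0])
                    )
                    responses[t] = resp
                    if prev is not None and resp != prev:
                        n_shifts += 1
                    prev = resp
                    if n_shifts == 0:
                        step = config.step_c / (t + 1.0)
                    else:
                        step = config.step_c / (2.0 + n_shifts)
                    level = level - step * (resp - target)
                    limit = DECISION_REGION_DEG
                    if abs(level) > limit:
                        level = float(np.clip(level, -limit, limit))
                        clipped = True
                runs.append(
                    StaircaseRun(
                        levels=levels, responses=responses, target=target,
                        clipped=clipped,
                    )
                )
        out[(condition, bias_direction)] = runs
    return out


def _fit_procedure(runs: list[StaircaseRun]) -> PsychometricFit:
    levels = np.concatenate([r.levels for r in runs])
    responses = np.concatenate([r.responses for r in runs])
    return fit_cumulative_normal(levels, responses)


def select_stimulus_levels(
    fits: dict[tuple[Condition, BiasDirection], PsychometricFit],
    targets: tuple[float, ...] = DEFAULT_TARGETS,
) -> list[StimulusSpec]:
    """Pick the eight theta values from the three procedure fits.

    Each target's level is the matching psychometric function's quantile,
    ``theta = mu + sigma * Phi^-1(target)``.  The No-Bias fit supplies all
    four targets; the blue-bias fit the two high targets and the orange-bias
    fit the two low ones.  Levels outside the decision region are rejected.
    """
    targets = tuple(sorted(targets))
    specs: list[StimulusSpec] = []
    plan = [
        (Condition.NO_BIAS, BiasDirection.NONE, targets),
        (Condition.BIAS, BiasDirection.BLUE, tuple(t for t in targets if t > 0.5)),
        (Condition.BIAS, BiasDirection.ORANGE, tuple(t for t in targets if t < 0.5)),
    ]
    for condition, bias_direction, tgts in plan:
        fit = fits[(condition, bias_direction)]
        for t in tgts:
            theta = fit.quantile(t)
            if abs(theta) >= DECISION_REGION_DEG:
                raise ValueError(
                    f"selected level {theta:.1f} deg for target {t} lies outside "
                    "the decision region"
                )
            specs.append(
                StimulusSpec(
                    condition=condition,
                    theta=theta,
                    bias_direction=bias_direction,
                    targeted_p_blue=t,
                )
            )
    return specs


def calibrate_settings(
    model_tag: ModelTag | str,
    params: ObserverParams,
    rng: np.random.Generator,
    config: ASAConfig | None = None,
    targets: tuple[float, ...] = DEFAULT_TARGETS,
):
    """ASA -> psychometric fit -> quantile selection, end to end."""
    config = config or ASAConfig()
    staircases = run_asa_staircase(model_tag, params, config, rng)
    fits = {key: _fit_procedure(runs) for key, runs in staircases.items()}
    settings = select_stimulus_levels(fits, targets)
    return settings, fits, staircases


def ideal_stimulus_levels(
    model_tag: ModelTag | str,
    params: ObserverParams,
    targets: tuple[float, ...] = DEFAULT_TARGETS,
) -> list[StimulusSpec]:
    """Noise-free calibration: exact quantiles of the observer's psychometric.

    Used where calibration noise is undesirable (e.g. model recovery), by
    inverting the observer's exact P('Blue' | theta) with a root finder.
    """
    from scipy.optimize import brentq

    targets = tuple(sorted(targets))
    specs: list[StimulusSpec] = []
    plan = [
        (Condition.NO_BIAS, BiasDirection.NONE, targets),
        (Condition.BIAS, BiasDirection.BLUE, tuple(t for t in targets if t > 0.5)),
        (Condition.BIAS, BiasDirection.ORANGE, tuple(t for t in targets if t < 0.5)),
    ]
    for condition, bias_direction, tgts in plan:
        p_blue = observers.first_order_choice_function(
            model_tag, params, condition, bias_direction
        )
        for t in tgts:
            theta = float(
                brentq(
                    lambda x: float(np.asarray(p_blue(x)).ravel()[0]) - t,
                    -89.99,
                    89.99,
                    xtol=1e-8,
                )
            )
            specs.append(
                StimulusSpec(
                    condition=condition,
                    theta=theta,
                    bias_direction=bias_direction,
                    targeted_p_blue=t,
                )
            )
    return specs


_COLUMNS = [
    "observer_id",
    "trial",
    "int1_condition",
    "int1_theta",
    "int1_bias_direction",
    "int1_line_orientation",
    "int1_targeted_p_blue",
    "int2_condition",
    "int2_theta",
    "int2_bias_direction",
    "int2_line_orientation",
    "int2_targeted_p_blue",
    "response1",
    "response2",
    "confidence_choice",
    "rt1",
    "rt2",
    "rt_conf",
]

SCHEMA_VERSION = 1


def simulate_dataset(
    design: TrialDesign,
    model_tag: ModelTag | str,
    params: ObserverParams,
    seed: int,
    observer_id: str = "obs1",
) -> pd.DataFrame:
    """Simulate one observer's full trial table (one row per CFC trial)."""
    rng = np.random.default_rng(seed)
    records = observers.simulate_trials(design.trials, model_tag, params, rng)
    rows = []
    for t, rec in enumerate(records):
        row: dict = {"observer_id": observer_id, "trial": t + 1}
        for j, stim in enumerate(rec.stimuli, start=1):
            row[f"int{j}_condition"] = stim.condition.value
            row[f"int{j}_theta"] = stim.theta
            row[f"int{j}_bias_direction"] = stim.bias_direction.value
            row[f"int{j}_line_orientation"] = stim.line_orientation
            row[f"int{j}_targeted_p_blue"] = stim.targeted_p_blue
        row["response1"], row["response2"] = rec.responses
        row["confidence_choice"] = rec.confidence_choice
        row["rt1"], row["rt2"], row["rt_conf"] = rec.rts
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def selected_levels_table(settings, observer_id: str = "obs1") -> pd.DataFrame:
    """Tidy table of an observer's calibrated levels (for exclusion checks)."""
    return pd.DataFrame(
        [
            {
                "observer_id": observer_id,
                "condition": s.condition.value,
                "bias_direction": s.bias_direction.value,
                "targeted_p_blue": s.targeted_p_blue,
                "theta": s.theta,
            }
            for s in settings
        ]
    )


def write_dataset(
    df: pd.DataFrame,
    path,
    manifest: dict | None = None,
    manifest_path=None,
) -> None:
    """Write a trial table as CSV (deterministic formatting) plus manifest."""
    df.to_csv(path, index=False, float_format="%.10g")
    if manifest is not None and manifest_path is not None:
        manifest = {"schema_version": SCHEMA_VERSION, **manifest}
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_dataset(path) -> pd.DataFrame:
    return pd.read_csv(path)
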