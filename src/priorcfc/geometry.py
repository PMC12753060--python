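"""Angle conventions and deterministic stimulus-space transforms.

All angles are expressed in degrees relative to the reference that separates
the orange and blue choice regions.  The sign convention used throughout the
package is: motion toward the orange region is *negative*, motion toward the
blue region is *positive*.  The allowed decision region spans (-90, +90).

In the No-Bias condition the two prior-preferred (orthogonal) motion
directions sit at +/-90 deg, symmetric about the reference.  In the Bias
condition one preferred direction sits 35 deg into the biased color's region
and the other 145 deg away on the opposite side, outside the decision region.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Condition",
    "BiasDirection",
    "StimulusSpec",
    "PreferredDirections",
    "BIAS_OFFSET_DEG",
    "DECISION_REGION_DEG",
    "LINE_ORIENTATIONS_DEG",
    "preferred_directions",
    "project_orange_to_blue",
    "normalize_stimulus",
]

#: Angular offset (deg) of the preferred direction from the reference in the
#: Bias condition; the mirror component sits at 180 - 35 = 145 deg.
BIAS_OFFSET_DEG = 35.0

#: Half-width (deg) of the allowed decision region around the reference.
DECISION_REGION_DEG = 90.0

#: Permitted line tilts from vertical (deg); cardinal orientations excluded.
LINE_ORIENTATIONS_DEG = (10, 20, 30, 40, 50, 60, 70, 80)


class Condition(str, enum.Enum):
    BIAS = "Bias"
    NO_BIAS = "NoBias"


class BiasDirection(str, enum.Enum):
    ORANGE = "orange"
    BLUE = "blue"
    NONE = "none"


@dataclass(frozen=True)
class StimulusSpec:
    """One interval's stimulus setting.

    Parameters
    ----------
    condition
        Whether the prior-preferred direction falls inside a colored region
        (``Bias``) or exactly on the region boundary (``NoBias``).
    theta
        Signed motion-direction angle from the reference in degrees;
        negative toward orange, positive toward blue.
    bias_direction
        Which color the preferred direction falls into; ``none`` iff the
        condition is ``NoBias``.
    line_orientation
        Tilt of the moving lines from vertical in degrees, signed for
        clockwise (+) versus counterclockwise (-); carried as metadata only.
    targeted_p_blue
        The choice rate P('Blue') this setting was calibrated to produce,
        if any (used by the design and analysis layers).
    """

    condition: Condition
    theta: float
    bias_direction: BiasDirection = BiasDirection.NONE
    line_orientation: float = 0.0
    targeted_p_blue: float | None = None

    def __post_init__(self) -> None:
        if not -DECISION_REGION_DEG < self.theta < DECISION_REGION_DEG:
            raise ValueError(
                f"theta must lie inside (+/-{DECISION_REGION_DEG}), got {self.theta}"
            )
        if (self.condition is Condition.NO_BIAS) != (
            self.bias_direction is BiasDirection.NONE
        ):
            raise ValueError(
                "bias_direction must be 'none' iff condition is NoBias "
                f"(got {self.condition.value!r}, {self.bias_direction.value!r})"
            )


@dataclass(frozen=True)
class PreferredDirections:
    """The two mixture-prior means, in reference-relative degrees.

    ``mu_orth1`` is the component inside (or on the edge of) the decision
    region; ``mu_orth2`` is its antipode, 180 deg away.
    """

    mu_orth1: float
    mu_orth2: float

    def __post_init__(self) -> None:
        sep = (self.mu_orth1 - self.mu_orth2) % 360.0
        if abs(sep - 180.0) > 1e-9:
            raise ValueError("preferred directions must be 180 deg apart")


def preferred_directions(
    condition: Condition, bias_direction: BiasDirection = BiasDirection.NONE
) -> PreferredDirections:
    """Mixture-prior means for a condition / bias-direction combination.

    No-Bias -> (+90, -90).  A blue bias puts the primary component at +35
    (and the antipode at -145); an orange bias mirrors this to (-35, +145).
    """
    condition = Condition(condition)
    bias_direction = BiasDirection(bias_direction)
    if condition is Condition.NO_BIAS:
        if bias_direction is not BiasDirection.NONE:
            raise ValueError("NoBias condition takes no bias direction")
        return PreferredDirections(+DECISION_REGION_DEG, -DECISION_REGION_DEG)
    if bias_direction is BiasDirection.BLUE:
        return PreferredDirections(+BIAS_OFFSET_DEG, BIAS_OFFSET_DEG - 180.0)
    if bias_direction is BiasDirection.ORANGE:
        return PreferredDirections(-BIAS_OFFSET_DEG, 180.0 - BIAS_OFFSET_DEG)
    raise ValueError("Bias condition requires an orange or blue bias direction")


def project_orange_to_blue(
    theta_orange: float, response: int | float, mu_nobias: float
) -> tuple[float, int]:
    """Reflect an orange-bias trial into the blue-bias space.

    The projection mirrors the stimulus about the No-Bias point of subjective
    equality, ``theta -> mu_nobias - theta``, and flips the response code
    (1 = Blue, 0 = Orange), so that both bias directions collapse onto a
    single psychometric function.
    """
    return mu_nobias - theta_orange, 1 - int(round(response))


def normalize_stimulus(theta: float, mu_nobias: float, sigma_nobias: float) -> float:
    """Express a stimulus angle in units of an observer's No-Bias sensitivity.

    ``theta_norm = (theta - mu_nobias) / sigma_nobias`` puts observers with
    different baseline bias and noise on a common scale before pooling.
    """
    if sigma_nobias <= 0:
        raise ValueError(f"sigma_nobias must be positive, got {sigma_nobias}")
    return (theta - mu_nobias) / sigma_nobias
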