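"""Exercise-protocol arithmetic for supine bicycling stress MRI.

Age-predicted maximal heart rate HRmax = 211 - 0.64 * age (beats/min),
multiplied by 0.9 to adjust for the lower HRmax attainable during supine
(vs. upright) ergometry.  Steady-state exercise stages target 60% (moderate)
and 80% (vigorous) of the supine HRmax.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

MODERATE_FRACTION = 0.60
VIGOROUS_FRACTION = 0.80
SUPINE_ADJUSTMENT = 0.9


def supine_hr_max(age_years: float) -> float:
    """Supine maximal heart rate (beats/min): 0.9 * (211 - 0.64 * age)."""
    if not (0 < age_years < 120):
        raise ConfigError(f"age {age_years} out of plausible range (0, 120)")
    return SUPINE_ADJUSTMENT * (211.0 - 0.64 * age_years)


def stage_fraction(observed_hr: float, age_years: float) -> float:
    """Observed heart rate as a percentage of the supine maximal heart rate."""
    if observed_hr <= 0:
        raise ConfigError("observed_hr must be > 0")
    return 100.0 * observed_hr / supine_hr_max(age_years)


@dataclass(frozen=True)
class ExerciseTargets:
    """Stage heart-rate targets for one subject (all beats/min, unrounded)."""

    age: float
    hr_max_upright: float
    hr_max_supine: float
    moderate_target: float  # 60% of supine HRmax
    vigorous_target: float  # 80% of supine HRmax


def exercise_targets(age_years: float) -> ExerciseTargets:
    """Compute the full target set for one subject.

    Displayed values round to the nearest integer; the returned fields stay
    unrounded.
    """
    upright = 211.0 - 0.64 * age_years
    supine = supine_hr_max(age_years)
    return ExerciseTargets(
        age=age_years,
        hr_max_upright=upright,
        hr_max_supine=supine,
        moderate_target=MODERATE_FRACTION * supine,
        vigorous_target=VIGOROUS_FRACTION * supine,
    )


__all__ = ["supine_hr_max", "stage_fraction", "ExerciseTargets", "exercise_targets"]
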