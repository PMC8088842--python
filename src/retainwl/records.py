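"""Domain records: per-user profiles and weekly lifelog entries.

A cohort is a pair of flat tables: one profile row per user (time-fixed
descriptors recorded at sign-up) and one lifelog row per user-week
(behavioral app-usage measurements plus the logged weight), weeks numbered
1..16 over the coaching program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

N_WEEKS = 16

#: Names of the seven weekly behavior variables, in canonical column order.
BEHAVIOR_VARIABLES = (
    "weight_input_freq",
    "meal_input_adherence",
    "exercise_input_freq",
    "calorie_intake",
    "steps_k",
    "alcohol_drinks",
    "over_calorie_events",
)

#: Semantic names of the five weight-trajectory archetypes, canonical order.
ARCHETYPES = (
    "sharp decrease",
    "moderate decrease",
    "yo-yo",
    "increase",
    "other",
)

#: Reserved label for weeks where no trajectory cluster can be assigned yet
#: (week 1 prefixes cannot be z-normalized).
UNASSIGNED = "unassigned"


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m² from weight in kg and height in cm."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError(
            f"weight and height must be positive, got {weight_kg} kg, {height_cm} cm"
        )
    return weight_kg / (height_cm / 100.0) ** 2


def obesity_class(bmi: float) -> str | None:
    """CDC adult obesity class for a BMI, or None below the overweight cutoff.

    Bands are half-open with inclusive lower bounds: overweight [25, 30),
    obese class I [30, 35), II [35, 40), III ≥ 40.
    """
    if bmi <= 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if bmi < 25:
        return None
    if bmi < 30:
        return "overweight"
    if bmi < 35:
        return "obese class I"
    if bmi < 40:
        return "obese class II"
    return "obese class III"


@dataclass(frozen=True)
class UserProfile:
    """Time-fixed descriptors of one program participant."""

    user_id: str
    gender: str  # "female" | "male"
    age: float  # years
    height: float  # cm
    initial_weight: float  # kg
    target_weight: float  # kg
    bmi: float = field(init=False)
    obesity_class: str | None = field(init=False)

    def __post_init__(self) -> None:
        if self.gender not in ("female", "male"):
            raise ValueError(f"unknown gender {self.gender!r}")
        object.__setattr__(self, "bmi", compute_bmi(self.initial_weight, self.height))
        object.__setattr__(self, "obesity_class", obesity_class(self.bmi))


@dataclass(frozen=True)
class WeeklyLog:
    """One user-week of lifelog measurements.

    Units: weight_input_freq, exercise_input_freq, alcohol_drinks and
    over_calorie_events are counts per week; meal_input_adherence is a
    percentage in [0, 100]; calorie_intake is kcal per day; steps_k is
    thousands of daily steps; weight is the logged body weight in kg.
    """

    user_id: str
    week: int  # 1-based, 1..16
    weight_input_freq: float
    meal_input_adherence: float
    exercise_input_freq: float
    calorie_intake: float
    steps_k: float
    alcohol_drinks: float
    over_calorie_events: float
    weight: float

    def __post_init__(self) -> None:
        if not 1 <= self.week <= N_WEEKS:
            raise ValueError(f"week must be in 1..{N_WEEKS}, got {self.week}")
        if not 0 <= self.meal_input_adherence <= 100:
            raise ValueError(
                f"meal_input_adherence must be in [0, 100], got {self.meal_input_adherence}"
            )
        for name in ("weight_input_freq", "exercise_input_freq", "calorie_intake",
                     "steps_k", "alcohol_drinks", "over_calorie_events"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")

    def behavior_vector(self) -> tuple[float, ...]:
        return tuple(getattr(self, v) for v in BEHAVIOR_VARIABLES)
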