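"""Synthetic 16-week weight-loss cohort with a known linear ground truth.

The generator emulates the marginal demographics of a large commercial
mobile weight-loss program (age 43.2 ± 10.8 y, 92.2% female, height
166.4 ± 7.5 cm, initial weight 93.4 ± 17.8 kg, BMI ≥ 25) and five weekly
weight-trajectory archetypes (sharp decrease, moderate decrease, yo-yo,
increase, other). The week-16 outcome follows a known additive model

    final = initial + Σ_v effect_v · z_v + effect_archetype + ε,

where z_v is the user's standardized 16-week mean of behavior v and ε is
Gaussian outcome noise, so downstream models can be checked against the
true effect signs and magnitudes. Weekly weight paths interpolate from the
initial to the final weight along the archetype's shape profile, with the
behavior/noise residual accrued linearly and week-to-week weigh-in jitter
added to interior weeks; week 1 equals the initial weight and week 16
equals the outcome exactly.

Behaviors are habitual: each user draws a latent per-variable mean
(between-user spread) and weekly values fluctuate around it (within-user
spread). Setting the within-user spread to zero makes weekly behaviors
constant; :meth:`GeneratorConfig.noiseless` switches off all three noise
channels at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .records import ARCHETYPES, BEHAVIOR_VARIABLES, N_WEEKS, UserProfile, WeeklyLog

__all__ = [
    "BehaviorSpec",
    "DemographicSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "ground_truth",
    "archetype_profile",
]


@dataclass(frozen=True)
class BehaviorSpec:
    """Location/scale/bounds for one weekly behavior variable.

    ``between_sd`` spreads the per-user latent mean; ``within_sd`` is the
    week-to-week fluctuation around it. Weekly draws are truncated to
    [lower, upper].
    """

    mean: float
    between_sd: float
    within_sd: float
    lower: float
    upper: float


@dataclass(frozen=True)
class DemographicSpec:
    age_mean: float = 43.2
    age_sd: float = 10.8
    age_range: tuple[float, float] = (18.0, 65.0)
    female_fraction: float = 0.922
    height_mean: float = 166.4
    height_sd: float = 7.5
    height_range: tuple[float, float] = (125.0, 230.0)
    weight_mean: float = 93.4
    weight_sd: float = 17.8
    weight_max: float = 250.0
    bmi_min: float = 25.0
    target_fraction_range: tuple[float, float] = (0.85, 0.95)


def _default_behaviors() -> dict[str, BehaviorSpec]:
    return {
        "weight_input_freq": BehaviorSpec(5.0, 1.5, 1.2, 1.0, 21.0),
        "meal_input_adherence": BehaviorSpec(70.0, 15.0, 8.0, 5.0, 100.0),
        "exercise_input_freq": BehaviorSpec(3.0, 1.5, 1.2, 0.0, 21.0),
        "calorie_intake": BehaviorSpec(1600.0, 250.0, 150.0, 600.0, 4000.0),
        "steps_k": BehaviorSpec(6.0, 2.0, 1.5, 0.0, 30.0),
        "alcohol_drinks": BehaviorSpec(1.5, 1.2, 1.0, 0.0, 30.0),
        "over_calorie_events": BehaviorSpec(1.5, 1.0, 0.8, 0.0, 7.0),
    }


def _default_effects() -> dict[str, float]:
    # kg per SD of the 16-week behavior aggregate; archetype entries are the
    # archetype's endpoint effect in kg (the shape-curve value at week 16).
    return {
        "weight_input_freq": -0.5,
        "meal_input_adherence": -0.6,
        "exercise_input_freq": -0.4,
        "calorie_intake": 0.8,
        "steps_k": -0.3,
        "alcohol_drinks": 0.3,
        "over_calorie_events": 0.4,
        "sharp decrease": -11.2,
        "moderate decrease": -4.7,
        "yo-yo": -1.9,
        "increase": 2.8,
        "other": 0.0,
    }


def archetype_profile(name: str) -> np.ndarray:
    """Normalized shape curve of an archetype over weeks 1..16.

    The profile is 0 at week 1 and 1 at week 16; multiplied by the
    archetype's endpoint effect (kg) it gives the archetype component of
    the weekly weight path. Sharp decrease approaches its endpoint
    exponentially; moderate decrease and increase are linear; yo-yo
    overshoots to ~2.6× its (small) net endpoint at week 8 and rebounds.
    """
    t = np.arange(1, N_WEEKS + 1, dtype=float)
    if name == "sharp decrease":
        gamma = 0.3
        return (1.0 - np.exp(-gamma * (t - 1))) / (1.0 - np.exp(-gamma * (N_WEEKS - 1)))
    if name in ("moderate decrease", "increase", "other"):
        return (t - 1) / (N_WEEKS - 1)
    if name == "yo-yo":
        # reference path: 0 kg -> -5 kg at week 8 -> -1.9 kg at week 16,
        # expressed in units of the endpoint (-1.9).
        ref = np.where(t <= 8, -5.0 * (t - 1) / 7.0, -5.0 + 3.1 * (t - 8) / 8.0)
        return ref / -1.9
    raise ValueError(f"unknown archetype {name!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of the synthetic cohort's data-generating process."""

    n_users: int = 500
    seed: int = 0
    archetype_mix: tuple[float, ...] = (0.18, 0.40, 0.15, 0.07, 0.20)
    behaviors: dict[str, BehaviorSpec] = field(default_factory=_default_behaviors)
    true_effects: dict[str, float] = field(default_factory=_default_effects)
    noise_sd: float = 1.0  # kg, outcome noise
    weekly_jitter_sd: float = 0.5  # kg, weigh-in fluctuation on interior weeks
    archetype_coupling_sd: float = 1.0  # kg, see generate_cohort
    demographics: DemographicSpec = field(default_factory=DemographicSpec)

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError(f"n_users must be >= 1, got {self.n_users}")
        if self.noise_sd < 0 or self.weekly_jitter_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if len(self.archetype_mix) != len(ARCHETYPES):
            raise ValueError("archetype_mix must have 5 entries")
        if any(p < 0 for p in self.archetype_mix):
            raise ValueError("archetype_mix entries must be non-negative")
        if abs(sum(self.archetype_mix) - 1.0) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")
        missing = [k for k in (*BEHAVIOR_VARIABLES, *ARCHETYPES) if k not in self.true_effects]
        if missing:
            raise ValueError(f"true_effects missing entries for {missing}")

    def noiseless(self) -> "GeneratorConfig":
        """Variant with all noise channels off: no outcome noise, no weigh-in
        jitter, and weekly behaviors pinned at the user's latent mean."""
        behaviors = {
            k: replace(v, within_sd=0.0) for k, v in self.behaviors.items()
        }
        return replace(self, noise_sd=0.0, weekly_jitter_sd=0.0, behaviors=behaviors)

    def aggregate_scale(self, var: str) -> float:
        """SD used to standardize the 16-week mean of a behavior in the
        ground-truth outcome model (between² + within²/16, untruncated)."""
        spec = self.behaviors[var]
        return float(np.sqrt(spec.between_sd**2 + spec.within_sd**2 / N_WEEKS)) or 1.0


@dataclass
class SyntheticCohort:
    """Generated profiles, per-user 16-week logs, truth, and archetype labels."""

    profiles: list[UserProfile]
    logs: dict[str, list[WeeklyLog]]
    truth: dict[str, float]
    archetype_labels: dict[str, str]
    config: GeneratorConfig

    def __post_init__(self) -> None:
        for p in self.profiles:
            if len(self.logs[p.user_id]) != N_WEEKS:
                raise ValueError(f"user {p.user_id} does not have {N_WEEKS} weekly logs")
            if p.bmi < 25:
                raise ValueError(f"user {p.user_id} has BMI {p.bmi:.2f} < 25")

    @property
    def user_ids(self) -> list[str]:
        return [p.user_id for p in self.profiles]

    def weight_series(self, user_id: str) -> np.ndarray:
        return np.array([l.weight for l in sorted(self.logs[user_id], key=lambda l: l.week)])

    def final_weights(self) -> np.ndarray:
        return np.array([self.weight_series(u)[-1] for u in self.user_ids])


def _tn_loc_for_mean(target: np.ndarray, sd: float, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Location parameter such that a truncated normal TN(loc, sd; lo, hi)
    has the requested mean (vectorized bisection; mean is monotone in loc)."""
    target = np.asarray(target, dtype=float)
    lo_b = np.broadcast_to(np.asarray(lo, dtype=float), target.shape).copy()
    hi_b = np.broadcast_to(np.asarray(hi, dtype=float), target.shape).copy()

    def tn_mean(loc: np.ndarray) -> np.ndarray:
        a = (lo_b - loc) / sd
        b = (hi_b - loc) / sd
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        return loc + sd * (stats.norm.pdf(a) - stats.norm.pdf(b)) / np.maximum(z, 1e-300)

    low = target - 6 * sd
    high = target + 6 * sd
    for _ in range(60):
        mid = 0.5 * (low + high)
        too_low = tn_mean(mid) < target
        low = np.where(too_low, mid, low)
        high = np.where(too_low, high, mid)
    return 0.5 * (low + high)


def _truncnorm(rng: np.random.Generator, loc, sd: float, lo, hi, size) -> np.ndarray:
    if sd == 0:
        return np.clip(np.broadcast_to(np.asarray(loc, dtype=float), size).copy(), lo, hi)
    a = (np.asarray(lo) - loc) / sd
    b = (np.asarray(hi) - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw a reproducible synthetic cohort from the configured process.

    Demographic samplers are mean-corrected truncated normals, so sampled
    means match the configured Table-style marginals despite truncation
    (initial weight is truncated below at the BMI-25 weight for the user's
    height). The same seed always yields an identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    d = config.demographics

    age_loc = _tn_loc_for_mean(np.full(n, d.age_mean), d.age_sd, *d.age_range)
    age = _truncnorm(rng, age_loc, d.age_sd, *d.age_range, size=n)
    female = rng.random(n) < d.female_fraction
    height_loc = _tn_loc_for_mean(np.full(n, d.height_mean), d.height_sd, *d.height_range)
    height = _truncnorm(rng, height_loc, d.height_sd, *d.height_range, size=n)
    weight_lo = d.bmi_min * (height / 100.0) ** 2
    weight_loc = _tn_loc_for_mean(
        np.full(n, d.weight_mean), d.weight_sd, weight_lo, np.full(n, d.weight_max)
    )
    initial = _truncnorm(rng, weight_loc, d.weight_sd, weight_lo, d.weight_max, size=n)
    target = initial * rng.uniform(*d.target_fraction_range, size=n)

    profiles_by_arch = {a: archetype_profile(a) for a in ARCHETYPES}

    # weekly behaviors: (n, weeks) per variable
    behavior_weekly: dict[str, np.ndarray] = {}
    agg_z: dict[str, np.ndarray] = {}
    for var in BEHAVIOR_VARIABLES:
        spec = config.behaviors[var]
        latent = _truncnorm(rng, spec.mean, spec.between_sd, spec.lower, spec.upper, size=n)
        weekly = _truncnorm(
            rng, latent[:, None], spec.within_sd, spec.lower, spec.upper, size=(n, N_WEEKS)
        )
        behavior_weekly[var] = weekly
        agg_z[var] = (weekly.mean(axis=1) - spec.mean) / config.aggregate_scale(var)

    behavior_effect = sum(config.true_effects[v] * agg_z[v] for v in BEHAVIOR_VARIABLES)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)

    # Archetype membership is mildly coupled to the behavior+noise-driven net
    # change: the "other" archetype (flat + noise trajectories) is taken by
    # the users whose non-archetype net change is nearest zero (noisy
    # ranking), so flat shapes really are flat; the four shaped archetypes
    # are distributed randomly among the rest. Quotas follow the mix by
    # largest remainder.
    quotas = np.floor(np.asarray(config.archetype_mix) * n).astype(int)
    remainder = np.asarray(config.archetype_mix) * n - quotas
    for j in np.argsort(-remainder)[: n - quotas.sum()]:
        quotas[j] += 1
    other_j = ARCHETYPES.index("other")
    abs_score = np.abs(
        behavior_effect + noise
        + rng.normal(0.0, config.archetype_coupling_sd, size=n)
    )
    order = np.argsort(abs_score, kind="stable")
    other_users = order[: quotas[other_j]]
    rest = rng.permutation(order[quotas[other_j]:])
    arch_idx = np.empty(n, dtype=int)
    arch_idx[other_users] = other_j
    pos = 0
    for j in range(len(ARCHETYPES)):
        if j == other_j:
            continue
        arch_idx[rest[pos: pos + quotas[j]]] = j
        pos += quotas[j]

    arch_effect = np.array([config.true_effects[a] for a in ARCHETYPES])[arch_idx]
    final = initial + behavior_effect + arch_effect + noise
    final = np.maximum(final, 0.3 * initial)  # physiological floor; never hit at defaults

    jitter = (
        rng.normal(0.0, config.weekly_jitter_sd, size=(n, N_WEEKS))
        if config.weekly_jitter_sd > 0
        else np.zeros((n, N_WEEKS))
    )
    jitter[:, 0] = 0.0
    jitter[:, -1] = 0.0

    profiles: list[UserProfile] = []
    logs: dict[str, list[WeeklyLog]] = {}
    labels: dict[str, str] = {}
    width = len(str(n - 1))
    for i in range(n):
        uid = f"u{i:0{width}d}"
        arch = ARCHETYPES[arch_idx[i]]
        # the whole net change follows the archetype's shape profile
        path = initial[i] + (final[i] - initial[i]) * profiles_by_arch[arch] + jitter[i]
        path = np.maximum(path, 20.0)
        profiles.append(
            UserProfile(
                user_id=uid,
                gender="female" if female[i] else "male",
                age=float(age[i]),
                height=float(height[i]),
                initial_weight=float(initial[i]),
                target_weight=float(target[i]),
            )
        )
        labels[uid] = arch
        logs[uid] = [
            WeeklyLog(
                user_id=uid,
                week=w + 1,
                weight_input_freq=float(behavior_weekly["weight_input_freq"][i, w]),
                meal_input_adherence=float(behavior_weekly["meal_input_adherence"][i, w]),
                exercise_input_freq=float(behavior_weekly["exercise_input_freq"][i, w]),
                calorie_intake=float(behavior_weekly["calorie_intake"][i, w]),
                steps_k=float(behavior_weekly["steps_k"][i, w]),
                alcohol_drinks=float(behavior_weekly["alcohol_drinks"][i, w]),
                over_calorie_events=float(behavior_weekly["over_calorie_events"][i, w]),
                weight=float(path[w]),
            )
            for w in range(N_WEEKS)
        ]

    return SyntheticCohort(
        profiles=profiles,
        logs=logs,
        truth=ground_truth(config),
        archetype_labels=labels,
        config=config,
    )


def ground_truth(config: GeneratorConfig) -> dict[str, float]:
    """The signed kg effects (per behavior SD / per archetype) the generator
    uses, for parameter-recovery assertions."""
    return dict(config.true_effects)
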