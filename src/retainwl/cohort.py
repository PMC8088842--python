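"""Eligibility filtering and profile-level outcome categorisation.

The study population is adults (18-65 y) with BMI ≥ 25 who completed a
16-week mobile coaching program, logged weight and meals in every week,
and aimed to lose weight (target weight below initial weight). Filters are
applied in a fixed order and an exclusion report accounts for every user.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

from .records import N_WEEKS, UserProfile, WeeklyLog, compute_bmi, obesity_class

__all__ = [
    "compute_bmi",
    "obesity_class",
    "outcome_category",
    "filter_eligible",
    "ExclusionReport",
    "HEIGHT_RANGE",
    "AGE_RANGE",
    "BMI_MIN",
]

HEIGHT_RANGE = (125.0, 230.0)  # cm
AGE_RANGE = (18.0, 65.0)  # years
BMI_MIN = 25.0  # kg/m²

#: Filter names in application order.
FILTER_ORDER = (
    "incomplete_program",
    "incomplete_records",
    "target_not_below_initial",
    "height_out_of_range",
    "age_out_of_range",
    "bmi_below_25",
)

#: Outcome category labels, from weight gain to large loss.
OUTCOME_CATEGORIES = (
    "gained >2%",
    "stable",
    "loss 2-5%",
    "loss 5-10%",
    "loss 10-15%",
    "loss >15%",
)


def outcome_category(initial_weight: float, final_weight: float) -> str:
    """Categorise the 16-week outcome by percentage weight change.

    Change is p = 100 × (initial − final) / initial. Bands are half-open
    with inclusive lower bounds on the loss side: a gain of more than 2% is
    "gained >2%"; p in [−2, 2) is "stable"; then [2,5), [5,10), [10,15) and
    ≥ 15% loss.
    """
    if initial_weight <= 0 or final_weight <= 0:
        raise ValueError("weights must be positive")
    p = 100.0 * (initial_weight - final_weight) / initial_weight
    if p < -2:
        return "gained >2%"
    if p < 2:
        return "stable"
    if p < 5:
        return "loss 2-5%"
    if p < 10:
        return "loss 5-10%"
    if p < 15:
        return "loss 10-15%"
    return "loss >15%"


@dataclass
class ExclusionReport:
    """Per-filter exclusion counts, in the order filters were applied."""

    n_in: int
    n_out: int
    exclusions: "OrderedDict[str, int]"

    def __post_init__(self) -> None:
        total = self.n_out + sum(self.exclusions.values())
        if total != self.n_in:
            raise ValueError(
                f"exclusion counts do not reconcile: {self.n_out} kept + "
                f"{sum(self.exclusions.values())} excluded != {self.n_in} input"
            )

    def summary(self) -> str:
        lines = [f"users in: {self.n_in}"]
        for name, count in self.exclusions.items():
            lines.append(f"  excluded ({name}): {count}")
        lines.append(f"users eligible: {self.n_out}")
        return "\n".join(lines)


def _has_complete_program(logs: list[WeeklyLog]) -> bool:
    return sorted(l.week for l in logs) == list(range(1, N_WEEKS + 1))

def _has_complete_records(logs: list[WeeklyLog]) -> bool:
    # "weight or meal records for the entire program": at least one weight
    # entry and non-zero meal logging in every one of the 16 weeks.
    return all(l.weight_input_freq >= 1 and l.meal_input_adherence > 0 for l in logs)


def filter_eligible(
    profiles: list[UserProfile],
    logs_by_user: dict[str, list[WeeklyLog]],
) -> tuple[list[UserProfile], ExclusionReport]:
    """Apply the eligibility filters in order; return survivors and a report.

    Each user is counted against the first filter that rejects them, so the
    per-filter counts plus the eligible count always sum to the input count.
    Raises ValueError on duplicate user ids.
    """
    seen: set[str] = set()
    for p in profiles:
        if p.user_id in seen:
            raise ValueError(f"duplicate user_id {p.user_id!r}")
        seen.add(p.user_id)

    counts: "OrderedDict[str, int]" = OrderedDict((f, 0) for f in FILTER_ORDER)
    eligible: list[UserProfile] = []
    for p in profiles:
        logs = logs_by_user.get(p.user_id, [])
        if len(logs) > N_WEEKS:
            raise ValueError(f"user {p.user_id!r} has more than {N_WEEKS} weekly logs")
        if not _has_complete_program(logs):
            counts["incomplete_program"] += 1
        elif not _has_complete_records(logs):
            counts["incomplete_records"] += 1
        elif not p.target_weight < p.initial_weight:
            counts["target_not_below_initial"] += 1
        elif not HEIGHT_RANGE[0] <= p.height <= HEIGHT_RANGE[1]:
            counts["height_out_of_range"] += 1
        elif not AGE_RANGE[0] <= p.age <= AGE_RANGE[1]:
            counts["age_out_of_range"] += 1
        elif not p.bmi >= BMI_MIN:
            counts["bmi_below_25"] += 1
        else:
            eligible.append(p)
    report = ExclusionReport(n_in=len(profiles), n_out=len(eligible), exclusions=counts)
    return eligible, report
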