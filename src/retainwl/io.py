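"""Delimited-text schemas and artifact persistence.

Cohorts travel as two UTF-8 CSV files with headers:

``profiles.csv``: user_id, gender, age, height_cm, initial_weight_kg,
target_weight_kg — one row per user.

``logs.csv``: user_id, week, weight_input_freq, meal_input_adherence,
exercise_input_freq, calorie_intake, steps_k, alcohol_drinks,
over_calorie_events, weight_kg — one row per user-week, weeks 1-based.

Row-level problems are collected with line numbers and reported together.
Fitted artifacts (trajectory model, network parameters) are persisted as
JSON with their seeds and a schema version embedded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelParameters
from .records import UserProfile, WeeklyLog
from .trajectories import TrajectoryModel

__all__ = [
    "DataFormatError",
    "PROFILE_COLUMNS",
    "LOG_COLUMNS",
    "read_profiles",
    "read_logs",
    "write_profiles",
    "write_logs",
    "write_truth",
    "read_truth",
    "save_trajectory_model",
    "load_trajectory_model",
    "save_model_params",
    "load_model_params",
]

SCHEMA_VERSION = 1

PROFILE_COLUMNS = (
    "user_id", "gender", "age", "height_cm", "initial_weight_kg", "target_weight_kg",
)
LOG_COLUMNS = (
    "user_id", "week", "weight_input_freq", "meal_input_adherence",
    "exercise_input_freq", "calorie_intake", "steps_k", "alcohol_drinks",
    "over_calorie_events", "weight_kg",
)


class DataFormatError(ValueError):
    """A delimited-text file does not conform to its schema."""

    def __init__(self, path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        shown = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"{path}: {len(problems)} problem(s):\n  {shown}{more}")


def _check_columns(df: pd.DataFrame, expected, path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataFormatError(path, [f"missing columns: {missing}"])


def read_profiles(path) -> list[UserProfile]:
    """Parse and validate a profiles CSV; raises on duplicate user ids or
    malformed rows (reported with line numbers)."""
    df = pd.read_csv(path, dtype={"user_id": str}, float_precision="round_trip")
    _check_columns(df, PROFILE_COLUMNS, path)
    problems: list[str] = []
    profiles: list[UserProfile] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            uid = str(row["user_id"])
            if uid in seen:
                raise ValueError(f"duplicate user_id {uid!r}")
            seen.add(uid)
            profiles.append(
                UserProfile(
                    user_id=uid,
                    gender=str(row["gender"]),
                    age=float(row["age"]),
                    height=float(row["height_cm"]),
                    initial_weight=float(row["initial_weight_kg"]),
                    target_weight=float(row["target_weight_kg"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise DataFormatError(path, problems)
    return profiles


def read_logs(path) -> dict[str, list[WeeklyLog]]:
    """Parse and validate a logs CSV into per-user weekly records; duplicate
    (user, week) rows are rejected with their line numbers."""
    df = pd.read_csv(path, dtype={"user_id": str}, float_precision="round_trip")
    _check_columns(df, LOG_COLUMNS, path)
    problems: list[str] = []
    logs: dict[str, list[WeeklyLog]] = {}
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        line = i + 2
        try:
            uid = str(row["user_id"])
            week = int(row["week"])
            if (uid, week) in seen:
                raise ValueError(f"duplicate (user_id, week) = ({uid!r}, {week})")
            seen.add((uid, week))
            logs.setdefault(uid, []).append(
                WeeklyLog(
                    user_id=uid,
                    week=week,
                    weight_input_freq=float(row["weight_input_freq"]),
                    meal_input_adherence=float(row["meal_input_adherence"]),
                    exercise_input_freq=float(row["exercise_input_freq"]),
                    calorie_intake=float(row["calorie_intake"]),
                    steps_k=float(row["steps_k"]),
                    alcohol_drinks=float(row["alcohol_drinks"]),
                    over_calorie_events=float(row["over_calorie_events"]),
                    weight=float(row["weight_kg"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise DataFormatError(path, problems)
    return logs


def write_profiles(profiles: list[UserProfile], path) -> None:
    pd.DataFrame(
        [
            (p.user_id, p.gender, p.age, p.height, p.initial_weight, p.target_weight)
            for p in profiles
        ],
        columns=PROFILE_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def write_logs(logs_by_user: dict[str, list[WeeklyLog]], path) -> None:
    rows = []
    for uid in logs_by_user:
        for l in sorted(logs_by_user[uid], key=lambda l: l.week):
            rows.append(
                (l.user_id, l.week, l.weight_input_freq, l.meal_input_adherence,
                 l.exercise_input_freq, l.calorie_intake, l.steps_k,
                 l.alcohol_drinks, l.over_calorie_events, l.weight)
            )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def write_truth(truth: dict[str, float], path) -> None:
    """Ground-truth effects as a simple ``key<TAB>value`` text file."""
    with open(path, "w") as fh:
        for key, value in truth.items():
            fh.write(f"{key}\t{value!r}\n")


def read_truth(path) -> dict[str, float]:
    truth: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            truth[key] = float(value)
    return truth


def save_trajectory_model(model: TrajectoryModel, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "k": model.k,
        "fit_seed": model.fit_seed,
        "labels": model.labels,
        "degenerate_label": model.degenerate_label,
        "barycenters": model.barycenters.tolist(),
        "inertia_history": model.inertia_history,
        "assignments": model.assignments,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_trajectory_model(path) -> TrajectoryModel:
    payload = json.loads(Path(path).read_text())
    return TrajectoryModel(
        k=payload["k"],
        barycenters=np.array(payload["barycenters"]),
        labels=payload["labels"],
        fit_seed=payload["fit_seed"],
        inertia_history=payload["inertia_history"],
        assignments=payload["assignments"],
        degenerate_label=payload["degenerate_label"],
    )


def save_model_params(params: ModelParameters, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "n_var": params.n_var,
        "n_fixed": params.n_fixed,
        "hidden_size": params.hidden_size,
        "reverse_time": params.reverse_time,
        "seed": params.seed,
        "arrays": {k: v.tolist() for k, v in params.arrays.items()},
        "history": params.history,
    }
    Path(path).write_text(json.dumps(payload))


def load_model_params(path) -> ModelParameters:
    payload = json.loads(Path(path).read_text())
    return ModelParameters(
        arrays={k: np.array(v) for k, v in payload["arrays"].items()},
        n_var=payload["n_var"],
        n_fixed=payload["n_fixed"],
        hidden_size=payload["hidden_size"],
        reverse_time=payload["reverse_time"],
        seed=payload["seed"],
        history=payload["history"],
    )
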