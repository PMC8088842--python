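"""Model-ready tensors: prefix samples, fixed-feature vectors, masks, target.

Every eligible user contributes 16 *prefix samples*: the sample for prefix
week t exposes weeks 1..t (trailing weeks masked) and targets the week-16
weight, so a single trained model predicts the program outcome from any
week. Time-variant inputs are the 7 weekly behaviors plus 5 trajectory-
cluster indicator columns (one-hot of the label assigned in real time at
each week; all-zero while unassigned), N = 12. Time-fixed inputs are
[female, male, age, height, initial weight, overweight, obese I, II, III],
K = 9.

Continuous columns are standardized with statistics fitted on the training
split only (masked entries excluded); indicator columns are left as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .records import ARCHETYPES, BEHAVIOR_VARIABLES, N_WEEKS, UserProfile, WeeklyLog
from .cohort import BMI_MIN

__all__ = [
    "FIXED_FEATURE_NAMES",
    "FeatureTensor",
    "Scaler",
    "encode_fixed",
    "decode_fixed",
    "build_tensor",
    "split_dataset",
    "drop_trajectory_columns",
]

FIXED_FEATURE_NAMES = (
    "female",
    "male",
    "age",
    "height",
    "initial_weight",
    "overweight",
    "obese class I",
    "obese class II",
    "obese class III",
)

#: Time-variant column names in tensor order.
TIME_VARIANT_NAMES = BEHAVIOR_VARIABLES + tuple(f"trajectory:{a}" for a in ARCHETYPES)

_OBESITY_ORDER = ("overweight", "obese class I", "obese class II", "obese class III")
_CONTINUOUS_FIXED = (2, 3, 4)  # age, height, initial weight


def encode_fixed(profile: UserProfile) -> np.ndarray:
    """Length-9 time-fixed vector for an eligible profile."""
    if profile.bmi < BMI_MIN:
        raise ValueError(f"profile {profile.user_id} is not eligible (BMI {profile.bmi:.2f})")
    vec = np.zeros(len(FIXED_FEATURE_NAMES))
    vec[0] = 1.0 if profile.gender == "female" else 0.0
    vec[1] = 1.0 if profile.gender == "male" else 0.0
    vec[2] = profile.age
    vec[3] = profile.height
    vec[4] = profile.initial_weight
    vec[5 + _OBESITY_ORDER.index(profile.obesity_class)] = 1.0
    return vec


def decode_fixed(vec: np.ndarray) -> dict:
    """Recover the categorical and continuous fields from an (unscaled)
    fixed-feature vector."""
    vec = np.asarray(vec, dtype=float)
    gender = "female" if vec[0] == 1.0 else "male"
    cls = None
    for i, name in enumerate(_OBESITY_ORDER):
        if vec[5 + i] == 1.0:
            cls = name
    return {
        "gender": gender,
        "age": float(vec[2]),
        "height": float(vec[3]),
        "initial_weight": float(vec[4]),
        "obesity_class": cls,
    }


@dataclass
class FeatureTensor:
    """Stacked prefix samples: X (S, 16, N), F (S, K), mask (S, 16), y (S,)."""

    X: np.ndarray
    F: np.ndarray
    mask: np.ndarray
    y: np.ndarray
    sample_index: list[tuple[str, int]]  # (user_id, prefix_week)
    var_names: tuple[str, ...] = TIME_VARIANT_NAMES
    fixed_names: tuple[str, ...] = FIXED_FEATURE_NAMES
    scaler: "Scaler | None" = None

    def __post_init__(self) -> None:
        s = self.X.shape[0]
        if not (self.F.shape[0] == self.mask.shape[0] == self.y.shape[0]
                == len(self.sample_index) == s):
            raise ValueError("inconsistent sample counts across tensor fields")
        if self.X.shape[1] != N_WEEKS or self.mask.shape[1] != N_WEEKS:
            raise ValueError(f"time axis must have {N_WEEKS} weeks")
        if self.X.shape[2] != len(self.var_names):
            raise ValueError("X width does not match var_names")
        if self.F.shape[1] != len(self.fixed_names):
            raise ValueError("F width does not match fixed_names")
        # prefix masks only: mask must be non-increasing along the week axis
        if np.any(np.diff(self.mask.astype(int), axis=1) > 0):
            raise ValueError("masks must be prefix masks (no interior gaps)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def users(self) -> list[str]:
        seen: dict[str, None] = {}
        for uid, _ in self.sample_index:
            seen.setdefault(uid)
        return list(seen)

    def subset(self, idx: np.ndarray) -> "FeatureTensor":
        idx = np.asarray(idx)
        return dc_replace(
            self,
            X=self.X[idx],
            F=self.F[idx],
            mask=self.mask[idx],
            y=self.y[idx],
            sample_index=[self.sample_index[i] for i in np.atleast_1d(idx)],
        )

    def for_users(self, user_ids) -> "FeatureTensor":
        wanted = set(user_ids)
        idx = np.array(
            [i for i, (u, _) in enumerate(self.sample_index) if u in wanted], dtype=int
        )
        return self.subset(idx)

    def full_length_only(self) -> "FeatureTensor":
        idx = np.array(
            [i for i, (_, t) in enumerate(self.sample_index) if t == N_WEEKS], dtype=int
        )
        return self.subset(idx)


@dataclass
class Scaler:
    """Per-column standardization parameters (identity for indicators).

    ``var_scaled``/``fixed_scaled`` record which columns were standardized;
    their SDs convert standardized coefficients back to raw units.
    """

    var_mean: np.ndarray
    var_sd: np.ndarray
    fixed_mean: np.ndarray
    fixed_sd: np.ndarray

    @classmethod
    def fit(cls, tensor: FeatureTensor) -> "Scaler":
        n_var = len(tensor.var_names)
        var_mean = np.zeros(n_var)
        var_sd = np.ones(n_var)
        m = tensor.mask.astype(bool)
        for j, name in enumerate(tensor.var_names):
            if name.startswith("trajectory:"):
                continue
            vals = tensor.X[:, :, j][m]
            var_mean[j] = vals.mean()
            var_sd[j] = vals.std() or 1.0
        fixed_mean = np.zeros(len(tensor.fixed_names))
        fixed_sd = np.ones(len(tensor.fixed_names))
        for j in _CONTINUOUS_FIXED:
            vals = tensor.F[:, j]
            fixed_mean[j] = vals.mean()
            fixed_sd[j] = vals.std() or 1.0
        return cls(var_mean, var_sd, fixed_mean, fixed_sd)

    def transform(self, tensor: FeatureTensor) -> "FeatureTensor":
        X = (tensor.X - self.var_mean) / self.var_sd
        X *= tensor.mask[:, :, None]  # masked weeks carry no values
        F = (tensor.F - self.fixed_mean) / self.fixed_sd
        return dc_replace(tensor, X=X, F=F, scaler=self)


def build_tensor(
    logs_by_user: dict[str, list[WeeklyLog]],
    profiles: list[UserProfile],
    trajectory_labels: dict[str, list[str]],
    include_trajectories: bool = True,
) -> FeatureTensor:
    """Assemble the (sample, week, variable) tensor of prefix samples.

    ``trajectory_labels`` maps each user to their 16 per-week real-time
    labels. Every user yields 16 samples sharing the week-16 target. The
    returned tensor is unscaled; fit a :class:`Scaler` on the training
    split afterwards.
    """
    var_names = TIME_VARIANT_NAMES if include_trajectories else BEHAVIOR_VARIABLES
    n_var = len(var_names)
    X_rows, F_rows, mask_rows, y_rows, index = [], [], [], [], []
    for profile in profiles:
        uid = profile.user_id
        logs = sorted(logs_by_user[uid], key=lambda l: l.week)
        if [l.week for l in logs] != list(range(1, N_WEEKS + 1)):
            raise ValueError(f"user {uid} lacks a complete 16-week log")
        if uid not in trajectory_labels:
            raise KeyError(f"no trajectory labels for user {uid}")
        labels = trajectory_labels[uid]
        if len(labels) != N_WEEKS:
            raise ValueError(f"user {uid} needs {N_WEEKS} per-week labels")

        x_user = np.zeros((N_WEEKS, n_var))
        for w, log in enumerate(logs):
            x_user[w, : len(BEHAVIOR_VARIABLES)] = log.behavior_vector()
            if include_trajectories and labels[w] in ARCHETYPES:
                x_user[w, len(BEHAVIOR_VARIABLES) + ARCHETYPES.index(labels[w])] = 1.0
        f_user = encode_fixed(profile)
        y_user = logs[-1].weight

        for t in range(1, N_WEEKS + 1):
            mask = np.zeros(N_WEEKS)
            mask[:t] = 1.0
            X_rows.append(x_user)
            F_rows.append(f_user)
            mask_rows.append(mask)
            y_rows.append(y_user)
            index.append((uid, t))

    return FeatureTensor(
        X=np.array(X_rows),
        F=np.array(F_rows),
        mask=np.array(mask_rows),
        y=np.array(y_rows),
        sample_index=index,
        var_names=var_names,
    )


def split_dataset(
    tensor: FeatureTensor, train_fraction: float, seed: int
) -> tuple[FeatureTensor, FeatureTensor]:
    """Split *by user* so all 16 prefix samples of a user land on one side."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    users = tensor.users
    if len(users) < 2:
        raise ValueError("need at least 2 users to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(users))
    n_train = int(round(train_fraction * len(users)))
    n_train = min(max(n_train, 1), len(users) - 1)
    train_users = [users[i] for i in order[:n_train]]
    test_users = [users[i] for i in order[n_train:]]
    return tensor.for_users(train_users), tensor.for_users(test_users)


def drop_trajectory_columns(tensor: FeatureTensor) -> FeatureTensor:
    """Ablated view with the 5 cluster-indicator columns removed (N = 7)."""
    n_b = len(BEHAVIOR_VARIABLES)
    return dc_replace(
        tensor, X=tensor.X[:, :, :n_b].copy(), var_names=BEHAVIOR_VARIABLES
    )
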