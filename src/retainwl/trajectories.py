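"""Shape-based clustering of weekly weight series.

Weight series are z-normalized (mean 0, population variance 1) so that only
the *shape* of the trajectory — not the absolute weight — enters the
distance. Dynamic time warping (classic symmetric step pattern, absolute
difference local cost, no window constraint) measures shape distance, and
k-means with DTW barycenter averaging (DBA) finds k reference shapes.
Clusters are mapped to the field's five semantic archetype labels (sharp
decrease, moderate decrease, yo-yo, increase, other) by matching
barycenters to canonical shape templates with an optimal one-to-one
assignment.

"Real-time" assignment labels a user's trajectory at every week t ≥ 2 from
the z-normalized prefix of weeks 1..t, compared against barycenters
truncated (and re-normalized) to the same length; week 1 carries a reserved
"unassigned" label because a single point cannot be z-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .records import ARCHETYPES, N_WEEKS, UNASSIGNED

__all__ = [
    "DegenerateSeriesError",
    "TrajectoryModel",
    "znormalize",
    "dtw_distance",
    "dtw_path",
    "fit_clusters",
    "assign_prefix",
    "per_week_labels",
]


class DegenerateSeriesError(ValueError):
    """Raised when a constant series cannot be z-normalized."""


def znormalize(values: np.ndarray) -> np.ndarray:
    """Z-score a series to mean 0 and population variance 1.

    Raises :class:`DegenerateSeriesError` for constant series (zero
    variance); callers route those to the degenerate-label path.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    sd = values.std()  # population SD
    if sd < 1e-12:
        raise DegenerateSeriesError("constant series cannot be z-normalized")
    return (values - values.mean()) / sd


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic DTW distance with |·| local cost and symmetric steps."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be non-empty")
    n, m = a.size, b.size
    prev = np.empty(m)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    cur = np.empty(m)
    for i in range(1, n):
        cur[0] = prev[0] + abs(a[i] - b[0])
        ai = a[i]
        for j in range(1, m):
            cur[j] = abs(ai - b[j]) + min(prev[j], prev[j - 1], cur[j - 1])
        prev, cur = cur, prev
    return float(prev[m - 1])


def dtw_path(a: np.ndarray, b: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """DTW distance plus one optimal alignment path (ties prefer the
    diagonal step, then the step in ``a``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    D = np.full((n, m), np.inf)
    D[0, 0] = abs(a[0] - b[0])
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + abs(a[i] - b[0])
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        for j in range(1, m):
            D[i, j] = abs(a[i] - b[j]) + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            steps = ((D[i - 1, j - 1], i - 1, j - 1), (D[i - 1, j], i - 1, j),
                     (D[i, j - 1], i, j - 1))
            _, i, j = min(steps, key=lambda s: s[0])
        path.append((i, j))
    path.reverse()
    return float(D[n - 1, m - 1]), path


def _dtw_cost_batch(series: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Full DTW cost tensors (S, n, m) for many series against one center,
    vectorized over the series axis. Identical recurrence to
    :func:`dtw_distance`."""
    S, n = series.shape
    m = center.size
    D = np.empty((S, n, m))
    cost = np.abs(series[:, :, None] - center[None, None, :])
    D[:, 0, 0] = cost[:, 0, 0]
    for j in range(1, m):
        D[:, 0, j] = D[:, 0, j - 1] + cost[:, 0, j]
    for i in range(1, n):
        D[:, i, 0] = D[:, i - 1, 0] + cost[:, i, 0]
        for j in range(1, m):
            D[:, i, j] = cost[:, i, j] + np.minimum(
                np.minimum(D[:, i - 1, j - 1], D[:, i - 1, j]), D[:, i, j - 1]
            )
    return D


def _dtw_dist_batch(series: np.ndarray, center: np.ndarray) -> np.ndarray:
    """DTW distance of every row of ``series`` to ``center``."""
    return _dtw_cost_batch(series, center)[:, -1, -1]


def _backtrack(D: np.ndarray) -> list[tuple[int, int]]:
    n, m = D.shape
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            steps = ((D[i - 1, j - 1], i - 1, j - 1), (D[i - 1, j], i - 1, j),
                     (D[i, j - 1], i, j - 1))
            _, i, j = min(steps, key=lambda s: s[0])
        path.append((i, j))
    path.reverse()
    return path


def _dba(series: np.ndarray, init: np.ndarray, n_iter: int = 5) -> np.ndarray:
    """DTW barycenter averaging: iteratively align members to the current
    barycenter and average the values mapped to each barycenter index."""
    center = init.copy()
    for _ in range(n_iter):
        sums = np.zeros_like(center)
        counts = np.zeros_like(center)
        D = _dtw_cost_batch(series, center)
        for s_idx in range(series.shape[0]):
            for si, ci in _backtrack(D[s_idx]):
                sums[ci] += series[s_idx, si]
                counts[ci] += 1
        updated = np.where(counts > 0, sums / np.maximum(counts, 1), center)
        if np.allclose(updated, center):
            break
        center = updated
    return center


def _semantic_templates() -> dict[str, np.ndarray]:
    """Canonical z-space shape templates for the five archetypes."""
    t = np.arange(1, N_WEEKS + 1, dtype=float)
    sharp = -(1.0 - np.exp(-0.3 * (t - 1)))
    moderate = -(t - 1)
    yoyo = np.where(t <= 8, -(t - 1) / 7.0, -1.0 + 0.62 * (t - 8) / 8.0)
    increase = t - 1
    return {
        "sharp decrease": znormalize(sharp),
        "moderate decrease": znormalize(moderate),
        "yo-yo": znormalize(yoyo),
        "increase": znormalize(increase),
        "other": np.zeros(N_WEEKS),  # flat/incoherent shapes average toward 0
    }


@dataclass
class TrajectoryModel:
    """Fitted cluster barycenters with semantic labels and training state."""

    k: int
    barycenters: np.ndarray  # (k, 16) in z-space
    labels: list[str]  # semantic label per cluster index (bijection)
    fit_seed: int
    inertia_history: list[float] = field(default_factory=list)
    assignments: dict[str, str] = field(default_factory=dict)  # training labels
    degenerate_label: str = "other"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.labels) != self.k or len(set(self.labels)) != self.k:
            raise ValueError("labels must be a bijection onto cluster indices")
        if not np.all(np.isfinite(self.barycenters)):
            raise ValueError("barycenters must be finite")


def _kmeanspp_init(z: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding under DTW distance."""
    n = z.shape[0]
    centers = [z[rng.integers(n)]]
    d2 = _dtw_dist_batch(z, centers[0]) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(np.argmin(d2))  # duplicates everywhere; deterministic pick
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers.append(z[idx])
        d2 = np.minimum(d2, _dtw_dist_batch(z, centers[-1]) ** 2)
    return np.array(centers)


def _map_semantic_labels(barycenters: np.ndarray) -> list[str]:
    """Assign each of 5 barycenters a distinct archetype label by minimising
    total DTW distance to the canonical templates (optimal assignment)."""
    templates = _semantic_templates()
    names = list(ARCHETYPES)
    cost = np.array(
        [[dtw_distance(b, templates[name]) for name in names] for b in barycenters]
    )
    rows, cols = linear_sum_assignment(cost)
    labels = [""] * len(barycenters)
    for r, c in zip(rows, cols):
        labels[r] = names[c]
    return labels


def _lloyd(z: np.ndarray, centers: np.ndarray, k: int, max_iter: int, dba_iter: int):
    n = z.shape[0]
    assign = np.full(n, -1)
    inertia_history: list[float] = []
    for _ in range(max_iter):
        dists = np.column_stack([_dtw_dist_batch(z, c) for c in centers])
        # snap float-noise near-ties so duplicate centers (possible when there
        # are fewer distinct shapes than k) break to the lowest index
        new_assign = np.round(dists, 8).argmin(axis=1)
        inertia_history.append(float((dists[np.arange(n), new_assign] ** 2).sum()))
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for ci in range(k):
            members = z[assign == ci]
            if members.shape[0]:
                centers[ci] = _dba(members, centers[ci], n_iter=dba_iter)
    return centers, assign, inertia_history


def fit_clusters(
    series: dict[str, np.ndarray],
    k: int = 5,
    seed: int = 0,
    max_iter: int = 30,
    dba_iter: int = 5,
    n_init: int = 10,
) -> TrajectoryModel:
    """DTW k-means over z-normalized weight series.

    Constant series are excluded from fitting and assigned the degenerate
    label directly. ``n_init`` k-means++ restarts are run and the solution
    with the lowest within-cluster squared-DTW inertia kept; the recorded
    inertia history is non-increasing within a run. Deterministic given
    seed; assignment ties break to the lowest cluster index.
    """
    ids: list[str] = []
    zs: list[np.ndarray] = []
    degenerate: list[str] = []
    for uid, values in series.items():
        try:
            zs.append(znormalize(np.asarray(values, dtype=float)))
            ids.append(uid)
        except DegenerateSeriesError:
            degenerate.append(uid)
    if len(zs) < k:
        raise ValueError(f"need at least k={k} non-degenerate series, got {len(zs)}")
    z = np.array(zs)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_init, 1)):
        init_centers = _kmeanspp_init(z, k, rng)
        centers_r, assign_r, hist_r = _lloyd(z, init_centers, k, max_iter, dba_iter)
        if best is None or hist_r[-1] < best[2][-1]:
            best = (centers_r, assign_r, hist_r)
    centers, assign, inertia_history = best

    labels = _map_semantic_labels(centers) if k == len(ARCHETYPES) else [
        f"cluster_{i}" for i in range(k)
    ]
    degenerate_label = "other" if k == len(ARCHETYPES) else UNASSIGNED
    assignments = {uid: labels[assign[i]] for i, uid in enumerate(ids)}
    assignments.update({uid: degenerate_label for uid in degenerate})
    return TrajectoryModel(
        k=k,
        barycenters=centers,
        labels=labels,
        fit_seed=seed,
        inertia_history=inertia_history,
        assignments=assignments,
        degenerate_label=degenerate_label,
    )


def assign_prefix(prefix: np.ndarray, model: TrajectoryModel) -> str:
    """Cluster label for a weight series prefix (weeks 1..t), t ≥ 2.

    The prefix and each barycenter truncated to the same length are both
    z-normalized before the DTW comparison. A single-week prefix returns
    the reserved unassigned label; a constant prefix gets the degenerate
    label.
    """
    prefix = np.asarray(prefix, dtype=float)
    t = prefix.size
    if t < 2:
        return UNASSIGNED
    try:
        zp = znormalize(prefix)
    except DegenerateSeriesError:
        return model.degenerate_label
    dists = []
    for b in model.barycenters:
        trunc = b[:t]
        if trunc.std() < 1e-12:
            zb = np.zeros(t)
        else:
            zb = znormalize(trunc)
        dists.append(dtw_distance(zp, zb))
    return model.labels[int(np.argmin(dists))]


def per_week_labels(series: np.ndarray, model: TrajectoryModel) -> list[str]:
    """Real-time labels for weeks 1..16: week t uses only weeks 1..t."""
    series = np.asarray(series, dtype=float)
    if series.size != N_WEEKS:
        raise ValueError(f"expected a {N_WEEKS}-week series, got length {series.size}")
    return [assign_prefix(series[:t], model) for t in range(1, N_WEEKS + 1)]
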