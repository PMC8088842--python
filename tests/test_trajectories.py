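"""Z-normalization, DTW (with an independent oracle), DTW k-means, and
real-time prefix assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from retainwl.records import ARCHETYPES, N_WEEKS, UNASSIGNED
from retainwl.synthetic import GeneratorConfig, archetype_profile
from retainwl.trajectories import (
    DegenerateSeriesError,
    _dtw_dist_batch,
    assign_prefix,
    dtw_distance,
    dtw_path,
    fit_clusters,
    per_week_labels,
    znormalize,
)


# ---------------------------------------------------------------- znormalize

def test_znormalize_hand_example():
    z = znormalize(np.array([1.0, 2.0, 3.0]))
    assert z == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)


@given(
    values=st.lists(st.floats(-50, 50), min_size=2, max_size=16),
    a=st.floats(0.1, 10),
    b=st.floats(-20, 20),
)
@settings(derandomize=True, max_examples=100)
def test_znormalize_moments_and_affine_invariance(values, a, b):
    x = np.asarray(values)
    if x.std() < 1e-6:
        with pytest.raises(DegenerateSeriesError):
            znormalize(x)
        return
    z = znormalize(x)
    assert abs(z.mean()) < 1e-9
    assert z.std() == pytest.approx(1.0, abs=1e-9)
    assert znormalize(a * x + b) == pytest.approx(z, abs=1e-6)


def test_znormalize_rejects_constant_and_short_series():
    with pytest.raises(DegenerateSeriesError):
        znormalize(np.full(10, 81.5))
    with pytest.raises(ValueError):
        znormalize(np.array([1.0]))


# ----------------------------------------------------------------------- DTW

def brute_force_dtw(a, b):
    """Independent oracle: recursive enumeration of monotone alignments."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        best = np.inf
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        return cost + best

    return rec(len(a) - 1, len(b) - 1)


def test_dtw_hand_example():
    assert dtw_distance([0.0, 1.0, 2.0], [0.0, 2.0]) == pytest.approx(1.0)


def test_dtw_identity_symmetry_and_l1_bound():
    rng = np.random.default_rng(3)
    for _ in range(30):
        a = rng.normal(size=rng.integers(2, 12))
        b = rng.normal(size=rng.integers(2, 12))
        assert dtw_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))
    for _ in range(30):
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        assert dtw_distance(a, b) <= np.abs(a - b).sum() + 1e-12


def test_dtw_matches_brute_force_oracle_exhaustive_short():
    alphabet = (0.0, 1.0, 2.0)
    pool = [
        s
        for ln in (1, 2, 3)
        for s in itertools.product(alphabet, repeat=ln)
    ]
    for a in pool:
        for b in pool:
            assert dtw_distance(np.array(a), np.array(b)) == pytest.approx(
                brute_force_dtw(a, b)
            ), (a, b)


def test_dtw_matches_brute_force_oracle_sampled_length6():
    rng = np.random.default_rng(17)
    alphabet = (0.0, 1.0, 2.0)
    pool = [
        tuple(rng.choice(alphabet, size=rng.integers(1, 7))) for _ in range(60)
    ]
    for a, b in itertools.combinations(pool, 2):
        assert dtw_distance(np.array(a), np.array(b)) == pytest.approx(
            brute_force_dtw(a, b)
        ), (a, b)


def test_dtw_batch_path_and_scalar_agree():
    rng = np.random.default_rng(5)
    A = rng.normal(size=(25, 10))
    b = rng.normal(size=16)
    batch = _dtw_dist_batch(A, b)
    for i, a in enumerate(A):
        assert batch[i] == pytest.approx(dtw_distance(a, b))
        d, path = dtw_path(a, b)
        assert d == pytest.approx(batch[i])
        assert path[0] == (0, 0) and path[-1] == (len(a) - 1, len(b) - 1)


def test_dtw_rejects_empty_series():
    with pytest.raises(ValueError):
        dtw_distance(np.array([]), np.array([1.0]))


# ------------------------------------------------------------------- k-means

def archetype_family_series(copies=20, base=90.0):
    """Noise-free families: exact archetype curves, identical within family."""
    effects = {"sharp decrease": -11.2, "moderate decrease": -4.7,
               "yo-yo": -1.9, "increase": 2.8, "other": 0.0}
    series, labels = {}, {}
    i = 0
    for name in ARCHETYPES:
        curve = base + archetype_profile(name) * effects[name]
        for _ in range(copies):
            series[f"s{i}"] = curve.copy()
            labels[f"s{i}"] = name
            i += 1
    return series, labels


def test_noise_free_families_recovered_exactly():
    series, labels = archetype_family_series()
    model = fit_clusters(series, k=5, seed=0)
    pred = [model.assignments[u] for u in series]
    true = [labels[u] for u in series]
    assert adjusted_rand_score(true, pred) == pytest.approx(1.0)
    # semantic mapping also lands on the right names for the shaped families
    for u in series:
        if labels[u] != "other":
            assert model.assignments[u] == labels[u]


def test_inertia_history_is_non_increasing(small_cohort):
    series = {u: small_cohort.weight_series(u) for u in small_cohort.user_ids}
    model = fit_clusters(series, k=4, seed=2, n_init=1)
    hist = model.inertia_history
    assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))


def test_k1_degenerate_clustering(small_cohort):
    series = {u: small_cohort.weight_series(u) for u in small_cohort.user_ids}
    model = fit_clusters(series, k=1, seed=0, n_init=1)
    assert len(set(model.assignments.values())) == 1


def test_every_series_gets_exactly_one_label(small_cohort):
    series = {u: small_cohort.weight_series(u) for u in small_cohort.user_ids}
    model = fit_clusters(series, k=5, seed=0, n_init=2)
    assert set(model.assignments) == set(series)
    assert sorted(model.labels) == sorted(ARCHETYPES)


def test_fewer_series_than_k_rejected():
    series = {"a": np.arange(16.0), "b": np.arange(16.0) * 2}
    with pytest.raises(ValueError, match="at least k"):
        fit_clusters(series, k=5)


# ---------------------------------------------------------- prefix assignment

def test_prefix_consistency_and_early_recognition():
    series, labels = archetype_family_series()
    model = fit_clusters(series, k=5, seed=0)
    sharp = next(u for u in series if labels[u] == "sharp decrease")
    # full series reproduces the training assignment
    assert assign_prefix(series[sharp], model) == model.assignments[sharp]
    # a noise-free sharp-decrease prefix is recognised by week 8
    assert assign_prefix(series[sharp][:8], model) == "sharp decrease"


def test_prefix_edge_cases(small_cohort):
    series = {u: small_cohort.weight_series(u) for u in small_cohort.user_ids}
    model = fit_clusters(series, k=5, seed=0, n_init=2)
    assert assign_prefix(np.array([90.0]), model) == UNASSIGNED
    assert assign_prefix(np.full(6, 90.0), model) == model.degenerate_label
    labels = per_week_labels(series[small_cohort.user_ids[0]], model)
    assert len(labels) == N_WEEKS
    assert labels[0] == UNASSIGNED
    assert all(l in (*ARCHETYPES, UNASSIGNED) for l in labels)
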