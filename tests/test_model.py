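"""The conditional attention regressor: forward contracts, gradients,
masking, and training behavior."""

import numpy as np
import pytest

from retainwl.features import FeatureTensor
from retainwl.model import (
    ModelConfig,
    forward,
    forward_batch,
    init_parameters,
    loss_and_grads,
    predict,
    train,
)
from retainwl.records import N_WEEKS


def tiny_params(n_var=3, n_fixed=2, hidden=5, seed=1):
    return init_parameters(n_var, n_fixed, ModelConfig(hidden_size=hidden, seed=seed))


def random_sample(rng, n_var=3, n_fixed=2, t_obs=N_WEEKS):
    X = rng.normal(size=(N_WEEKS, n_var))
    F = rng.normal(size=n_fixed)
    mask = np.zeros(N_WEEKS)
    mask[:t_obs] = 1.0
    return X, F, mask


def test_equal_logits_give_uniform_attention():
    """With identical attention logits over 16 unmasked weeks each weekly
    attention weight is exactly 1/16 = 0.0625."""
    params = tiny_params()
    params.arrays["w_alpha"][:] = 0.0  # every week gets the same logit
    X, F, mask = random_sample(np.random.default_rng(0))
    res = forward(X, F, mask, params)
    assert res.alpha == pytest.approx(np.full(N_WEEKS, 0.0625), abs=1e-12)


def test_zero_beta_reduces_to_fixed_feature_regression():
    params = tiny_params()
    params.arrays["W_beta"][:] = 0.0
    params.arrays["b_beta"][:] = 0.0
    X, F, mask = random_sample(np.random.default_rng(1))
    res = forward(X, F, mask, params)
    assert res.context == pytest.approx(np.zeros(3), abs=1e-12)
    expected = F @ params.arrays["w"][3:] + params.arrays["b"]
    assert res.y_hat == pytest.approx(float(expected), abs=1e-10)


def test_attention_bounds_and_context_identity():
    params = tiny_params(seed=7)
    rng = np.random.default_rng(2)
    for t_obs in (1, 5, 16):
        X, F, mask = random_sample(rng, t_obs=t_obs)
        res = forward(X, F, mask, params)
        assert res.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.alpha >= 0) and np.all(res.alpha <= 1)
        assert np.all(res.alpha[t_obs:] == 0)
        assert np.all(np.abs(res.beta) <= 1)
        ctx = (res.alpha[:, None] * res.beta * X).sum(axis=0)
        assert res.context == pytest.approx(ctx, abs=1e-9)


def test_masked_weeks_never_change_prediction():
    params = tiny_params(seed=3)
    rng = np.random.default_rng(4)
    X, F, mask = random_sample(rng, t_obs=5)
    base = forward(X, F, mask, params).y_hat
    X2 = X.copy()
    X2[5:] = rng.normal(size=(11, 3)) * 100  # garbage in masked weeks
    assert forward(X2, F, mask, params).y_hat == pytest.approx(base, abs=1e-10)


def test_analytic_gradients_match_finite_differences():
    params = tiny_params(seed=5)
    rng = np.random.default_rng(6)
    params.arrays["w"] = rng.normal(0, 0.5, size=5)
    B = 2
    X = rng.normal(size=(B, 4, 3))
    F = rng.normal(size=(B, 2))
    mask = np.array([[1, 1, 1, 0], [1, 1, 1, 1]], dtype=float)
    # pad to 4-week toy sequences (the model is length-agnostic)
    y = rng.normal(size=B)
    _, grads = loss_and_grads(params, X, F, mask, y)
    eps = 1e-6
    for key, arr in params.arrays.items():
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            old = arr[idx]
            arr[idx] = old + eps
            lp, _ = loss_and_grads(params, X, F, mask, y)
            arr[idx] = old - eps
            lm, _ = loss_and_grads(params, X, F, mask, y)
            arr[idx] = old
            num[idx] = (lp - lm) / (2 * eps)
        if np.linalg.norm(num) < 1e-7:
            # structurally zero gradient (e.g. the shared attention-logit
            # bias cancels in the softmax); the analytic one must agree
            assert np.linalg.norm(grads[key]) < 1e-7
            continue
        rel = np.linalg.norm(grads[key] - num) / np.linalg.norm(num)
        assert rel < 1e-4, f"gradient mismatch for {key}: {rel}"


def test_forward_rejects_degenerate_inputs():
    params = tiny_params()
    X, F, mask = random_sample(np.random.default_rng(0))
    with pytest.raises(ValueError, match="unmasked"):
        forward(X, F, np.zeros(N_WEEKS), params)
    X_bad = X.copy()
    X_bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        forward(X_bad, F, mask, params)


def _toy_tensor(n_users=12, n_var=3, seed=0):
    """Small synthetic tensor with a linear target for training tests."""
    rng = np.random.default_rng(seed)
    rows = n_users * N_WEEKS
    X = np.zeros((rows, N_WEEKS, n_var))
    F = np.zeros((rows, 2))
    mask = np.zeros((rows, N_WEEKS))
    y = np.zeros(rows)
    index = []
    r = 0
    for u in range(n_users):
        xu = rng.normal(size=(N_WEEKS, n_var))
        fu = rng.normal(size=2)
        target = 90 + 2 * fu[0] + xu[:, 0].mean() - 0.5 * xu[:, 1].mean()
        for t in range(1, N_WEEKS + 1):
            X[r] = xu
            F[r] = fu
            mask[r, :t] = 1
            y[r] = target
            index.append((f"u{u}", t))
            r += 1
    return FeatureTensor(X=X, F=F, mask=mask, y=y, sample_index=index,
                         var_names=("a", "b", "c"), fixed_names=("f1", "f2"))


def test_training_is_deterministic_and_decreases_loss():
    tensor = _toy_tensor()
    cfg = ModelConfig(hidden_size=8, epochs=12, seed=9, batch_size=64)
    p1 = train(tensor, cfg)
    p2 = train(tensor, cfg)
    assert [h["train_mse"] for h in p1.history] == [h["train_mse"] for h in p2.history]
    for k in p1.arrays:
        np.testing.assert_array_equal(p1.arrays[k], p2.arrays[k])
    assert p1.history[-1]["train_mse"] < p1.history[0]["train_mse"]


def test_batched_and_single_sample_predictions_agree():
    tensor = _toy_tensor(n_users=7, seed=4)
    cfg = ModelConfig(hidden_size=8, epochs=3, seed=2, batch_size=32)
    params = train(tensor, cfg)
    batch = predict(tensor, params)
    for i in range(0, tensor.n_samples, 17):
        single = forward(tensor.X[i], tensor.F[i], tensor.mask[i], params).y_hat
        assert batch[i] == pytest.approx(single, abs=1e-9)
    assert np.all(np.isfinite(batch))


def test_predict_rejects_variable_count_mismatch():
    tensor = _toy_tensor(n_users=4)
    params = train(tensor, ModelConfig(hidden_size=8, epochs=2, seed=0))
    from retainwl.features import FeatureTensor as FT
    from dataclasses import replace
    bad = replace(tensor, X=tensor.X[:, :, :2], var_names=("a", "b"))
    with pytest.raises(ValueError, match="time-variant"):
        predict(bad, params)
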