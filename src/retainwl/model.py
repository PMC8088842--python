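"""Conditional RETAIN regression core.

An interpretable recurrent regressor in the RETAIN family, adapted for
continuous lifelog inputs and a per-user time-fixed profile:

* two GRUs consume the time-variant inputs directly (no embedding layer),
  by default in reverse time;
* one GRU drives a scalar *time-level* attention logit per week, softmax-
  normalized over unmasked weeks (α, positive, summing to 1);
* the other drives a *variable-level* attention vector per week through a
  tanh (β, entries in [−1, 1]);
* the context vector c = Σ_j α_j (β_j ⊙ x_j) is concatenated with the
  time-fixed features and mapped to the predicted week-16 weight by a
  plain linear head (no output nonlinearity), keeping the prediction an
  exact sum of per-variable, per-week contributions.

Everything here is NumPy: the forward pass, backpropagation through time,
and Adam. Training minimizes mean squared error on an internally
standardized target; the output layer is rescaled to kilograms afterwards,
which preserves the additive decomposition exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTensor
from .records import N_WEEKS

__all__ = [
    "ModelConfig",
    "ModelParameters",
    "ForwardResult",
    "TrainingDivergedError",
    "init_parameters",
    "forward",
    "forward_batch",
    "loss_and_grads",
    "train",
    "predict",
]

_NEG_INF = -1e30


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Training hyperparameters (none are dictated by the method itself)."""

    hidden_size: int = 24
    seed: int = 0
    learning_rate: float = 1e-2
    epochs: int = 100
    batch_size: int = 256
    val_fraction: float = 0.15
    reverse_time: bool = True


@dataclass
class ModelParameters:
    """All trainable arrays plus the metadata needed to reuse them.

    Keys in ``arrays``: per attention GRU g ∈ {a, b}: ``W_g`` (N, 3H),
    ``U_g`` (H, 3H), ``bi_g``/``bh_g`` (3H) with gate order (reset, update,
    candidate); ``w_alpha`` (H,), ``b_alpha`` (); ``W_beta`` (H, N),
    ``b_beta`` (N,); output ``w`` (N+K,) and ``b`` ().
    """

    arrays: dict[str, np.ndarray]
    n_var: int
    n_fixed: int
    hidden_size: int
    reverse_time: bool = True
    seed: int = 0
    history: list[dict] = field(default_factory=list)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            arrays={k: v.copy() for k, v in self.arrays.items()},
            n_var=self.n_var,
            n_fixed=self.n_fixed,
            hidden_size=self.hidden_size,
            reverse_time=self.reverse_time,
            seed=self.seed,
            history=copy.deepcopy(self.history),
        )


@dataclass
class ForwardResult:
    """Per-sample forward pass with everything interpretation needs."""

    y_hat: float
    alpha: np.ndarray  # (16,)
    beta: np.ndarray  # (16, N)
    context: np.ndarray  # (N,)
    hidden_g: np.ndarray  # (16, H) time-level attention RNN states
    hidden_h: np.ndarray  # (16, H) variable-level attention RNN states


def init_parameters(
    n_var: int, n_fixed: int, config: ModelConfig
) -> ModelParameters:
    """Uniform(-1/√H, 1/√H) recurrent weights, small output head."""
    rng = np.random.default_rng(config.seed)
    h = config.hidden_size
    lim = 1.0 / np.sqrt(h)
    arrays: dict[str, np.ndarray] = {}
    for g in ("a", "b"):
        arrays[f"W_{g}"] = rng.uniform(-lim, lim, size=(n_var, 3 * h))
        arrays[f"U_{g}"] = rng.uniform(-lim, lim, size=(h, 3 * h))
        arrays[f"bi_{g}"] = np.zeros(3 * h)
        arrays[f"bh_{g}"] = np.zeros(3 * h)
    arrays["w_alpha"] = rng.uniform(-lim, lim, size=h)
    arrays["b_alpha"] = np.zeros(())
    arrays["W_beta"] = rng.uniform(-lim, lim, size=(h, n_var))
    arrays["b_beta"] = np.zeros(n_var)
    arrays["w"] = rng.normal(0.0, 0.01, size=n_var + n_fixed)
    arrays["b"] = np.zeros(())
    return ModelParameters(
        arrays=arrays,
        n_var=n_var,
        n_fixed=n_fixed,
        hidden_size=h,
        reverse_time=config.reverse_time,
        seed=config.seed,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gru_step(p, g: str, x, h_prev):
    """One GRU step; returns new hidden state and the cache for backprop."""
    H = h_prev.shape[1]
    gx = x @ p[f"W_{g}"] + p[f"bi_{g}"]
    gh = h_prev @ p[f"U_{g}"] + p[f"bh_{g}"]
    r = _sigmoid(gx[:, :H] + gh[:, :H])
    z = _sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
    ghn = gh[:, 2 * H:]
    n = np.tanh(gx[:, 2 * H:] + r * ghn)
    h_new = (1.0 - z) * n + z * h_prev
    return h_new, (x, h_prev, r, z, n, ghn)


def forward_batch(
    params: ModelParameters,
    X: np.ndarray,
    F: np.ndarray,
    mask: np.ndarray,
    want_cache: bool = False,
):
    """Vectorized forward pass over a batch of samples.

    Returns a dict with ``y_hat`` (B,), ``alpha`` (B, T), ``beta``
    (B, T, N), ``context`` (B, N), hidden state stacks, and (optionally)
    the caches backpropagation needs. Masked weeks receive exactly zero
    attention and never alter the recurrent states.
    """
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be (batch, weeks, variables)")
    if not (np.isfinite(X).all() and np.isfinite(F).all()):
        raise ValueError("inputs contain non-finite values")
    if np.any(mask.sum(axis=1) == 0):
        raise ValueError("every sample must have at least one unmasked week")
    B, T, N = X.shape
    H = params.hidden_size
    p = params.arrays

    order = range(T - 1, -1, -1) if params.reverse_time else range(T)
    h_a = np.zeros((B, H))
    h_b = np.zeros((B, H))
    g_states = np.zeros((B, T, H))
    h_states = np.zeros((B, T, H))
    caches = []
    for t in order:
        active = mask[:, t][:, None]
        ha_new, cache_a = _gru_step(p, "a", X[:, t, :], h_a)
        hb_new, cache_b = _gru_step(p, "b", X[:, t, :], h_b)
        h_a = active * ha_new + (1 - active) * h_a
        h_b = active * hb_new + (1 - active) * h_b
        g_states[:, t, :] = h_a
        h_states[:, t, :] = h_b
        if want_cache:
            caches.append((t, cache_a, cache_b))

    logits = g_states @ p["w_alpha"] + p["b_alpha"]
    logits = np.where(mask > 0, logits, _NEG_INF)
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    alpha = expl / expl.sum(axis=1, keepdims=True)
    beta = np.tanh(h_states @ p["W_beta"] + p["b_beta"])
    context = np.einsum("bt,btn,btn->bn", alpha, beta, X)
    y_hat = context @ p["w"][:N] + F @ p["w"][N:] + p["b"]

    out = {
        "y_hat": y_hat,
        "alpha": alpha,
        "beta": beta,
        "context": context,
        "g_states": g_states,
        "h_states": h_states,
    }
    if want_cache:
        out["caches"] = caches
        out["X"], out["F"], out["mask"] = X, F, mask
    return out


def forward(
    X_sample: np.ndarray,
    F_sample: np.ndarray,
    mask: np.ndarray,
    params: ModelParameters,
) -> ForwardResult:
    """Forward pass for a single (user, prefix-week) sample."""
    out = forward_batch(params, X_sample[None], F_sample[None], mask[None])
    return ForwardResult(
        y_hat=float(out["y_hat"][0]),
        alpha=out["alpha"][0],
        beta=out["beta"][0],
        context=out["context"][0],
        hidden_g=out["g_states"][0],
        hidden_h=out["h_states"][0],
    )


def _gru_backward(p, grads, g: str, d_h_new, cache, active):
    """Backprop one GRU step. Returns gradient w.r.t. the previous hidden
    state; ``active`` zeroes gate gradients for masked samples (whose state
    passed through unchanged)."""
    x, h_prev, r, z, n, ghn = cache
    d_h_new = d_h_new * active
    dz = d_h_new * (h_prev - n)
    dn = d_h_new * (1.0 - z)
    dh_prev = d_h_new * z
    dn_pre = dn * (1.0 - n * n)
    dr = dn_pre * ghn
    dghn = dn_pre * r
    dr_pre = dr * r * (1.0 - r)
    dz_pre = dz * z * (1.0 - z)
    dgx = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
    dgh = np.concatenate([dr_pre, dz_pre, dghn], axis=1)
    grads[f"W_{g}"] += x.T @ dgx
    grads[f"bi_{g}"] += dgx.sum(axis=0)
    grads[f"U_{g}"] += h_prev.T @ dgh
    grads[f"bh_{g}"] += dgh.sum(axis=0)
    dh_prev += dgh @ p[f"U_{g}"].T
    return dh_prev


def loss_and_grads(
    params: ModelParameters,
    X: np.ndarray,
    F: np.ndarray,
    mask: np.ndarray,
    y: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean-squared-error loss and analytic gradients for a batch."""
    out = forward_batch(params, X, F, mask, want_cache=True)
    p = params.arrays
    B, T, N = out["X"].shape
    resid = out["y_hat"] - np.asarray(y, dtype=float)
    loss = float(np.mean(resid**2))
    dy = 2.0 * resid / B

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    cF = np.concatenate([out["context"], out["F"]], axis=1)
    grads["w"] += cF.T @ dy
    grads["b"] += dy.sum()
    dc = dy[:, None] * p["w"][:N]

    alpha, beta, Xd = out["alpha"], out["beta"], out["X"]
    dalpha = np.einsum("bn,btn,btn->bt", dc, beta, Xd)
    dbeta = alpha[:, :, None] * dc[:, None, :] * Xd
    dbeta_pre = dbeta * (1.0 - beta * beta)
    grads["W_beta"] += np.einsum("bth,btn->hn", out["h_states"], dbeta_pre)
    grads["b_beta"] += dbeta_pre.sum(axis=(0, 1))
    dh_states = dbeta_pre @ p["W_beta"].T

    # softmax backward; masked weeks have alpha exactly 0, so their logits
    # receive zero gradient automatically
    de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    grads["w_alpha"] += np.einsum("bth,bt->h", out["g_states"], de)
    grads["b_alpha"] += de.sum()
    dg_states = de[:, :, None] * p["w_alpha"]

    dh_a = np.zeros((B, params.hidden_size))
    dh_b = np.zeros((B, params.hidden_size))
    for t, cache_a, cache_b in reversed(out["caches"]):
        active = out["mask"][:, t][:, None]
        dh_a_total = dg_states[:, t, :] + dh_a
        dh_b_total = dh_states[:, t, :] + dh_b
        # masked samples passed their state through unchanged, so their
        # gradient flows on untouched; active samples backprop the GRU step
        dh_a = _gru_backward(p, grads, "a", dh_a_total, cache_a, active) \
            + (1 - active) * dh_a_total
        dh_b = _gru_backward(p, grads, "b", dh_b_total, cache_b, active) \
            + (1 - active) * dh_b_total
    return loss, grads


class _Adam:
    def __init__(self, arrays: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in arrays:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            arrays[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _user_val_split(tensor: FeatureTensor, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    users = tensor.users
    order = rng.permutation(len(users))
    n_val = int(round(fraction * len(users)))
    n_val = min(max(n_val, 1), len(users) - 1) if fraction > 0 else 0
    val_users = {users[i] for i in order[:n_val]}
    idx_val = np.array([i for i, (u, _) in enumerate(tensor.sample_index) if u in val_users], dtype=int)
    idx_fit = np.array([i for i, (u, _) in enumerate(tensor.sample_index) if u not in val_users], dtype=int)
    return idx_fit, idx_val


def train(train_tensor: FeatureTensor, config: ModelConfig) -> ModelParameters:
    """Fit the model by minibatch Adam on MSE; return best-on-validation
    parameters (validation is a user-level holdout from the training set).

    The target is standardized internally; the returned parameters predict
    in kilograms (the output layer is linearly rescaled, which leaves the
    additive decomposition intact). Deterministic given the config seed.
    """
    if train_tensor.n_samples == 0:
        raise ValueError("training tensor is empty")
    rng = np.random.default_rng(config.seed)
    n_var = len(train_tensor.var_names)
    n_fixed = len(train_tensor.fixed_names)
    params = init_parameters(n_var, n_fixed, config)

    mu, sigma = float(train_tensor.y.mean()), float(train_tensor.y.std() or 1.0)
    ty = (train_tensor.y - mu) / sigma

    idx_fit, idx_val = _user_val_split(train_tensor, config.val_fraction, rng)
    Xf, Ff, mf, yf = (train_tensor.X[idx_fit], train_tensor.F[idx_fit],
                      train_tensor.mask[idx_fit], ty[idx_fit])
    has_val = idx_val.size > 0
    if has_val:
        Xv, Fv, mv, yv = (train_tensor.X[idx_val], train_tensor.F[idx_val],
                          train_tensor.mask[idx_val], ty[idx_val])

    opt = _Adam(params.arrays, config.learning_rate)
    best = params.copy()
    best_val = np.inf
    n_fit = idx_fit.size
    for epoch in range(config.epochs):
        order = rng.permutation(n_fit)
        epoch_loss = 0.0
        for start in range(0, n_fit, config.batch_size):
            sel = order[start:start + config.batch_size]
            loss, grads = loss_and_grads(params, Xf[sel], Ff[sel], mf[sel], yf[sel])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}"
                )
            opt.step(params.arrays, grads)
            epoch_loss += loss * sel.size
        epoch_loss /= n_fit
        if has_val:
            vout = forward_batch(params, Xv, Fv, mv)
            val_loss = float(np.mean((vout["y_hat"] - yv) ** 2))
        else:
            val_loss = epoch_loss
        params.history.append({"epoch": epoch, "train_mse": epoch_loss, "val_mse": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best = params.copy()

    best.history = params.history
    # rescale the linear head back to kilograms
    best.arrays["w"] *= sigma
    best.arrays["b"] = best.arrays["b"] * sigma + mu
    return best


def predict(tensor: FeatureTensor, params: ModelParameters, batch_size: int = 1024) -> np.ndarray:
    """Predicted week-16 weight (kg) for every sample in the tensor."""
    if len(tensor.var_names) != params.n_var:
        raise ValueError(
            f"tensor has {len(tensor.var_names)} time-variant variables, "
            f"model expects {params.n_var}"
        )
    preds = np.empty(tensor.n_samples)
    for start in range(0, tensor.n_samples, batch_size):
        stop = min(start + batch_size, tensor.n_samples)
        out = forward_batch(params, tensor.X[start:stop], tensor.F[start:stop],
                            tensor.mask[start:stop])
        preds[start:stop] = out["y_hat"]
    return preds
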