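"""Additive decomposition of predictions into per-variable contributions.

Because the output head is linear, every prediction is an exact sum

    ŷ = Σ_j Σ_n α_j β_jn w_n x_jn  +  Σ_m w_m x_m  +  b,

so each time-variant cell (week j, variable n) owns a *contribution
coefficient* ω_jn = α_j · β_jn · w_n and a *contribution* ω_jn · x_jn; each
time-fixed variable's coefficient is simply its output weight w_m. Masked
weeks have α_j = 0 and contribute nothing. Averaging attentions and
coefficients over a test set gives the model's global usage pattern.

The model cannot attach statistical significance to these coefficients;
they are descriptive weights of a single fitted network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .features import FeatureTensor, Scaler
from .model import ModelParameters, forward, forward_batch
from .records import N_WEEKS

__all__ = [
    "ContributionTable",
    "GlobalPattern",
    "decompose",
    "global_pattern",
    "raw_unit_coefficients",
]


@dataclass
class ContributionTable:
    """Per-sample attentions, coefficients, and contributions."""

    alpha: np.ndarray  # (16,)
    beta: np.ndarray  # (16, N)
    w: np.ndarray  # (N + K,) output weights
    coefficients: np.ndarray  # (16, N)  alpha_j * beta_jn * w_n
    contributions: np.ndarray  # (16, N)  coefficient * x_jn
    fixed_coefficients: np.ndarray  # (K,)  = w_m
    fixed_contributions: np.ndarray  # (K,)  w_m * x_m
    bias: float
    y_hat: float
    var_names: tuple[str, ...]
    fixed_names: tuple[str, ...]
    units: str = "standardized"

    def total_contribution(self) -> float:
        return float(self.contributions.sum() + self.fixed_contributions.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of every time-variant cell plus fixed rows."""
        rows = []
        for j in range(N_WEEKS):
            for n, name in enumerate(self.var_names):
                rows.append(
                    ("time-variant", name, j + 1, self.alpha[j], self.beta[j, n],
                     self.w[n], self.coefficients[j, n], self.contributions[j, n])
                )
        for m, name in enumerate(self.fixed_names):
            rows.append(
                ("time-fixed", name, None, None, None,
                 self.fixed_coefficients[m], self.fixed_coefficients[m],
                 self.fixed_contributions[m])
            )
        return pd.DataFrame(
            rows,
            columns=["kind", "variable", "week", "alpha", "beta", "w",
                     "coefficient", "contribution"],
        )


@dataclass
class GlobalPattern:
    """Test-set averages of attentions and coefficients (the model's
    global explanation, mirroring per-week attention/coefficient plots)."""

    mean_alpha: np.ndarray  # (16,)
    mean_beta: np.ndarray  # (16, N)
    mean_coefficients: np.ndarray  # (16, N)
    mean_fixed_coefficients: np.ndarray  # (K,)
    n_samples: int
    var_names: tuple[str, ...]
    fixed_names: tuple[str, ...]

    def mean_variable_coefficients(self) -> dict[str, float]:
        """Coefficient of each time-variant variable averaged over weeks."""
        over_weeks = self.mean_coefficients.mean(axis=0)
        return {name: float(over_weeks[i]) for i, name in enumerate(self.var_names)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(N_WEEKS):
            for n, name in enumerate(self.var_names):
                rows.append((name, j + 1, self.mean_alpha[j], self.mean_beta[j, n],
                             self.mean_coefficients[j, n]))
        return pd.DataFrame(
            rows, columns=["variable", "week", "mean_alpha", "mean_beta",
                           "mean_coefficient"]
        )


def decompose(
    X_sample: np.ndarray,
    F_sample: np.ndarray,
    mask: np.ndarray,
    params: ModelParameters,
) -> ContributionTable:
    """Exact additive decomposition of one sample's prediction."""
    res = forward(X_sample, F_sample, mask, params)
    N = params.n_var
    w = params.arrays["w"]
    coefficients = res.alpha[:, None] * res.beta * w[:N]
    contributions = coefficients * X_sample
    fixed_coefficients = w[N:].copy()
    fixed_contributions = fixed_coefficients * F_sample
    return ContributionTable(
        alpha=res.alpha,
        beta=res.beta,
        w=w.copy(),
        coefficients=coefficients,
        contributions=contributions,
        fixed_coefficients=fixed_coefficients,
        fixed_contributions=fixed_contributions,
        bias=float(params.arrays["b"]),
        y_hat=res.y_hat,
        var_names=tuple(f"x{i}" for i in range(N)),
        fixed_names=tuple(f"f{i}" for i in range(len(fixed_contributions))),
    )


def decompose_tensor_sample(
    tensor: FeatureTensor, i: int, params: ModelParameters
) -> ContributionTable:
    """Decompose sample ``i`` of a tensor, carrying its variable names."""
    table = decompose(tensor.X[i], tensor.F[i], tensor.mask[i], params)
    return dc_replace(table, var_names=tuple(tensor.var_names),
                      fixed_names=tuple(tensor.fixed_names))


def global_pattern(
    test_tensor: FeatureTensor,
    params: ModelParameters,
    full_length_only: bool = True,
    batch_size: int = 1024,
) -> GlobalPattern:
    """Average attentions/coefficients over a test set.

    By default only full-length (prefix week 16) samples enter, matching
    16-week attention and coefficient axes; set ``full_length_only=False``
    to average over every prefix sample.
    """
    tensor = test_tensor.full_length_only() if full_length_only else test_tensor
    if tensor.n_samples == 0:
        raise ValueError("empty test set")
    N = params.n_var
    w = params.arrays["w"]
    sum_alpha = np.zeros(N_WEEKS)
    sum_beta = np.zeros((N_WEEKS, N))
    sum_coeff = np.zeros((N_WEEKS, N))
    for start in range(0, tensor.n_samples, batch_size):
        stop = min(start + batch_size, tensor.n_samples)
        out = forward_batch(params, tensor.X[start:stop], tensor.F[start:stop],
                            tensor.mask[start:stop])
        sum_alpha += out["alpha"].sum(axis=0)
        sum_beta += out["beta"].sum(axis=0)
        coeff = out["alpha"][:, :, None] * out["beta"] * w[:N]
        sum_coeff += coeff.sum(axis=0)
    n = tensor.n_samples
    return GlobalPattern(
        mean_alpha=sum_alpha / n,
        mean_beta=sum_beta / n,
        mean_coefficients=sum_coeff / n,
        mean_fixed_coefficients=w[N:].copy(),
        n_samples=n,
        var_names=tuple(tensor.var_names),
        fixed_names=tuple(tensor.fixed_names),
    )


def raw_unit_coefficients(table: ContributionTable, scaler: Scaler) -> ContributionTable:
    """Convert standardized coefficients to per-raw-unit coefficients.

    A coefficient fitted on a z-scored column shrinks by the column's SD
    when expressed per raw unit (per n/week, per kcal, ...); contributions
    are invariant because the value grows by the same factor.
    """
    if scaler is None:
        raise ValueError("scaler required to recover raw units")
    return dc_replace(
        table,
        coefficients=table.coefficients / scaler.var_sd,
        fixed_coefficients=table.fixed_coefficients / scaler.fixed_sd,
        units="raw",
    )
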