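"""Masked non-negative CP fitting by EM imputation + multiplicative updates.

The solver minimizes the weighted least-squares objective

    f(A, B, C) = sum_{(i,j,k): w_fit=1} (X[i,j,k] - Xhat[i,j,k])^2

where ``w_fit`` is an element-wise binary fit weight (observed *and* not
CV-masked).  Each outer iteration performs one EM step — fill unweighted
cells with the current reconstruction — followed by one Lee–Seung-style
multiplicative update per mode on the filled tensor.  Both steps preserve
non-negativity, and the EM majorization makes the masked objective
non-increasing.

Cells missing from the data (weight 0 in the tensor itself) and cells
hidden for cross-validation are treated identically during fitting (both
imputed), but data-missing cells are never counted in any error metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor_model import CPModel, WeightedTensor, masked_mse, observed_cells, reconstruct

__all__ = ["FitConfig", "FitResult", "init_factors", "fit", "rec_error"]


@dataclass
class FitConfig:
    """Solver settings for one masked NTF fit.

    rank
        Number of CP components (R >= 1).
    n_iter_max
        Iteration cap; the reference workflow runs up to 1000 iterations
        before convergence.
    tol
        Relative-change convergence tolerance on the masked objective.
    seed
        Seeds the uniform(0,1) factor initialization.
    eps
        Denominator guard added in the multiplicative updates.
    """

    rank: int
    n_iter_max: int = 1000
    tol: float = 1e-8
    seed: int = 0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.n_iter_max < 1:
            raise ValueError(f"n_iter_max must be >= 1, got {self.n_iter_max}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")


@dataclass
class FitResult:
    """Outcome of one fit: the model, its objective trace, and errors."""

    model: CPModel
    objective_trace: list[float]
    n_iter_used: int
    converged: bool
    rec_error: float  # training MSE over fit-weight-1 cells


def init_factors(shape: tuple[int, int, int], rank: int, seed: int) -> CPModel:
    """Uniform(0,1) random factors, deterministic given ``seed``."""
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    rng = np.random.default_rng(seed)
    return CPModel(*(rng.uniform(size=(dim, rank)) for dim in shape))


def _mode_update(
    factors: list[np.ndarray], x_filled: np.ndarray, mode: int, eps: float
) -> np.ndarray:
    """One multiplicative update of factor ``mode`` against the filled tensor.

    The numerator is the mode-n unfolding times the Khatri–Rao product of
    the other two factors; the denominator uses the Hadamard product of
    the other factors' Gram matrices (equivalent to KR^T KR, cheaper).
    """
    a, b, c = factors
    if mode == 0:
        num = np.einsum("ijk,jr,kr->ir", x_filled, b, c, optimize=True)
        gram = (b.T @ b) * (c.T @ c)
        tgt = a
    elif mode == 1:
        num = np.einsum("ijk,ir,kr->jr", x_filled, a, c, optimize=True)
        gram = (a.T @ a) * (c.T @ c)
        tgt = b
    else:
        num = np.einsum("ijk,ir,jr->kr", x_filled, a, b, optimize=True)
        gram = (a.T @ a) * (b.T @ b)
        tgt = c
    return tgt * num / (tgt @ gram + eps)


def fit(x: WeightedTensor, fit_weights: np.ndarray, cfg: FitConfig) -> FitResult:
    """Fit a rank-``cfg.rank`` non-negative CP model under element weights.

    ``fit_weights`` must be element-wise <= ``x.weights``: the solver
    never trains on data-missing cells.  Raises if no cell has fit
    weight 1 or if any weight-1 cell holds a negative value.
    """
    w = np.asarray(fit_weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError(f"fit_weights shape {w.shape} != tensor shape {x.shape}")
    if (w > x.weights).any():
        raise ValueError("fit_weights may not exceed the tensor's observation weights")
    n_train = w.sum()
    if n_train == 0:
        raise ValueError("no cell has fit weight 1; nothing to fit")
    vals = np.nan_to_num(x.values, nan=0.0)
    if (vals[w == 1] < 0).any():
        raise ValueError("The data tensor contains negative elements")

    model = init_factors(x.shape, cfg.rank, cfg.seed)
    factors = list(model.factors)

    def objective(xhat: np.ndarray) -> float:
        return float(np.sum(w * (vals - xhat) ** 2))

    trace: list[float] = []
    converged = False
    n_iter = 0
    xhat = np.einsum("ir,jr,kr->ijk", *factors, optimize=True)
    f_prev = objective(xhat)
    for n_iter in range(1, cfg.n_iter_max + 1):
        x_filled = w * vals + (1.0 - w) * xhat
        for mode in range(3):
            factors[mode] = _mode_update(factors, x_filled, mode, cfg.eps)
        xhat = np.einsum("ir,jr,kr->ijk", *factors, optimize=True)
        f_cur = objective(xhat)
        trace.append(f_cur)
        if abs(f_cur - f_prev) / max(f_prev, cfg.eps) < cfg.tol:
            converged = True
            break
        f_prev = f_cur

    final = CPModel(*factors)
    train_mse = float(np.sum(w * (vals - xhat) ** 2) / n_train)
    return FitResult(
        model=final,
        objective_trace=trace,
        n_iter_used=n_iter,
        converged=converged,
        rec_error=train_mse,
    )


def rec_error(result: FitResult, x: WeightedTensor) -> float:
    """MSE over *all* observed cells of ``x``, regardless of fit weights."""
    return masked_mse(x, reconstruct(result.model), observed_cells(x))
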