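"""Core tensor/factor data types and error metrics.

A :class:`WeightedTensor` couples a dense third-order non-negative array
(subjects x symptoms x days) with a binary observation-weight array:
weight 1 marks an observed cell, weight 0 a missing cell.  Missing cells
additionally carry NaN in ``values`` as a guard, but the weight array is
authoritative everywhere.

A :class:`CPModel` is a rank-R CANDECOMP/PARAFAC factor triple with all
entries constrained >= 0.  There is no separate component-weight vector:
component scale is absorbed into the factor columns, matching the raw
output of multiplicative-update solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedTensor",
    "CPModel",
    "reconstruct",
    "masked_mse",
    "observed_cells",
]

CellSet = set[tuple[int, int, int]]


@dataclass
class WeightedTensor:
    """Dense third-order non-negative tensor with observation weights.

    Parameters
    ----------
    values
        Array of shape (I, J, K), float.  Observed cells hold finite
        values >= 0; missing cells hold NaN.
    weights
        Binary array, same shape: 1 = observed, 0 = missing.
    dim_labels
        Optional (subject, symptom, day) label lists for the three modes.
    """

    values: np.ndarray
    weights: np.ndarray
    dim_labels: tuple[list | None, list | None, list | None] = (None, None, None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a third-order tensor, got {self.values.ndim} dimensions"
            )
        if self.weights.shape != self.values.shape:
            raise ValueError(
                f"weights shape {self.weights.shape} != values shape {self.values.shape}"
            )
        if not np.isin(self.weights, (0.0, 1.0)).all():
            raise ValueError("weights must contain only 0 and 1")
        obs = self.weights == 1
        obs_vals = self.values[obs]
        if not np.isfinite(obs_vals).all():
            raise ValueError("observed cells (weight 1) must hold finite values")
        if (obs_vals < 0).any():
            raise ValueError(
                "The data tensor contains negative elements: non-negative "
                "factorization requires values >= 0"
            )
        # enforce the NaN sentinel at missing cells
        self.values = self.values.copy()
        self.values[~obs] = np.nan

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.weights.sum())


@dataclass
class CPModel:
    """Rank-R non-negative CP factor triple.

    ``factor_subject`` (I x R), ``factor_symptom`` (J x R) and
    ``factor_day`` (K x R) share the column count R; the model tensor is
    the sum over r of the outer products of their r-th columns.
    """

    factor_subject: np.ndarray
    factor_symptom: np.ndarray
    factor_day: np.ndarray

    def __post_init__(self) -> None:
        self.factor_subject = np.asarray(self.factor_subject, dtype=float)
        self.factor_symptom = np.asarray(self.factor_symptom, dtype=float)
        self.factor_day = np.asarray(self.factor_day, dtype=float)
        ranks = {f.shape[1] for f in self.factors}
        if len(ranks) != 1:
            raise ValueError(f"factor column counts differ: {sorted(ranks)}")
        for name, f in zip(("subject", "symptom", "day"), self.factors):
            if f.ndim != 2:
                raise ValueError(f"factor_{name} must be a matrix")
            if (f < 0).any():
                raise ValueError(f"factor_{name} has negative entries")

    @property
    def factors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.factor_subject, self.factor_symptom, self.factor_day)

    @property
    def rank(self) -> int:
        return self.factor_subject.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return (
            self.factor_subject.shape[0],
            self.factor_symptom.shape[0],
            self.factor_day.shape[0],
        )


def reconstruct(model: CPModel) -> np.ndarray:
    """Dense CP reconstruction X_hat[i,j,k] = sum_r A[i,r] B[j,r] C[k,r]."""
    a, b, c = model.factors
    return np.einsum("ir,jr,kr->ijk", a, b, c, optimize=True)


def masked_mse(x: WeightedTensor, xhat: np.ndarray, cell_set: CellSet) -> float:
    """Mean squared error between ``x.values`` and ``xhat`` over ``cell_set``.

    Every cell in ``cell_set`` must be observed (weight 1); the mean over
    an empty set is undefined and raises.
    """
    if not cell_set:
        raise ValueError("masked_mse over an empty cell set is undefined")
    idx = tuple(np.array(sorted(cell_set)).T)
    if not (x.weights[idx] == 1).all():
        raise ValueError("cell_set contains unobserved (weight 0) cells")
    diff = x.values[idx] - np.asarray(xhat)[idx]
    return float(np.mean(diff**2))


def observed_cells(x: WeightedTensor) -> CellSet:
    """The set of (i, j, k) index triples with weight 1."""
    return {tuple(idx) for idx in np.argwhere(x.weights == 1)}
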