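"""Planted-rank non-negative tensor generator.

Every pipeline stage is testable without external data: a ground-truth
CP model with uniform(0,1) factors is planted, Gaussian noise scaled to
a fraction of the signal RMS is added (clipped at zero to preserve
non-negativity), and a fraction of cells is knocked out as missing —
uniformly at random, or whole-subject blocks to exercise the
subject-completeness filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor_model import CPModel, WeightedTensor, reconstruct

__all__ = ["PlantedSpec", "generate"]


@dataclass
class PlantedSpec:
    """Generator settings.

    dims
        Tensor shape (I, J, K).
    rank
        Planted component count; must not exceed min(I*J, J*K, I*K).
    noise_level
        Relative Gaussian noise scale: sigma as a fraction of the
        noiseless signal's root-mean-square.
    missing_fraction
        Fraction of cells set to weight 0, in [0, 1).
    missing_mode
        "uniform" knocks out cells at random; "subject_block" knocks out
        entire subject slices (for testing the completeness filter).
    """

    dims: tuple[int, int, int]
    rank: int
    noise_level: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0
    missing_mode: str = "uniform"

    def __post_init__(self) -> None:
        i, j, k = self.dims
        if min(i, j, k) < 1:
            raise ValueError(f"degenerate dims {self.dims}")
        if not 1 <= self.rank <= min(i * j, j * k, i * k):
            raise ValueError(f"rank {self.rank} infeasible for dims {self.dims}")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.missing_mode not in ("uniform", "subject_block"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")


def generate(spec: PlantedSpec) -> tuple[WeightedTensor, CPModel]:
    """Draw (tensor, ground-truth model); deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    i, j, k = spec.dims
    truth = CPModel(
        rng.uniform(size=(i, spec.rank)),
        rng.uniform(size=(j, spec.rank)),
        rng.uniform(size=(k, spec.rank)),
    )
    signal = reconstruct(truth)
    values = signal.copy()
    if spec.noise_level > 0:
        rms = float(np.sqrt(np.mean(signal**2)))
        values = values + spec.noise_level * rms * rng.standard_normal(signal.shape)
        np.clip(values, 0.0, None, out=values)

    weights = np.ones(spec.dims)
    n_cells = values.size
    if spec.missing_fraction > 0:
        if spec.missing_mode == "uniform":
            n_missing = int(np.floor(spec.missing_fraction * n_cells))
            flat = rng.choice(n_cells, size=n_missing, replace=False)
            weights.flat[flat] = 0.0
        else:
            n_subjects = int(np.floor(spec.missing_fraction * i))
            blocked = rng.choice(i, size=n_subjects, replace=False)
            weights[blocked] = 0.0
    values[weights == 0] = np.nan
    return WeightedTensor(values=values, weights=weights), truth
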