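"""Rank selection by masked (unsupervised) cross-validation.

A fraction of the observed cells is hidden ("masked as noise"), a
non-negative CP model is fitted on the rest, and each candidate rank is
scored by the imputation error on the hidden cells — the *test error*.
The selected rank minimizes the median test error over random trials;
the per-trial *reconstruction error* (MSE over all observed cells) is
kept alongside for elbow-style inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masked_ntf import FitConfig, FitResult, fit
from .tensor_model import WeightedTensor, reconstruct

__all__ = [
    "MaskSpec",
    "CVGrid",
    "make_mask",
    "run_trial",
    "run_grid",
    "select_rank",
    "best_trial",
    "trial_seed",
]

#: Masking above this percentage is known to destabilize the decomposition
#: (global patterns dominate and the rank tends to be underestimated).
RATIO_WARN_THRESHOLD = 40.0


@dataclass
class MaskSpec:
    """One CV mask: the observed cells hidden for a trial."""

    seed: int
    ratio: float
    masked_cells: set[tuple[int, int, int]]


@dataclass
class CVGrid:
    """Per-(rank, trial) errors plus the selected best rank.

    ``records`` is a long-format DataFrame with columns
    rank, trial, seed, test_error, rec_error — exactly ``trials_per_rank``
    rows per rank.  ``models`` maps (rank, trial) to the fitted result.
    """

    records: pd.DataFrame
    ranks: range
    trials_per_rank: int
    best_rank: int
    per_rank_median_test_error: dict[int, float]
    models: dict[tuple[int, int], FitResult] = field(default_factory=dict)


def make_mask(x: WeightedTensor, ratio: float, seed: int) -> MaskSpec:
    """Sample floor(ratio/100 * n_observed) observed cells to hide.

    Deterministic given ``seed``.  Warns when ratio > 40 (decomposition
    becomes unstable) and when ratio == 0 (CV degenerates: nothing is
    held out).  Raises if masking would leave no training cell.
    """
    if not 0 <= ratio <= 100:
        raise ValueError(f"ratio must be in [0, 100], got {ratio}")
    if ratio == 0:
        warnings.warn("ratio = 0 masks nothing; cross-validation degenerates")
    elif ratio > RATIO_WARN_THRESHOLD:
        warnings.warn(
            f"masking ratio {ratio}% > {RATIO_WARN_THRESHOLD:.0f}% tends to make "
            "the decomposition unstable and underestimate the rank"
        )
    obs = np.argwhere(x.weights == 1)
    n_obs = len(obs)
    n_mask = int(np.floor(ratio / 100.0 * n_obs))
    if n_obs - n_mask == 0:
        raise ValueError("masking would leave zero training cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_obs, size=n_mask, replace=False)
    cells = {tuple(obs[i]) for i in chosen}
    return MaskSpec(seed=seed, ratio=ratio, masked_cells=cells)


def _errors(x: WeightedTensor, xhat: np.ndarray, mask: MaskSpec) -> tuple[float, float]:
    """(test_error over masked cells, rec_error over all observed cells)."""
    vals = np.nan_to_num(x.values, nan=0.0)
    sq = (vals - xhat) ** 2
    rec = float(np.sum(x.weights * sq) / x.weights.sum())
    if not mask.masked_cells:
        raise ValueError("test error over an empty mask is undefined")
    idx = tuple(np.array(sorted(mask.masked_cells)).T)
    test = float(np.mean(sq[idx]))
    return test, rec


def run_trial(
    x: WeightedTensor, rank: int, mask: MaskSpec, cfg: FitConfig
) -> tuple[float, float, FitResult]:
    """One masked fit: train with the masked cells' weight zeroed, score on them."""
    fit_weights = x.weights.copy()
    if mask.masked_cells:
        idx = tuple(np.array(sorted(mask.masked_cells)).T)
        fit_weights[idx] = 0.0
    cfg = FitConfig(
        rank=rank, n_iter_max=cfg.n_iter_max, tol=cfg.tol, seed=cfg.seed, eps=cfg.eps
    )
    result = fit(x, fit_weights, cfg)
    test_error, rec = _errors(x, reconstruct(result.model), mask)
    return test_error, rec, result


def trial_seed(seed_base: int, rank: int, trial: int, stage: int = 0) -> int:
    """Deterministic init seed for grid cell (rank, trial), independent of
    scheduling order (safe for parallel execution).  ``stage`` separates
    the masked CV fits (0) from the unmasked refits (1)."""
    ss = np.random.SeedSequence([seed_base, rank, trial, stage])
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(
    x: WeightedTensor,
    rank_min: int,
    rank_max: int,
    trials: int,
    ratio: float,
    seed_base: int,
    n_iter_max: int = 1000,
    tol: float = 1e-8,
    n_jobs: int = 1,
    keep_models: bool = False,
) -> CVGrid:
    """The (rank x trial) grid of masked fits.

    One mask per trial, drawn with seed ``seed_base + t`` and shared
    across all ranks (paired design: every rank is scored on the same
    held-out cells within a trial).  Fit initialization seeds derive
    from (seed_base, rank, trial), so results do not depend on execution
    order; with ``n_jobs > 1`` grid cells run in parallel via joblib.
    """
    if rank_min > rank_max:
        raise ValueError(f"rank_min {rank_min} > rank_max {rank_max}")
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    ranks = range(rank_min, rank_max + 1)
    masks = {t: make_mask(x, ratio, seed_base + t) for t in range(1, trials + 1)}

    jobs = [(r, t) for r in ranks for t in range(1, trials + 1)]

    def _cell(r: int, t: int):
        seed = trial_seed(seed_base, r, t)
        cfg = FitConfig(rank=r, n_iter_max=n_iter_max, tol=tol, seed=seed)
        test_err, rec, result = run_trial(x, r, masks[t], cfg)
        return r, t, seed, test_err, rec, result

    if n_jobs > 1:
        from joblib import Parallel, delayed

        out = Parallel(n_jobs=n_jobs)(delayed(_cell)(r, t) for r, t in jobs)
    else:
        out = [_cell(r, t) for r, t in jobs]

    records = pd.DataFrame(
        [(r, t, s, te, re_) for r, t, s, te, re_, _ in out],
        columns=["rank", "trial", "seed", "test_error", "rec_error"],
    )
    models = {(r, t): res for r, t, _, _, _, res in out} if keep_models else {}
    medians = records.groupby("rank")["test_error"].median().to_dict()
    grid = CVGrid(
        records=records,
        ranks=ranks,
        trials_per_rank=trials,
        best_rank=0,
        per_rank_median_test_error=medians,
        models=models,
    )
    grid.best_rank = select_rank(grid)
    return grid


def select_rank(grid: CVGrid) -> int:
    """Argmin over ranks of the median test error; ties go to the
    smallest rank (parsimony)."""
    medians = grid.per_rank_median_test_error
    if not medians:
        raise ValueError("empty grid")
    best = min(sorted(medians), key=lambda r: medians[r])
    return int(best)


def best_trial(results: list[FitResult]) -> FitResult:
    """The result with minimal reconstruction error; ties go to the lowest index."""
    if not results:
        raise ValueError("best_trial of an empty list")
    errs = [r.rec_error for r in results]
    return results[int(np.argmin(errs))]
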