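"""End-to-end orchestration: CV rank scan, unmasked refit, reports, plots.

Output tree (subset relevant to the run mode)::

    outdir/
      tensorly/
        rec_errors.csv, test_errors.csv     # long format: rank,trial,value
        bestrank/error.txt                  # best trial's reconstruction MSE
        bestrank/factor{1,2,3}.csv          # factor matrices at the best rank
        bestrank/model.json                 # rank, seed, iterations, objective
        <rank>/factor{1,2,3}.csv            # best masked trial per scanned rank
      plot/
        rec_errors.png, test_errors.png     # boxplots over trials per rank
        barplot/bestrank/factor{1,2,3}.png
        barplot/<rank>/factor{1,2,3}.png
      logs/pipeline.log

Rank selection uses masked fits; the ``bestrank`` model is refitted
*unmasked* (all observed cells carry fit weight 1), so the reported model
uses every observation.  When ``rank_min == rank_max`` the CV scan is
skipped entirely and the decomposition runs directly at that rank.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import load_tensor
from .masked_ntf import FitConfig, FitResult, fit
from .rank_cv import CVGrid, best_trial, run_grid, trial_seed
from .tensor_model import CPModel, WeightedTensor

__all__ = ["PipelineConfig", "run_pipeline", "write_factor_csv", "write_error_report"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


@dataclass
class PipelineConfig:
    """Arguments of one pipeline run; mirrors the workflow's config keys."""

    input: str | Path | None
    outdir: str | Path
    rank_min: int = 1
    rank_max: int = 10
    trials: int = 50
    n_iter_max: int = 1000
    ratio: float = 30.0
    tol: float = 1e-8
    seed_base: int = 0
    cores: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.rank_min <= self.rank_max:
            raise ValueError(
                f"need 1 <= rank_min <= rank_max, got --rank_min={self.rank_min} "
                f"--rank_max={self.rank_max}"
            )
        if self.trials < 1:
            raise ValueError(f"--trials must be >= 1, got {self.trials}")
        if not 0 <= self.ratio <= 100:
            raise ValueError(f"--ratio must be in [0, 100], got {self.ratio}")
        if self.n_iter_max < 1:
            raise ValueError(f"--n_iter_max must be >= 1, got {self.n_iter_max}")


def write_factor_csv(model: CPModel, outdir: str | Path, dim_labels=None) -> None:
    """factor1/2/3.csv: one file per mode, columns component_1..R."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = dim_labels or (None, None, None)
    for n, (factor, labs) in enumerate(zip(model.factors, labels), start=1):
        cols = [f"component_{r}" for r in range(1, model.rank + 1)]
        df = pd.DataFrame(factor, columns=cols)
        if labs is not None:
            df.insert(0, "label", list(labs))
        df.to_csv(outdir / f"factor{n}.csv", index=False, float_format=_FLOAT_FMT)


def read_factor_csv(outdir: str | Path) -> CPModel:
    """Inverse of :func:`write_factor_csv` (labels dropped)."""
    mats = []
    for n in range(1, 4):
        df = pd.read_csv(Path(outdir) / f"factor{n}.csv",
                         float_precision="round_trip")
        comp_cols = [c for c in df.columns if c.startswith("component_")]
        mats.append(df[comp_cols].to_numpy(dtype=float))
    return CPModel(*mats)


def _write_errors_csv(records: pd.DataFrame, column: str, path: Path) -> None:
    out = records[["rank", "trial", column]].rename(columns={column: "value"})
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_error_report(
    grid: CVGrid | None, best: FitResult, outdir: str | Path
) -> None:
    """error.txt (best trial's reconstruction MSE) plus the long-format
    rec/test error CSVs when a CV grid was run."""
    outdir = Path(outdir)
    bestdir = outdir / "bestrank"
    bestdir.mkdir(parents=True, exist_ok=True)
    (bestdir / "error.txt").write_text(_FLOAT_FMT % best.rec_error + "\n")
    if grid is not None:
        _write_errors_csv(grid.records, "rec_error", outdir / "rec_errors.csv")
        _write_errors_csv(grid.records, "test_error", outdir / "test_errors.csv")


def _plot_error_boxes(csv_path: Path, png_path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    df = pd.read_csv(csv_path)  # plots always derive from the CSVs
    fig, ax = plt.subplots(figsize=(6, 4))
    sns.boxplot(data=df, x="rank", y="value", ax=ax, color="skyblue")
    ax.set_xlabel("rank")
    ax.set_ylabel("MSE")
    ax.set_title(title)
    fig.tight_layout()
    png_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(png_path, dpi=100)
    plt.close(fig)


def _plot_factor_bars(model: CPModel, outdir: Path, dim_labels=None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    labels = dim_labels or (None, None, None)
    for n, (factor, labs) in enumerate(zip(model.factors, labels), start=1):
        r = model.rank
        fig, axes = plt.subplots(r, 1, figsize=(7, 1.6 * r), squeeze=False)
        xs = np.arange(factor.shape[0])
        for comp in range(r):
            ax = axes[comp, 0]
            ax.bar(xs, factor[:, comp], color="steelblue")
            ax.set_ylabel(f"c{comp + 1}")
            if comp == r - 1 and labs is not None and len(labs) <= 20:
                ax.set_xticks(xs)
                ax.set_xticklabels([str(v) for v in labs], rotation=90, fontsize=6)
            else:
                ax.set_xticks([])
        fig.tight_layout()
        fig.savefig(outdir / f"factor{n}.png", dpi=100)
        plt.close(fig)


def _unmasked_refits(
    x: WeightedTensor, rank: int, cfg: PipelineConfig
) -> list[FitResult]:
    results = []
    for t in range(1, cfg.trials + 1):
        seed = trial_seed(cfg.seed_base, rank, t, stage=1)
        fr = fit(
            x,
            x.weights,
            FitConfig(rank=rank, n_iter_max=cfg.n_iter_max, tol=cfg.tol, seed=seed),
        )
        logger.info(
            "unmasked rank=%d trial=%d seed=%d iters=%d rec_error=%.6g",
            rank, t, seed, fr.n_iter_used, fr.rec_error,
        )
        results.append(fr)
    return results


def run_pipeline(
    cfg: PipelineConfig, tensor: WeightedTensor | None = None
) -> dict:
    """Run the full workflow; returns {'best_rank', 'best_result', 'grid'}.

    ``tensor`` may be passed directly to bypass the ``cfg.input`` file.
    Deterministic given ``cfg.seed_base`` (PNG bytes excepted).
    """
    outdir = Path(cfg.outdir)
    (outdir / "logs").mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "logs" / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, tensor, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, tensor: WeightedTensor | None, outdir: Path) -> dict:
    if tensor is None:
        if cfg.input is None:
            raise ValueError("no input tensor: set cfg.input or pass tensor=")
        tensor = load_tensor(cfg.input)
    x = tensor
    tdir = outdir / "tensorly"
    tdir.mkdir(parents=True, exist_ok=True)

    grid: CVGrid | None = None
    if cfg.rank_min < cfg.rank_max:
        logger.info(
            "CV scan ranks %d..%d trials=%d ratio=%g", cfg.rank_min, cfg.rank_max,
            cfg.trials, cfg.ratio,
        )
        grid = run_grid(
            x,
            cfg.rank_min,
            cfg.rank_max,
            cfg.trials,
            cfg.ratio,
            cfg.seed_base,
            n_iter_max=cfg.n_iter_max,
            tol=cfg.tol,
            n_jobs=cfg.cores,
            keep_models=True,
        )
        for rec in grid.records.itertuples(index=False):
            logger.info(
                "masked rank=%d trial=%d seed=%d test_error=%.6g rec_error=%.6g",
                rec.rank, rec.trial, rec.seed, rec.test_error, rec.rec_error,
            )
        best_rank = grid.best_rank
        logger.info("selected best_rank=%d", best_rank)
    else:
        # rank_min == rank_max: skip rank estimation, decompose directly
        best_rank = cfg.rank_min
        logger.info("rank_min == rank_max == %d; skipping CV", best_rank)

    refits = _unmasked_refits(x, best_rank, cfg)
    best = best_trial(refits)

    write_error_report(grid, best, tdir)
    write_factor_csv(best.model, tdir / "bestrank", dim_labels=x.dim_labels)
    (tdir / "bestrank" / "model.json").write_text(
        json.dumps(
            {
                "rank": best_rank,
                "n_iter_used": best.n_iter_used,
                "converged": best.converged,
                "final_objective": best.objective_trace[-1],
                "rec_error": best.rec_error,
                "seed_base": cfg.seed_base,
            },
            indent=2,
        )
        + "\n"
    )
    _plot_factor_bars(best.model, outdir / "plot" / "barplot" / "bestrank",
                      dim_labels=x.dim_labels)

    if grid is not None:
        # per-rank outputs: best masked trial (min rec_error) at each rank
        for r in grid.ranks:
            sub = grid.records[grid.records["rank"] == r]
            t_best = int(sub.loc[sub["rec_error"].idxmin(), "trial"])
            model_r = grid.models[(r, t_best)].model
            write_factor_csv(model_r, tdir / str(r), dim_labels=x.dim_labels)
            _plot_factor_bars(model_r, outdir / "plot" / "barplot" / str(r),
                              dim_labels=x.dim_labels)
        _plot_error_boxes(tdir / "rec_errors.csv", outdir / "plot" / "rec_errors.png",
                          "reconstruction error (no mask)")
        _plot_error_boxes(tdir / "test_errors.csv", outdir / "plot" / "test_errors.png",
                          "test error (masked CV)")

    return {"best_rank": best_rank, "best_result": best, "grid": grid}
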