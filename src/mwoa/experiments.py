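"""Desk-scale experiment runners: benchmark sweeps, wrapper-selection
comparisons, and convergence-curve export.

Every runner fans seeds out as ``base_seed + run_index``, so tables are
reproducible cell-by-cell and any cell can be recomputed in isolation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .feature_selection import select_features
from .ffnn import FFNNClassifier, FFNNConfig
from .optimizers import OptimizerConfig, optimize_benchmark
from .preprocessing import TabularDataset

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkRunConfig",
    "run_benchmark_suite",
    "benchmark_cell",
    "run_selection_experiment",
    "export_convergence_curves",
]


@dataclass
class BenchmarkRunConfig:
    functions: list
    variants: list = field(default_factory=lambda: ["mwoa2"])
    runs: int = 30
    n_agents: int = 30
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


def benchmark_cell(
    function_id: str, variant: str, config: BenchmarkRunConfig
) -> tuple[list, list]:
    """All per-run results for one (function, variant) cell."""
    results, failures = [], []
    for r in range(config.runs):
        cfg = OptimizerConfig(
            variant=variant,
            n_agents=config.n_agents,
            max_iter=config.max_iter,
            seed=config.seed + r,
        )
        try:
            results.append(optimize_benchmark(function_id, cfg))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("run %d on %s/%s failed: %s", r, function_id, variant, exc)
            failures.append(r)
    return results, failures


def run_benchmark_suite(config: BenchmarkRunConfig) -> tuple[pd.DataFrame, dict]:
    """Mean and sample std of final best values per (function, variant).

    Returns the table and the raw per-cell histories (for curve export).
    Cells with failed runs are flagged in the ``completed`` column.
    """
    rows = []
    histories: dict[tuple, np.ndarray] = {}
    for fid in config.functions:
        for variant in config.variants:
            results, failures = benchmark_cell(fid, variant, config)
            finals = np.array([res.best_value for res in results])
            histories[(fid, variant)] = np.vstack([res.history for res in results])
            rows.append(
                {
                    "function": fid,
                    "variant": variant,
                    "avg": float(np.mean(finals)),
                    "std": metrics.sample_std(finals) if finals.size > 1 else 0.0,
                    "completed": len(results),
                    "requested": config.runs,
                }
            )
    return pd.DataFrame(rows), histories


def export_convergence_curves(histories: dict) -> dict[str, str]:
    """Median and quartile best-so-far traces as CSV text per cell."""
    out = {}
    for (fid, variant), H in histories.items():
        if H.size == 0:
            continue
        med = np.median(H, axis=0)
        q1 = np.quantile(H, 0.25, axis=0)
        q3 = np.quantile(H, 0.75, axis=0)
        lines = ["iteration,median,q1,q3"]
        lines += [
            f"{i + 1},{float(med[i])!r},{float(q1[i])!r},{float(q3[i])!r}"
            for i in range(H.shape[1])
        ]
        out[f"{fid}_{variant}.csv"] = "\n".join(lines) + "\n"
    return out


def run_selection_experiment(
    cohorts: list[TabularDataset],
    variants: list[str] | None = None,
    n_agents: int = 10,
    max_iter: int = 20,
    fitness_repeats: int = 3,
    restarts: int = 3,
    seed: int = 0,
    classifier_factory=None,
) -> pd.DataFrame:
    """Wrapper selection per (cohort, variant): fitness, subset size,
    wall time, and held-out metrics of a final fit on the chosen subset.

    Wall times are recorded for context only; they are hardware-bound.
    """
    variants = variants or ["woa", "mwoa2"]
    rows = []
    for cohort in cohorts:
        for variant in variants:
            cfg = OptimizerConfig(variant=variant, n_agents=n_agents, max_iter=max_iter)
            t0 = time.perf_counter()
            sel = select_features(
                cohort,
                optimizer_config=cfg,
                classifier_factory=classifier_factory,
                N=fitness_repeats,
                repetitions=restarts,
                seed=seed,
            )
            elapsed = time.perf_counter() - t0
            report = _final_holdout_metrics(cohort, sel.best_mask.indices, seed)
            rows.append(
                {
                    "profile": cohort.profile,
                    "variant": variant,
                    "best_fitness": sel.best_fitness,
                    "n_features_chosen": sel.n_features_chosen,
                    "mask_code": sel.best_mask.code,
                    "holdout_mce": report.mce,
                    "holdout_accuracy": report.accuracy,
                    "wall_time_s": elapsed,
                }
            )
    return pd.DataFrame(rows)


def _final_holdout_metrics(
    dataset: TabularDataset, indices: tuple, seed: int
) -> metrics.MetricsReport:
    from sklearn.model_selection import train_test_split

    X = dataset.features[:, list(indices)]
    y = dataset.labels
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, stratify=y, random_state=seed % (2**31)
    )
    clf = FFNNClassifier(FFNNConfig(max_epochs=50, seed=seed))
    clf.fit(X_tr, y_tr)
    cm = metrics.confusion(y_te, clf.predict(X_te), int(y.max()))
    return metrics.accuracy_precision_recall(cm)
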