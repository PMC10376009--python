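"""Benchmark orchestration: repeats x feature tables x algorithms.

Replays the comparison protocol around the wrapper stage: the data are
re-split ten times (stratified 80/20, one split per repeat shared by every
table and algorithm so cells are comparable), each optimizer prunes each
table's features on each split, the all-ones mask provides the full-features
baseline, and per-cell mean +/- sample SD of holdout accuracy, selected
feature count, and wall-clock time are emitted as CSV.  Every printed cell
is recomputable from the persisted per-run JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import FeatureTable
from .fitness import CostConfig, SVMSettings, evaluate_mask, make_fitness, stratified_holdout
from .optimizers import ALGORITHMS, OptimizerConfig, run_optimizer

__all__ = ["RunConfig", "run_benchmark", "summarize"]

logger = logging.getLogger("budl.experiment")

FULL_FEATURES_COLUMN = "full_features"


@dataclass
class RunConfig:
    """Protocol parameters for one benchmark sweep."""

    tables: dict[str, FeatureTable]
    algorithms: tuple[str, ...] = ALGORITHMS
    repeats: int = 10
    test_fraction: float = 0.2
    cost: CostConfig = field(default_factory=CostConfig)
    svm: SVMSettings = field(default_factory=SVMSettings)
    population_size: int = 10
    max_iterations: int = 100
    base_seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise ValueError(f"unknown algorithms: {unknown}; valid: {', '.join(ALGORITHMS)}")
        if not self.tables:
            raise ValueError("at least one feature table is required")


def _run_record(table_name, algorithm, repeat, seed, accuracy, n_selected, cost, elapsed, trace=None):
    rec = {
        "table": table_name,
        "algorithm": algorithm,
        "repeat": repeat,
        "seed": seed,
        "accuracy": accuracy,
        "n_selected": n_selected,
        "cost": cost,
        "elapsed_seconds": elapsed,
    }
    if trace is not None:
        rec["trace_best_cost"] = trace
    return rec


def run_benchmark(config: RunConfig) -> dict:
    """Execute the sweep; returns records plus accuracy/size/timing summaries.

    A failing cell is logged and recorded as missing; the sweep continues and
    the returned dict's ``"failures"`` entry lists the failed cells.
    """
    records: list[dict] = []
    failures: list[dict] = []
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        (out_dir / "runs").mkdir(parents=True, exist_ok=True)

    for repeat in range(config.repeats):
        seed = config.base_seed + repeat
        for table_name, table in config.tables.items():
            split = stratified_holdout(table.labels, config.test_fraction, seed)
            fitness = make_fitness(table, split, config.cost, config.svm)

            # full-features baseline for this repeat
            full = evaluate_mask(
                table, split, np.ones(table.n_features, dtype=bool), config.cost, config.svm
            )
            records.append(
                _run_record(
                    table_name, FULL_FEATURES_COLUMN, repeat, seed,
                    full.accuracy, full.n_selected, full.cost, 0.0,
                )
            )

            for algorithm in config.algorithms:
                opt = OptimizerConfig(
                    algorithm=algorithm,
                    population_size=config.population_size,
                    max_iterations=config.max_iterations,
                    seed=seed,
                )
                try:
                    res = run_optimizer(table, split, config.cost, opt, config.svm, fitness)
                except Exception as exc:  # partial-failure policy: record and go on
                    logger.error(
                        "cell failed: table=%s algo=%s repeat=%d: %s",
                        table_name, algorithm, repeat, exc,
                    )
                    failures.append(
                        {"table": table_name, "algorithm": algorithm, "repeat": repeat,
                         "error": str(exc)}
                    )
                    continue
                logger.info(
                    "table=%s algo=%s repeat=%d seed=%d best_cost=%.6f acc=%.4f k=%d",
                    table_name, algorithm, repeat, seed,
                    res.best_cost, res.best_accuracy, res.n_selected,
                )
                rec = _run_record(
                    table_name, algorithm, repeat, seed,
                    res.best_accuracy, res.n_selected, res.best_cost,
                    res.elapsed_seconds, list(res.trace.best_cost),
                )
                records.append(rec)
                if out_dir is not None:
                    fname = out_dir / "runs" / f"{table_name}_{algorithm}_r{repeat}.json"
                    with open(fname, "w") as fh:
                        json.dump(
                            rec | {"best_mask": "".join(map(str, res.best_mask.tolist()))},
                            fh,
                        )

    summaries = summarize_records(records)
    if out_dir is not None:
        summaries["accuracy"].to_csv(out_dir / "accuracy_summary.csv")
        summaries["n_features"].to_csv(out_dir / "nfeatures_summary.csv")
        summaries["timing"].to_csv(out_dir / "timing_summary.csv")
        with open(out_dir / "records.json", "w") as fh:
            json.dump({"records": records, "failures": failures}, fh)
    return {"records": records, "failures": failures, **summaries}


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 1:
        logger.warning("single repeat: SD reported as 0")
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))  # sample SD (n-1)


def summarize_records(records: list[dict]) -> dict[str, pd.DataFrame]:
    """Mean +/- SD tables (accuracy %, feature counts, seconds) from run records.

    Accuracy cells are formatted with one decimal, feature counts as
    integers; the underlying float precision stays in the records.
    """
    if not records:
        raise ValueError("no run records to summarize")
    df = pd.DataFrame(records)
    tables = sorted(df["table"].unique())
    algos = [a for a in list(ALGORITHMS) + [FULL_FEATURES_COLUMN] if a in set(df["algorithm"])]

    acc = pd.DataFrame(index=tables, columns=algos, dtype=object)
    nfeat = pd.DataFrame(index=tables, columns=algos, dtype=object)
    for tname in tables:
        for algo in algos:
            cell = df[(df["table"] == tname) & (df["algorithm"] == algo)]
            if cell.empty:
                acc.loc[tname, algo] = ""
                nfeat.loc[tname, algo] = ""
                continue
            if len(cell) != df[df["table"] == tname].groupby("algorithm").size().max():
                logger.warning(
                    "inconsistent grid: %s/%s has n=%d repeats", tname, algo, len(cell)
                )
            m, s = _mean_sd([100.0 * a for a in cell["accuracy"]])
            acc.loc[tname, algo] = f"{m:.1f} ± {s:.1f}"
            m, s = _mean_sd(list(cell["n_selected"]))
            nfeat.loc[tname, algo] = f"{m:.0f} ± {s:.0f}"

    timing_rows = []
    for algo in algos:
        if algo == FULL_FEATURES_COLUMN:
            continue
        cell = df[df["algorithm"] == algo]
        m, s = _mean_sd(list(cell["elapsed_seconds"]))
        timing_rows.append({"algorithm": algo, "mean_seconds": m, "sd_seconds": s})
    timing = pd.DataFrame(timing_rows)
    return {"accuracy": acc, "n_features": nfeat, "timing": timing}


def summarize(results_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Recompute the summary tables from a sweep's persisted records.json."""
    path = Path(results_dir) / "records.json"
    if not path.exists():
        raise FileNotFoundError(f"no records.json under {results_dir}")
    with open(path) as fh:
        payload = json.load(fh)
    return summarize_records(payload["records"])
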