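"""Network selection: keep backbones whose optimized accuracy clears a bar.

After each pre-trained backbone's deep features have been pruned by a
wrapper run, backbones whose best holdout accuracy exceeds a threshold
(94% by default, strictly) are retained; their selected feature columns are
concatenated sample-wise into one combined descriptor, and a final SVM is
trained on it — optionally after a second wrapper pass over the combined
columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import FeatureTable
from .fitness import CostConfig, FitnessResult, HoldoutSplit, SVMSettings, evaluate_mask
from .optimizers import OptimizerConfig, SelectionResult, run_optimizer

__all__ = [
    "NetworkRunSummary",
    "ConcatenatedFeatureSet",
    "select_networks",
    "concatenate_selected",
    "final_classifier",
]

DEFAULT_THRESHOLD_PCT = 94.0


@dataclass(frozen=True)
class NetworkRunSummary:
    """Best wrapper-run outcome for one backbone: accuracy (%) and the kept columns."""

    backbone: str
    algorithm: str
    best_accuracy_pct: float
    selected_feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.best_accuracy_pct <= 100.0:
            raise ValueError("best_accuracy_pct must lie in [0, 100]")


@dataclass
class ConcatenatedFeatureSet:
    """Selected columns of the retained backbones, concatenated sample-wise."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]
    contributing_networks: list[str]

    def as_table(self) -> FeatureTable:
        return FeatureTable(
            matrix=self.matrix,
            labels=self.labels,
            feature_ids=self.feature_ids,
            source="concat(" + "+".join(self.contributing_networks) + ")",
        )


def select_networks(
    summaries: list[NetworkRunSummary], threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> list[str]:
    """Backbones with accuracy strictly above the threshold, best first.

    A summary at exactly the threshold is excluded; an empty selection is
    returned as an empty list (the caller decides how to proceed).
    """
    if not summaries:
        raise ValueError("summaries must be non-empty")
    if not 0.0 < threshold_pct < 100.0:
        raise ValueError("threshold_pct must be in (0, 100)")
    passing = [s for s in summaries if s.best_accuracy_pct > threshold_pct]
    passing.sort(key=lambda s: (-s.best_accuracy_pct, s.backbone))
    return [s.backbone for s in passing]


def concatenate_selected(
    tables: dict[str, FeatureTable],
    summaries: list[NetworkRunSummary],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> ConcatenatedFeatureSet:
    """Concatenate each retained backbone's selected columns, in selection order.

    All contributing tables must share the sample order (labels are compared
    row-wise); provenance-tagged feature ids are preserved.
    """
    chosen = select_networks(summaries, threshold_pct)
    if not chosen:
        raise ValueError(f"no network passed the {threshold_pct}% threshold")
    by_backbone = {s.backbone: s for s in summaries}

    blocks, ids = [], []
    ref_labels = None
    for name in chosen:
        if name not in tables:
            raise KeyError(f"no feature table supplied for selected backbone {name!r}")
        table = tables[name]
        if ref_labels is None:
            ref_labels = table.labels
        else:
            if table.n_samples != len(ref_labels):
                raise ValueError(f"sample count mismatch in table for {name!r}")
            if not np.array_equal(table.labels, ref_labels):
                raise ValueError(f"label/sample order mismatch in table for {name!r}")
        sub = table.select_columns(list(by_backbone[name].selected_feature_ids))
        blocks.append(sub.matrix)
        ids.extend(sub.feature_ids)
    return ConcatenatedFeatureSet(
        matrix=np.hstack(blocks),
        labels=ref_labels.copy(),
        feature_ids=ids,
        contributing_networks=chosen,
    )


def final_classifier(
    concat: ConcatenatedFeatureSet,
    split: HoldoutSplit,
    cost_config: CostConfig = CostConfig(),
    svm_settings: SVMSettings = SVMSettings(),
    rerun: OptimizerConfig | None = None,
) -> tuple[FitnessResult, SelectionResult | None]:
    """Train/evaluate the final SVM on the concatenated feature set.

    With ``rerun`` given, a second wrapper pass first prunes the concatenated
    columns and the fit of that run's best mask is reported alongside the
    plain all-columns fit.
    """
    table = concat.as_table()
    full = evaluate_mask(
        table, split, np.ones(table.n_features, dtype=bool), cost_config, svm_settings
    )
    rerun_result = None
    if rerun is not None:
        rerun_result = run_optimizer(table, split, cost_config, rerun, svm_settings)
    return full, rerun_result
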