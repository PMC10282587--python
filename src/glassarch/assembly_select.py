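"""Weighted rank aggregation for choosing among candidate assemblies.

Each assembly is ranked on every metric (1 = best, average ranks on ties,
per-metric optimisation direction), ranks are combined as a weighted sum,
and the assembly with the smallest weighted score wins.  Metric computation
itself (BUSCO, read mapping, ...) is upstream; this module consumes the
resulting table.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
import yaml
from scipy.stats import rankdata

HIGHER = "higher_better"
LOWER = "lower_better"


@dataclass(frozen=True)
class MetricSpec:
    direction: str  # higher_better | lower_better
    weight: float

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"direction must be {HIGHER} or {LOWER}")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


#: the default scheme: the seven standard evaluation metrics, unit weights
DEFAULT_SCHEME: dict[str, MetricSpec] = {
    "n50": MetricSpec(HIGHER, 1.0),
    "size_delta_pct": MetricSpec(LOWER, 1.0),
    "mean_scaffold_len": MetricSpec(HIGHER, 1.0),
    "scaffold_count": MetricSpec(LOWER, 1.0),
    "busco_single_complete": MetricSpec(HIGHER, 1.0),
    "rna_map_pct": MetricSpec(HIGHER, 1.0),
    "dna_map_pct": MetricSpec(HIGHER, 1.0),
}


@dataclass(frozen=True)
class RankResult:
    ranks: pd.DataFrame  # per-assembly per-metric rank (1 = best)
    scores: pd.Series  # weighted rank sum per assembly
    ordering: tuple[str, ...]  # ascending score, ties by id

    @property
    def best(self) -> str:
        return self.ordering[0]


def load_scheme(path) -> dict[str, MetricSpec]:
    """Load a ranking scheme from YAML: ``metric: {direction:..., weight:...}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: MetricSpec(spec["direction"], float(spec.get("weight", 1.0)))
        for name, spec in raw.items()
    }


def rank_assemblies(
    table: pd.DataFrame, scheme: Mapping[str, MetricSpec] | None = None
) -> RankResult:
    """Rank assemblies by weighted sum of per-metric ranks.

    *table* rows are assemblies (unique index), columns are metrics; every
    metric in the scheme must be present with no missing values.
    """
    if scheme is None:
        scheme = DEFAULT_SCHEME
    if not scheme:
        raise ValueError("ranking scheme is empty")
    if table.index.has_duplicates:
        raise ValueError("assembly ids must be unique")
    if all(spec.weight == 0 for spec in scheme.values()):
        raise ValueError("at least one metric must have positive weight")
    ranks = {}
    for metric, spec in scheme.items():
        if metric not in table.columns:
            raise KeyError(f"metric {metric!r} missing from table")
        col = table[metric].astype(float)
        if col.isna().any():
            raise ValueError(f"metric {metric!r} has missing values")
        values = col.to_numpy()
        if spec.direction == HIGHER:
            values = -values
        ranks[metric] = rankdata(values, method="average")
    rank_df = pd.DataFrame(ranks, index=table.index)
    scores = sum(
        spec.weight * rank_df[metric] for metric, spec in scheme.items()
    )
    scores = pd.Series(scores, index=table.index, name="weighted_score")
    ordering = tuple(
        scores.to_frame()
        .assign(_id=scores.index.astype(str))
        .sort_values(["weighted_score", "_id"])
        .index
    )
    return RankResult(ranks=rank_df, scores=scores, ordering=ordering)


def size_delta_metric(assembly_size: float, predicted_size: float) -> float:
    """Absolute percent difference between assembly and predicted genome size."""
    if predicted_size <= 0:
        raise ValueError("predicted size must be positive")
    return 100.0 * abs(assembly_size - predicted_size) / predicted_size
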