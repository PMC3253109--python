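"""Optimal number of reference genes via the pairwise-variation series.

The normalization factor (NF) of a gene subset is the per-sample geometric
mean of the subset's relative quantities. V_n/n+1 measures, across samples,
the dispersion of log2(NF with the top-n ranked genes / NF with the
top-(n+1)); genes enter strictly in stability-rank order. The series runs
from V_1/2 up to V_{G-1/G}, and the n with minimal V is the optimal
reference-gene count (ties favor fewer genes).

The default dispersion metric is the sample standard deviation;
``metric="variance"`` switches to the variance. The choice is recorded on
the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .stability import QuantityMatrix, StabilityRanking

METRIC_SD = "sd"
METRIC_VARIANCE = "variance"


@dataclass
class PairwiseVariationSeries:
    """Entries (n, V_n/n+1) for n = 1..G-1 over a ranked gene list."""

    entries: list[tuple[int, float]]
    ranked_genes: list[str]
    metric: str = METRIC_SD

    def __post_init__(self):
        expected = list(range(1, len(self.ranked_genes)))
        if [n for n, _ in self.entries] != expected:
            raise ValueError("series entries must be indexed consecutively from 1")
        if any(v < 0 for _, v in self.entries):
            raise ValueError("pairwise variations must be non-negative")

    def labels(self) -> list[str]:
        return [f"V_{n}/{n + 1}" for n, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": [n for n, _ in self.entries],
                "label": self.labels(),
                "v": [v for _, v in self.entries],
            }
        )


def normalization_factor(qm: QuantityMatrix, genes: Sequence[str]) -> np.ndarray:
    """Per-sample geometric mean of the subset's quantities."""
    genes = list(genes)
    if not genes:
        raise ValueError("normalization factor needs a non-empty gene subset")
    logs = np.vstack([np.log2(qm.row(g)) for g in genes])
    return np.exp2(logs.mean(axis=0))


def pairwise_variation(
    qm: QuantityMatrix,
    ranked_genes: Sequence[str],
    n: int,
    metric: str = METRIC_SD,
) -> float:
    """Dispersion across samples of log2(NF_n / NF_{n+1})."""
    ranked_genes = list(ranked_genes)
    if not 1 <= n <= len(ranked_genes) - 1:
        raise ValueError(
            f"n must be in 1..{len(ranked_genes) - 1}, got {n}"
        )
    nf_n = normalization_factor(qm, ranked_genes[:n])
    nf_n1 = normalization_factor(qm, ranked_genes[: n + 1])
    ratios = np.log2(nf_n) - np.log2(nf_n1)
    if metric == METRIC_SD:
        return float(np.std(ratios, ddof=1))
    if metric == METRIC_VARIANCE:
        return float(np.var(ratios, ddof=1))
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_variation_series(
    qm: QuantityMatrix,
    ranking: StabilityRanking | Sequence[str],
    metric: str = METRIC_SD,
) -> PairwiseVariationSeries:
    """V_1/2 .. V_{G-1/G} with genes included strictly in rank order."""
    if isinstance(ranking, StabilityRanking):
        ranked = ranking.ordered_genes()
    else:
        ranked = list(ranking)
    if len(ranked) < 2:
        raise InsufficientDataError("pairwise variation needs >= 2 ranked genes")
    entries = [
        (n, pairwise_variation(qm, ranked, n, metric=metric))
        for n in range(1, len(ranked))
    ]
    return PairwiseVariationSeries(entries, ranked, metric=metric)


def optimal_reference_count(series: PairwiseVariationSeries) -> int:
    """The n of the minimal V entry; ties go to the smallest n."""
    if not series.entries:
        raise ValueError("empty pairwise-variation series")
    best_n, best_v = series.entries[0]
    for n, v in series.entries[1:]:
        if v < best_v:
            best_n, best_v = n, v
    return best_n
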