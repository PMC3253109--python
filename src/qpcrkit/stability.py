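"""Reference-gene stability ranking by iterative M-value exclusion.

The M value of a gene is the mean, over the other genes remaining in the
candidate panel, of the sample standard deviation of log2 expression ratios
across samples. The least stable gene (largest M) is removed one round at a
time until three genes remain; ranks are assigned by the reverse exclusion
order, with the final trio ordered by its final-panel M values so that
rank 1 is the most stable gene.

The reported M value of each gene is its M at exclusion time (final trio:
final-panel M), which is why the rank order need not match a sort of the
reported M values.

All logs are base 2; the base rescales M and V uniformly and never changes
any ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import CtTable
from .errors import InsufficientDataError, QpcrError, StageError

CALIBRATOR_MIN_CT = "min_ct"
CALIBRATOR_CONTROL_MEAN = "control_mean"


@dataclass
class QuantityMatrix:
    """Genes x samples efficiency-corrected relative quantities.

    ``q[g, s] = (1 + E_g) ** (Ct_cal(g) - Ct[g, s])`` — all entries
    positive, no missing cells.
    """

    genes: list[str]
    samples: list[str]
    q: np.ndarray  # shape (G, S)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.genes), len(self.samples)):
            raise ValueError("quantity matrix shape does not match labels")
        if not np.all(self.q > 0):
            raise ValueError("quantities must be strictly positive")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.q[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in quantity matrix") from None

    @property
    def log2q(self) -> np.ndarray:
        return np.log2(self.q)

    def subset(self, genes: Sequence[str]) -> "QuantityMatrix":
        return QuantityMatrix(
            list(genes), list(self.samples), np.vstack([self.row(g) for g in genes])
        )


@dataclass
class StabilityRanking:
    """Per-gene M value, rank (1 = most stable) and exclusion round.

    ``exclusion_round`` is 0 for the three genes that survived to the final
    panel, else the 1-based round at which the gene was removed.
    """

    genes: list[str]
    m_values: dict[str, float]
    ranks: dict[str, int]
    exclusion_rounds: dict[str, int]

    def ordered_genes(self) -> list[str]:
        """Genes sorted from rank 1 (most stable) upward."""
        return sorted(self.genes, key=lambda g: self.ranks[g])

    def to_frame(self) -> pd.DataFrame:
        order = self.ordered_genes()
        return pd.DataFrame(
            {
                "gene": order,
                "M": [self.m_values[g] for g in order],
                "rank": [self.ranks[g] for g in order],
                "exclusion_round": [self.exclusion_rounds[g] for g in order],
            }
        )


def build_quantity_matrix(
    table: CtTable,
    genes: Sequence[str],
    efficiencies: Mapping[str, float] | None = None,
    calibrator: str = CALIBRATOR_MIN_CT,
    control_type: str | None = None,
) -> QuantityMatrix:
    """Relative quantities of the listed genes across unknown samples.

    Technical replicates are collapsed to a mean Ct per (gene, sample) first.
    The per-gene calibrator Ct is either the gene's minimum Ct over samples
    (default: every gene's maximal quantity is 1) or its mean Ct over
    control-type samples (control-type geometric-mean quantity is exactly 1).
    Genes missing one or more samples are excluded with a warning; a gene
    absent from the table altogether is an error.
    """
    mean_ct = table.mean_ct_by_gene_sample()
    if mean_ct.empty:
        raise InsufficientDataError("no usable unknown reactions in table")
    present = set(mean_ct["gene"])
    for g in genes:
        if g not in present:
            raise QpcrError(
                f"gene {g!r} not found among unknown reactions; input names must "
                "exactly match those in the dataset"
            )
    samples = _unique(mean_ct["sample"])
    if len(samples) < 2:
        raise InsufficientDataError("need Ct for >= 2 samples")
    pivot = mean_ct.pivot_table(index="gene", columns="sample", values="ct")

    if calibrator == CALIBRATOR_CONTROL_MEAN:
        if control_type is None:
            raise ValueError("control_type is required for the control_mean calibrator")
        types = table.sample_types()
        control_samples = [s for s in samples if types.get(s) == control_type]
        if not control_samples:
            raise StageError(f"no samples of control type {control_type!r}")
    elif calibrator != CALIBRATOR_MIN_CT:
        raise ValueError(f"unknown calibrator {calibrator!r}")

    efficiencies = efficiencies or {}
    kept, rows = [], []
    dropped = []
    for g in genes:
        ct = pivot.loc[g, samples].to_numpy(dtype=float)
        if np.isnan(ct).any():
            dropped.append(g)
            continue
        e = float(efficiencies.get(g, 1.0))
        if not 0 < 1 + e:
            raise ValueError(f"gene {g!r}: invalid efficiency {e}")
        if calibrator == CALIBRATOR_MIN_CT:
            ct_cal = ct.min()
        else:
            idx = [samples.index(s) for s in control_samples]
            ct_cal = ct[idx].mean()
        kept.append(g)
        rows.append((1.0 + e) ** (ct_cal - ct))
    if dropped:
        warnings.warn(
            f"excluded gene(s) with missing samples: {', '.join(dropped)}",
            stacklevel=2,
        )
    if not kept:
        raise InsufficientDataError("no gene has complete Ct data across samples")
    return QuantityMatrix(kept, samples, np.vstack(rows))


def _unique(values) -> list[str]:
    seen: dict[str, None] = {}
    for v in values:
        seen.setdefault(v)
    return list(seen)


def pairwise_sd(qm: QuantityMatrix, g1: str, g2: str) -> float:
    """Sample SD (n-1) over samples of log2(q[g1]/q[g2]); symmetric."""
    if len(qm.samples) < 2:
        raise InsufficientDataError("pairwise SD needs >= 2 samples")
    ratios = np.log2(qm.row(g1)) - np.log2(qm.row(g2))
    return float(np.std(ratios, ddof=1))


def m_value(qm: QuantityMatrix, gene: str, panel: Sequence[str]) -> float:
    """Mean pairwise SD of ``gene`` against every other panel member."""
    panel = list(panel)
    if gene not in panel:
        raise ValueError(f"gene {gene!r} is not in the panel")
    if len(panel) < 2:
        raise InsufficientDataError("M value needs a panel of >= 2 genes")
    others = [k for k in panel if k != gene]
    return float(np.mean([pairwise_sd(qm, gene, k) for k in others]))


def rank_stability(qm: QuantityMatrix) -> StabilityRanking:
    """Iteratively exclude the least stable gene until three remain.

    Each round removes the gene with the largest current M (ties: the
    lexicographically later name goes), recording its M at exclusion time.
    The final trio gets ranks 3..1 by final-panel M descending, smallest M
    last (rank 1); exact trio M ties break lexicographically.
    """
    genes = list(qm.genes)
    G = len(genes)
    if G < 3:
        raise InsufficientDataError(
            f"ranking needs >= 3 genes, got {G}; use pairwise_sd directly"
        )
    panel = list(genes)
    m_out: dict[str, float] = {}
    rank: dict[str, int] = {}
    excl_round: dict[str, int] = {}
    round_no = 0
    while len(panel) > 3:
        round_no += 1
        ms = {g: m_value(qm, g, panel) for g in panel}
        worst_m = max(ms.values())
        # lexicographically later name among the tied maxima
        worst = max(g for g, m in ms.items() if m == worst_m)
        m_out[worst] = ms[worst]
        rank[worst] = len(panel)
        excl_round[worst] = round_no
        panel.remove(worst)
    final_ms = {g: m_value(qm, g, panel) for g in panel}
    for pos, g in enumerate(sorted(panel, key=lambda g: (final_ms[g], g))):
        m_out[g] = final_ms[g]
        rank[g] = pos + 1
        excl_round[g] = 0
    return StabilityRanking(genes, m_out, rank, excl_round)
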