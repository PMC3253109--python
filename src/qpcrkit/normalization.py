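"""Efficiency-corrected relative quantification and expression statistics.

Target quantities are calibrated to the control-sample mean Ct per gene
(the delta-delta-Ct construct with per-gene efficiency correction), divided
by the per-sample normalization factor built from the chosen reference
genes, and compared between each treatment type and the control on the
log2 scale with a pooled-variance Student's t-test. Fold changes R = 2^d
with d the mean log2 difference; SE of R by the delta method
(se_R = R * ln2 * SE(d)). P values are adjusted with the Benjamini-Hochberg
step-up procedure over all rows produced in one call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CtTable, write_stage_output
from .errors import InsufficientDataError, QpcrError
from .optimization import normalization_factor
from .stability import CALIBRATOR_CONTROL_MEAN, build_quantity_matrix


@dataclass(frozen=True)
class NormalizedExpression:
    """One target gene's normalized relative quantity in one sample."""

    gene: str
    sample: str
    type: str
    value: float
    log2_value: float


@dataclass
class ExpressionRatioRow:
    """Fold change of one target in one treatment type vs the control."""

    gene: str
    type: str
    ratio: float
    se_ratio: float
    t_stat: float
    p: float
    p_adj: float
    n_control: int
    n_treated: int


def normalize_targets(
    table: CtTable,
    control: str,
    ref_genes: Sequence[str],
    n_refs: int | None = None,
    efficiencies: Mapping[str, float] | None = None,
    targets: Sequence[str] | None = None,
) -> list[NormalizedExpression]:
    """Normalized relative expression of target genes per unknown sample.

    The top ``n_refs`` genes of ``ref_genes`` (user-given order) form the
    normalizer. Targets default to every unknown gene not among the
    references. By construction the control-type geometric mean of each
    target's values is exactly 1.
    """
    refs = list(ref_genes)
    if n_refs is not None:
        if not 1 <= n_refs <= len(refs):
            raise ValueError(f"n_refs must be in 1..{len(refs)}, got {n_refs}")
        refs = refs[:n_refs]
    if not refs:
        raise ValueError("at least one reference gene is required")
    unknown_genes = table.unknowns().genes
    if targets is None:
        targets = [g for g in unknown_genes if g not in refs]
    else:
        targets = list(targets)
    overlap = sorted(set(refs) & set(targets))
    if overlap:
        raise QpcrError(
            f"reference gene(s) listed among targets: {', '.join(overlap)}"
        )
    if not targets:
        raise QpcrError("no target genes to normalize")
    for g in refs + targets:
        if g not in unknown_genes:
            raise QpcrError(
                f"gene {g!r} not found among unknown reactions; input names "
                "must exactly match those in the dataset"
            )
    if control not in table.unknowns().types:
        raise QpcrError(f"control type {control!r} not present in table")

    qm = build_quantity_matrix(
        table,
        refs + targets,
        efficiencies=efficiencies,
        calibrator=CALIBRATOR_CONTROL_MEAN,
        control_type=control,
    )
    missing = [g for g in refs + targets if g not in qm.genes]
    if missing:
        raise QpcrError(
            f"gene(s) lack complete Ct data across samples: {', '.join(missing)}"
        )
    nf = normalization_factor(qm, refs)
    types = table.sample_types()
    out: list[NormalizedExpression] = []
    for t in targets:
        values = qm.row(t) / nf
        for s, v in zip(qm.samples, values):
            out.append(
                NormalizedExpression(
                    gene=t,
                    sample=s,
                    type=types[s],
                    value=float(v),
                    log2_value=float(np.log2(v)),
                )
            )
    return out


def _pooled_t(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, float, float]:
    """(d, se_d, t) for mean(y) - mean(x); se is pooled (or Welch)."""
    n1, n2 = len(x), len(y)
    d = float(y.mean() - x.mean())
    v1 = float(np.var(x, ddof=1))
    v2 = float(np.var(y, ddof=1))
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
    t = d / se if se > 0 else (0.0 if d == 0 else math.copysign(math.inf, d))
    return d, se, t


def expression_ratios(
    normed: Sequence[NormalizedExpression],
    control: str,
    targets: Sequence[str] | None = None,
    equal_var: bool = True,
) -> list[ExpressionRatioRow]:
    """Fold change, SE, t-test p and BH-adjusted p per (target, treatment).

    Each sample is one biological replicate; both sides need >= 2 samples.
    The BH family is all rows produced by this call.
    """
    by_gene: dict[str, list[NormalizedExpression]] = {}
    gene_order: list[str] = []
    type_order: list[str] = []
    for ne in normed:
        if ne.gene not in by_gene:
            by_gene[ne.gene] = []
            gene_order.append(ne.gene)
        by_gene[ne.gene].append(ne)
        if ne.type not in type_order:
            type_order.append(ne.type)
    if targets is None:
        targets = gene_order
    treatments = [t for t in type_order if t != control]
    if not treatments:
        raise QpcrError(f"no non-control treatment types besides {control!r}")

    rows: list[ExpressionRatioRow] = []
    for gene in targets:
        if gene not in by_gene:
            raise QpcrError(f"target {gene!r} missing from normalized expression")
        recs = by_gene[gene]
        ctrl = np.array([r.log2_value for r in recs if r.type == control])
        if len(ctrl) < 2:
            raise InsufficientDataError(
                f"target {gene!r}: {len(ctrl)} control sample(s); need >= 2"
            )
        for trt in treatments:
            treated = np.array([r.log2_value for r in recs if r.type == trt])
            if len(treated) < 2:
                raise InsufficientDataError(
                    f"target {gene!r}, type {trt!r}: {len(treated)} sample(s); "
                    "need >= 2"
                )
            d, se_d, t = _pooled_t(ctrl, treated, equal_var)
            if se_d > 0:
                if equal_var:
                    df = len(ctrl) + len(treated) - 2
                else:
                    v1, v2 = np.var(ctrl, ddof=1), np.var(treated, ddof=1)
                    n1, n2 = len(ctrl), len(treated)
                    df = (v1 / n1 + v2 / n2) ** 2 / (
                        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
                    )
                p = 2.0 * stats.t.sf(abs(t), df)
            else:
                p = 1.0 if d == 0 else 0.0
            ratio = 2.0**d
            rows.append(
                ExpressionRatioRow(
                    gene=gene,
                    type=trt,
                    ratio=float(ratio),
                    se_ratio=float(ratio * math.log(2.0) * se_d),
                    t_stat=float(t),
                    p=float(p),
                    p_adj=math.nan,
                    n_control=len(ctrl),
                    n_treated=len(treated),
                )
            )
    adjusted = bh_adjust([r.p for r in rows])
    for row, pa in zip(rows, adjusted):
        row.p_adj = float(pa)
    return rows


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def ratios_frame(rows: Sequence[ExpressionRatioRow]) -> pd.DataFrame:
    """Tabular form of expression-ratio rows for the Exp_ratio sheet."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "type": [r.type for r in rows],
            "R": [r.ratio for r in rows],
            "SE_R": [r.se_ratio for r in rows],
            "t": [r.t_stat for r in rows],
            "p": [r.p for r in rows],
            "p_adj": [r.p_adj for r in rows],
            "n_control": [r.n_control for r in rows],
            "n_treated": [r.n_treated for r in rows],
        }
    )


def export_exp_dataset(
    normed: Sequence[NormalizedExpression], path: str | Path | None = None
) -> pd.DataFrame:
    """Per-sample normalized table (the downstream-analysis export).

    Returns the dataframe; when ``path`` is given it is also written as the
    ``Exp_R`` stage sheet.
    """
    if not normed:
        raise ValueError("nothing to export: empty normalized expression list")
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in normed],
            "sample": [r.sample for r in normed],
            "type": [r.type for r in normed],
            "value": [r.value for r in normed],
            "log2_value": [r.log2_value for r in normed],
        }
    )
    if path is not None:
        write_stage_output(df, path, sheet="Exp_R")
    return df


def normalized_from_frame(df: pd.DataFrame) -> list[NormalizedExpression]:
    """Rebuild :class:`NormalizedExpression` records from an Exp_R export."""
    return [
        NormalizedExpression(
            gene=str(r.gene),
            sample=str(r.sample),
            type=str(r.type),
            value=float(r.value),
            log2_value=float(r.log2_value),
        )
        for r in df.itertuples(index=False)
    ]
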