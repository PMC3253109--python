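"""Per-gene PCR amplification efficiency from serially diluted standards.

Ct is regressed (OLS) on the log10 relative concentration of each dilution
level; the amplification efficiency is recovered from the slope as

    E = 10 ** (-1 / slope) - 1

so a perfect doubling per cycle (E = 1) corresponds to a slope of
-1/log10(2) ~ -3.3219 Ct per 10-fold dilution. E is stored as a fraction
(1.0 = 100%) everywhere; report columns print percent.

Serial 1 is the undiluted standard (relative concentration 1); increasing
serial means further dilution. Replicates within a dilution level are
averaged to a mean Ct before the fit (all levels weighted equally) unless
``all_points=True``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_io import CtTable
from .errors import DegenerateDesignError, InsufficientDataError


@dataclass(frozen=True)
class DilutionDesign:
    """Serial-dilution layout: ``dilut``-fold steps over ``grad`` levels."""

    dilut: float
    grad: int

    def __post_init__(self):
        if not self.dilut > 1:
            raise ValueError(f"dilut must be > 1, got {self.dilut}")
        if not self.grad >= 3:
            raise ValueError(f"grad must be >= 3, got {self.grad}")


@dataclass
class EfficiencyResult:
    """Standard-curve fit for one gene.

    ``efficiency`` is NaN (with a warning at fit time) when the slope is
    non-negative and no meaningful E exists.
    """

    gene: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    n_points: int

    @property
    def efficiency_pct(self) -> float:
        return self.efficiency * 100.0


def relative_concentrations(design: DilutionDesign) -> np.ndarray:
    """[dilut^0, dilut^-1, ..., dilut^-(grad-1)]; undiluted level first."""
    return design.dilut ** -np.arange(design.grad, dtype=float)


def fit_standard_curve(
    points: Iterable[tuple[int, float]],
    design: DilutionDesign,
    gene: str = "",
) -> EfficiencyResult:
    """OLS of Ct on log10 relative concentration.

    ``points`` are (dilution level serial, Ct) pairs; level ``k`` has
    relative concentration ``dilut**-(k-1)``. Duplicate levels are averaged.
    """
    by_level: dict[int, list[float]] = {}
    for level, ct in points:
        level = int(level)
        if not 1 <= level <= design.grad:
            raise ValueError(
                f"dilution level {level} outside design 1..{design.grad}"
            )
        if ct is None or not math.isfinite(ct):
            continue
        by_level.setdefault(level, []).append(float(ct))
    if len(by_level) < 3:
        raise InsufficientDataError(
            f"gene {gene!r}: {len(by_level)} usable dilution level(s); need >= 3"
        )
    levels = np.array(sorted(by_level), dtype=float)
    y = np.array([np.mean(by_level[int(k)]) for k in levels])
    x = -(levels - 1.0) * math.log10(design.dilut)
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError(f"gene {gene!r}: zero variance in log concentration")
    fit = stats.linregress(x, y)
    if fit.slope < 0:
        eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    else:
        warnings.warn(
            f"gene {gene!r}: non-negative standard-curve slope "
            f"({fit.slope:.4g}); efficiency undefined",
            stacklevel=2,
        )
        eff = math.nan
    return EfficiencyResult(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
        n_points=int(len(levels)),
    )


def estimate_efficiencies(
    table: CtTable, design: DilutionDesign, all_points: bool = False
) -> list[EfficiencyResult]:
    """One standard-curve fit per gene that has standard reactions.

    Genes without standards are listed in a warning and get no result.
    With ``all_points=True`` replicate reactions enter the regression
    individually instead of being averaged per level.
    """
    standards = table.standards()
    if len(standards) == 0:
        raise InsufficientDataError("table contains no standard reactions")
    per_gene: dict[str, list[tuple[int, float]]] = {}
    for r in standards:
        if r.is_missing:
            continue
        per_gene.setdefault(r.gene, []).append((r.serial, r.ct))
    results = []
    for gene in standards.genes:
        pts = per_gene.get(gene, [])
        if not all_points:
            by_level: dict[int, list[float]] = {}
            for level, ct in pts:
                by_level.setdefault(level, []).append(ct)
            pts = [(lv, float(np.mean(v))) for lv, v in sorted(by_level.items())]
        results.append(fit_standard_curve(pts, design, gene=gene))
    without = [g for g in table.genes if g not in per_gene]
    if without:
        warnings.warn(
            f"{len(without)} gene(s) have no standard reactions and were not "
            f"fitted: {', '.join(without)}",
            stacklevel=2,
        )
    return results


def filter_genes_by_efficiency(
    results: Sequence[EfficiencyResult], threshold: float
) -> list[str]:
    """Genes whose E >= threshold (fraction), in input order.

    Genes with undefined efficiency never pass. Threshold 0 keeps every
    gene with a defined E.
    """
    if not 0 <= threshold <= 2:
        raise ValueError(f"threshold must be in [0, 2], got {threshold}")
    return [
        r.gene
        for r in results
        if math.isfinite(r.efficiency) and r.efficiency >= threshold
    ]


def efficiency_map(results: Sequence[EfficiencyResult]) -> dict[str, float]:
    """Per-gene E lookup for downstream quantity construction."""
    return {r.gene: r.efficiency for r in results if math.isfinite(r.efficiency)}
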