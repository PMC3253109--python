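"""Synthetic Ct datasets with known ground truth.

Generates dilution-series standard reactions plus unknown reactions for a
panel of candidate reference genes and target genes across treatment types,
with designed per-gene amplification efficiencies, a strictly ordered
reference-gene stability structure, per-sample loading offsets shared by
all genes (the confounding variation normalization must remove), and
designed fold changes for targets. Everything needed to assert recovery is
returned alongside the table.

Noise is placed additively on Ct, i.e. multiplicatively on quantities,
matching the error structure RT-qPCR normalization assumes. Per-gene noise
magnitudes are specified in log2-quantity units and converted to Ct cycles
through the gene's amplification base (1 Ct cycle = log2(1+E) log2 units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .data_io import CtRecord, CtTable, ROLE_STANDARD, ROLE_UNKNOWN
from .efficiency import DilutionDesign
from .errors import QpcrError

DEFAULT_TYPES = ("C05", "A05", "T05")


@dataclass(frozen=True)
class SimulationDesign:
    """Shape and ground-truth parameters of a simulated experiment.

    Defaults reproduce the canonical dataset shape: 19 candidate reference
    genes and 9 target genes across 3 treatment types with one control, and
    a 5-step 10-fold dilution series of standards for every gene.
    """

    n_ref_genes: int = 19
    n_target_genes: int = 9
    types: tuple[str, ...] = DEFAULT_TYPES
    control_type: str = "C05"
    n_samples_per_type: int = 6
    true_efficiencies: Mapping[str, float] | None = None  # default: all E = 1
    ref_noise_sds: tuple[float, ...] | None = None  # log2 units, default ordered
    target_noise_sd: float = 0.25
    fold_changes: Mapping[tuple[str, str], float] | None = None
    dilution: DilutionDesign = field(default_factory=lambda: DilutionDesign(10, 5))
    n_standard_replicates: int = 2
    ct_noise_sd: float = 0.1
    load_sd: float = 0.5
    standard_type: str = "STD"
    seed: int = 0

    def __post_init__(self):
        if self.n_ref_genes < 1 or self.n_target_genes < 0:
            raise ValueError("need >= 1 reference gene and >= 0 targets")
        if self.control_type not in self.types:
            raise ValueError(
                f"control type {self.control_type!r} not among types {self.types}"
            )
        if self.ct_noise_sd < 0 or self.load_sd < 0 or self.target_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for sd in self.resolved_ref_noise_sds():
            if sd < 0:
                raise ValueError("reference noise SDs must be >= 0")
        for (gene, type_), fold in (self.fold_changes or {}).items():
            if fold <= 0:
                raise ValueError(f"fold change for {(gene, type_)} must be > 0")
            if type_ == self.control_type and fold != 1.0:
                raise ValueError("control-type fold changes must all be 1")

    # -- derived naming ----------------------------------------------------

    @property
    def ref_genes(self) -> list[str]:
        return [f"Ref{i + 1:02d}" for i in range(self.n_ref_genes)]

    @property
    def target_genes(self) -> list[str]:
        return [f"Tgt{i + 1}" for i in range(self.n_target_genes)]

    @property
    def genes(self) -> list[str]:
        return self.ref_genes + self.target_genes

    @property
    def samples(self) -> list[tuple[str, str]]:
        """(sample name, type) pairs for the unknown reactions."""
        return [
            (f"{t}_s{i + 1}", t)
            for t in self.types
            for i in range(self.n_samples_per_type)
        ]

    def resolved_ref_noise_sds(self) -> np.ndarray:
        if self.ref_noise_sds is not None:
            if len(self.ref_noise_sds) != self.n_ref_genes:
                raise ValueError("ref_noise_sds length must equal n_ref_genes")
            return np.asarray(self.ref_noise_sds, dtype=float)
        # strictly increasing by construction: gene Ref01 is the most stable
        return np.linspace(0.05, 0.05 + 0.15 * (self.n_ref_genes - 1), self.n_ref_genes)

    def efficiency_of(self, gene: str) -> float:
        if self.true_efficiencies is None:
            return 1.0
        return float(self.true_efficiencies.get(gene, 1.0))

    def fold_of(self, gene: str, type_: str) -> float:
        if self.fold_changes is None:
            return 1.0
        return float(self.fold_changes.get((gene, type_), 1.0))


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    design: SimulationDesign
    efficiencies: dict[str, float]
    baselines: dict[str, float]
    ref_noise_sds: dict[str, float]
    stability_order: tuple[str, ...]  # most stable first
    fold_changes: dict[tuple[str, str], float]
    loading_offsets: dict[str, float]


def generate_dataset(design: SimulationDesign) -> tuple[CtTable, GroundTruth]:
    """Simulate a Ct table plus its ground truth; fixed seed => identical output.

    For unknown sample ``s`` of type ``T``, gene ``g`` gets

        Ct = B_g - log2(F_{g,T}) / log2(1 + E_g) + L_s + eta / log2(1 + E_g)

    with a per-sample loading offset ``L_s ~ N(0, load_sd)`` shared by every
    gene and per-gene log2-quantity noise ``eta``. Standards follow the
    dilution design with the slope implied by the gene's true E plus Ct
    noise.
    """
    rng = np.random.default_rng(design.seed)
    genes = design.genes
    effs = {g: design.efficiency_of(g) for g in genes}
    baselines = {g: float(b) for g, b in zip(genes, rng.uniform(18.0, 26.0, len(genes)))}
    samples = design.samples
    loads = {s: float(v) for (s, _), v in zip(samples, rng.normal(0.0, design.load_sd, len(samples)))}
    ref_sds = {g: float(sd) for g, sd in zip(design.ref_genes, design.resolved_ref_noise_sds())}

    records: list[CtRecord] = []

    # standard (dilution series) reactions
    grad = design.dilution.grad
    log10_dilut = math.log10(design.dilution.dilut)
    for g in genes:
        slope = -1.0 / math.log10(1.0 + effs[g])
        for level in range(1, grad + 1):
            x = -(level - 1) * log10_dilut
            base_ct = baselines[g] + slope * x
            for rep in range(design.n_standard_replicates):
                ct = base_ct + rng.normal(0.0, design.ct_noise_sd) if design.ct_noise_sd else base_ct
                records.append(
                    CtRecord(
                        gene=g,
                        sample=f"std_r{rep + 1}",
                        type=design.standard_type,
                        serial=level,
                        ct=float(ct),
                        role=ROLE_STANDARD,
                    )
                )

    # unknown reactions
    for g in genes:
        log2_base = math.log2(1.0 + effs[g])
        if g in ref_sds:
            sd_log2 = ref_sds[g]
        else:
            sd_log2 = design.target_noise_sd
        for s, t in samples:
            fold = design.fold_of(g, t)
            ct = baselines[g] - math.log2(fold) / log2_base + loads[s]
            if sd_log2:
                ct += rng.normal(0.0, sd_log2) / log2_base
            if design.ct_noise_sd:
                ct += rng.normal(0.0, design.ct_noise_sd)
            records.append(
                CtRecord(
                    gene=g, sample=s, type=t, serial=1, ct=float(ct), role=ROLE_UNKNOWN
                )
            )

    order = tuple(sorted(design.ref_genes, key=lambda g: (ref_sds[g], g)))
    truth = GroundTruth(
        design=design,
        efficiencies=effs,
        baselines=baselines,
        ref_noise_sds=ref_sds,
        stability_order=order,
        fold_changes={
            (g, t): design.fold_of(g, t)
            for g in design.target_genes
            for t in design.types
            if t != design.control_type
        },
        loading_offsets=loads,
    )
    return CtTable(records), truth


def ground_truth_report(truth: GroundTruth, results: Mapping[str, object]) -> dict:
    """Recovery metrics comparing stage outputs to the designed truth.

    ``results`` may contain any of:

    - ``"efficiencies"``: list of :class:`EfficiencyResult`
    - ``"ranking"``: :class:`StabilityRanking`
    - ``"series"``: :class:`PairwiseVariationSeries` (with ``"optimal_count"``)
    - ``"optimal_count"``: int
    - ``"ratios"``: list of rows with gene/type/ratio attributes

    The report is a plain dict and the function is pure.
    """
    report: dict = {}
    design = truth.design

    eff_results = results.get("efficiencies")
    if eff_results is not None:
        errors = {}
        for r in eff_results:
            if r.gene not in truth.efficiencies:
                raise QpcrError(f"gene {r.gene!r} not part of the simulated design")
            if math.isfinite(r.efficiency):
                errors[r.gene] = abs(r.efficiency - truth.efficiencies[r.gene])
        report["efficiency_abs_error"] = errors
        report["efficiency_mean_abs_error"] = (
            float(np.mean(list(errors.values()))) if errors else math.nan
        )

    ranking = results.get("ranking")
    if ranking is not None:
        unknown = [g for g in ranking.genes if g not in truth.ref_noise_sds]
        if unknown:
            raise QpcrError(f"ranked gene(s) not in simulated references: {unknown}")
        common = [g for g in truth.stability_order if g in ranking.ranks]
        designed = np.arange(1, len(common) + 1)
        recovered = np.array([ranking.ranks[g] for g in common])
        rho = _sps.spearmanr(designed, recovered).statistic
        report["stability_spearman"] = float(rho)

    optimal = results.get("optimal_count")
    if optimal is None and results.get("series") is not None:
        from .optimization import optimal_reference_count

        optimal = optimal_reference_count(results["series"])
    if optimal is not None:
        report["optimal_count"] = int(optimal)

    ratio_rows = results.get("ratios")
    if ratio_rows is not None:
        errors = {}
        for row in ratio_rows:
            key = (row.gene, row.type)
            if key not in truth.fold_changes:
                raise QpcrError(f"ratio row {key} not part of the simulated design")
            errors[key] = abs(
                math.log2(row.ratio) - math.log2(truth.fold_changes[key])
            )
        report["fold_log2_abs_error"] = errors
        report["fold_mean_log2_abs_error"] = (
            float(np.mean(list(errors.values()))) if errors else math.nan
        )
    return report


def null_design(**overrides) -> SimulationDesign:
    """A noiseless design: every recovery metric should be exactly zero."""
    kwargs = {
        "ref_noise_sds": tuple([0.0] * overrides.get("n_ref_genes", 19)),
        "target_noise_sd": 0.0,
        "ct_noise_sd": 0.0,
    }
    kwargs.update(overrides)
    return SimulationDesign(**kwargs)
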