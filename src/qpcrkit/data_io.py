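"""Reading, validating and writing the tabular data flowing between stages.

The sole analytical input is a long-format table of raw threshold-cycle (Ct)
values with five required columns: ``gene``, ``sample``, ``type``, ``serial``
and ``ct``. Standard (dilution-series) reactions are distinguished from
unknown reactions by their ``type`` label (default ``"STD"``); everything
else is an unknown reaction.

Stage results are written as one TSV file per stage, named after the stage
sheet (``Efficiency``, ``M_value``, ``Pairwise_V``, ``Exp_ratio``,
``Exp_R``), or as sheets of a single ``.xlsx`` workbook when requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

CANONICAL_COLUMNS = ("gene", "sample", "type", "serial", "ct")

#: sheet names used for per-stage exports
STAGE_SHEETS = ("Efficiency", "M_value", "Pairwise_V", "Exp_ratio", "Exp_R")

#: instrument-export spellings treated as a missing Ct
MISSING_CT_TOKENS = frozenset(
    {"", "na", "n/a", "nan", "none", "null", "undetermined", "undet", "no ct", "-"}
)

DEFAULT_STANDARD_TYPE = "STD"

ROLE_STANDARD = "standard"
ROLE_UNKNOWN = "unknown"


@dataclass(frozen=True)
class CtRecord:
    """One real-time PCR reaction.

    ``serial`` is the dilution level for standard reactions and the
    technical-replicate index for unknown reactions. ``ct`` is ``None``
    when the instrument reported no amplification.
    """

    gene: str
    sample: str
    type: str
    serial: int
    ct: float | None
    role: str = ROLE_UNKNOWN

    @property
    def is_missing(self) -> bool:
        return self.ct is None or not math.isfinite(self.ct)


@dataclass
class ValidationReport:
    """Row-indexed validation findings. ``ok`` iff there are no errors."""

    errors: list[tuple[int, str, str]] = field(default_factory=list)
    warnings: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add_error(self, row: int, rule: str, message: str) -> None:
        self.errors.append((row, rule, message))

    def add_warning(self, row: int, rule: str, message: str) -> None:
        self.warnings.append((row, rule, message))

    def summary(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        for row, rule, msg in self.errors:
            lines.append(f"  ERROR row {row} [{rule}]: {msg}")
        for row, rule, msg in self.warnings:
            lines.append(f"  warning row {row} [{rule}]: {msg}")
        return "\n".join(lines)


class CtTable:
    """Ordered collection of :class:`CtRecord` with standard/unknown roles."""

    def __init__(self, records: Iterable[CtRecord]):
        self.records: list[CtRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, CtTable) and self.records == other.records

    def __iter__(self):
        return iter(self.records)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, standard_type: str = DEFAULT_STANDARD_TYPE
    ) -> "CtTable":
        """Build from a dataframe with the five canonical columns."""
        records = []
        for row in frame.itertuples(index=False):
            type_ = str(row.type)
            role = ROLE_STANDARD if type_ == standard_type else ROLE_UNKNOWN
            ct = None if pd.isna(row.ct) else float(row.ct)
            records.append(
                CtRecord(
                    gene=str(row.gene),
                    sample=str(row.sample),
                    type=type_,
                    serial=int(row.serial),
                    ct=ct,
                    role=role,
                )
            )
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.records],
                "sample": [r.sample for r in self.records],
                "type": [r.type for r in self.records],
                "serial": [r.serial for r in self.records],
                "ct": [math.nan if r.ct is None else r.ct for r in self.records],
            }
        )

    # -- views ------------------------------------------------------------

    def standards(self) -> "CtTable":
        return CtTable(r for r in self.records if r.role == ROLE_STANDARD)

    def unknowns(self) -> "CtTable":
        return CtTable(r for r in self.records if r.role == ROLE_UNKNOWN)

    @property
    def genes(self) -> list[str]:
        return _unique_in_order(r.gene for r in self.records)

    @property
    def samples(self) -> list[str]:
        return _unique_in_order(r.sample for r in self.records)

    @property
    def types(self) -> list[str]:
        return _unique_in_order(r.type for r in self.records)

    def sample_types(self) -> dict[str, str]:
        """Map sample -> treatment type (first occurrence wins)."""
        out: dict[str, str] = {}
        for r in self.records:
            out.setdefault(r.sample, r.type)
        return out

    # -- replicate handling ------------------------------------------------

    def collapse(self) -> "CtTable":
        """Collapse technical replicates: mean Ct per (gene, sample, serial).

        Missing Ct values are dropped before averaging; a key whose
        replicates are all missing collapses to a single missing record.
        """
        groups: dict[tuple, list[CtRecord]] = {}
        order: list[tuple] = []
        for r in self.records:
            key = (r.gene, r.sample, r.serial)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(r)
        collapsed = []
        for key in order:
            recs = groups[key]
            cts = [r.ct for r in recs if not r.is_missing]
            ct = sum(cts) / len(cts) if cts else None
            first = recs[0]
            collapsed.append(
                CtRecord(first.gene, first.sample, first.type, first.serial, ct, first.role)
            )
        return CtTable(collapsed)

    def mean_ct_by_gene_sample(self) -> pd.DataFrame:
        """Mean Ct of unknown reactions per (gene, sample), missing dropped.

        Returns a tidy frame with columns gene, sample, type, ct.
        """
        rows = [
            (r.gene, r.sample, r.type, r.ct)
            for r in self.records
            if r.role == ROLE_UNKNOWN and not r.is_missing
        ]
        df = pd.DataFrame(rows, columns=["gene", "sample", "type", "ct"])
        if df.empty:
            return df
        return (
            df.groupby(["gene", "sample", "type"], sort=False, as_index=False)["ct"]
            .mean()
        )


def _unique_in_order(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x)
    return list(seen)


# ---------------------------------------------------------------------------
# reading


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".tab", ".txt"):
        return "tsv"
    if suffix in (".xlsx", ".xls"):
        return "xlsx"
    return "csv"


def read_ct_table(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    standard_type: str = DEFAULT_STANDARD_TYPE,
) -> CtTable:
    """Load a long-format Ct table from CSV/TSV (or xlsx).

    Column matching is case-insensitive on the five canonical names;
    ``column_map`` (canonical -> actual column name) overrides. Technical
    replicates are NOT collapsed here. Unparseable serial/Ct cells are
    collected into a :class:`ValidationReport`; any error aborts the load.
    Missing-Ct tokens (e.g. "Undetermined") parse as missing with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif fmt == "tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    elif fmt == "xlsx":
        raw = pd.read_excel(path, dtype=str).fillna("")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    resolved: dict[str, str] = {}
    lower_cols = {c.lower().strip(): c for c in raw.columns}
    for canonical in CANONICAL_COLUMNS:
        if column_map and canonical in column_map:
            actual = column_map[canonical]
            if actual not in raw.columns:
                raise SchemaError(
                    f"mapped column {actual!r} for {canonical!r} not found in {path.name}"
                )
        elif canonical in lower_cols:
            actual = lower_cols[canonical]
        else:
            raise SchemaError(f"missing required column {canonical!r} in {path.name}")
        resolved[canonical] = actual

    report = ValidationReport()
    records: list[CtRecord] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        asdict = dict(zip(raw.columns, row))
        gene = str(asdict[resolved["gene"]]).strip()
        sample = str(asdict[resolved["sample"]]).strip()
        type_ = str(asdict[resolved["type"]]).strip()
        serial_raw = str(asdict[resolved["serial"]]).strip()
        ct_raw = str(asdict[resolved["ct"]]).strip()
        try:
            serial = int(float(serial_raw))
        except ValueError:
            report.add_error(i, "serial_parse", f"unparseable serial {serial_raw!r}")
            continue
        if ct_raw.lower() in MISSING_CT_TOKENS:
            ct: float | None = None
            report.add_warning(i, "missing_ct", f"missing Ct for {gene}/{sample}")
        else:
            try:
                ct = float(ct_raw)
            except ValueError:
                report.add_error(i, "ct_parse", f"unparseable Ct {ct_raw!r}")
                continue
        role = ROLE_STANDARD if type_ == standard_type else ROLE_UNKNOWN
        records.append(CtRecord(gene, sample, type_, serial, ct, role))

    if not report.ok:
        raise ValidationError(
            f"cannot load {path.name}: {report.summary()}", report=report
        )
    return CtTable(records)


# ---------------------------------------------------------------------------
# validation


def validate_ct_table(table: CtTable) -> ValidationReport:
    """Check every table invariant; all problems are reported, never thrown.

    Rules: ``ct_positive`` (finite, > 0 unless flagged missing),
    ``nonempty_fields``, ``serial_min`` (>= 1), ``unique_triple``
    (duplicated (gene, sample, serial) with conflicting type labels cannot
    be collapsed as technical replicates), ``standard_levels`` (a gene with
    standards needs >= 3 distinct usable dilution levels) and the
    ``missing_ct`` warning.
    """
    report = ValidationReport()
    for i, r in enumerate(table.records):
        if r.ct is None:
            report.add_warning(i, "missing_ct", f"missing Ct for {r.gene}/{r.sample}")
        elif not math.isfinite(r.ct) or r.ct <= 0:
            report.add_error(
                i, "ct_positive", f"Ct must be finite and > 0, got {r.ct!r}"
            )
        if not r.gene or not r.sample or not r.type:
            report.add_error(
                i, "nonempty_fields", "gene, sample and type must be non-empty"
            )
        if r.serial < 1:
            report.add_error(i, "serial_min", f"serial must be >= 1, got {r.serial}")

    # duplicated triples are fine as technical replicates (collapsed by mean)
    # unless the labels conflict, which makes the collapse ambiguous
    seen: dict[tuple, tuple[int, CtRecord]] = {}
    for i, r in enumerate(table.records):
        key = (r.gene, r.sample, r.serial)
        if key in seen:
            _, first = seen[key]
            if first.type != r.type or first.role != r.role:
                report.add_error(
                    i,
                    "unique_triple",
                    f"(gene, sample, serial)={key} duplicated with conflicting "
                    f"type {first.type!r} vs {r.type!r}; cannot collapse",
                )
        else:
            seen[key] = (i, r)

    levels: dict[str, set[int]] = {}
    last_row: dict[str, int] = {}
    for i, r in enumerate(table.records):
        if r.role == ROLE_STANDARD and not r.is_missing:
            levels.setdefault(r.gene, set()).add(r.serial)
            last_row[r.gene] = i
    for gene, lv in levels.items():
        if len(lv) < 3:
            report.add_error(
                last_row[gene],
                "standard_levels",
                f"gene {gene!r} has {len(lv)} dilution level(s); "
                "regression needs >= 3",
            )
    return report


# ---------------------------------------------------------------------------
# writing


def stage_output_path(path: str | Path, sheet: str) -> Path:
    """Resolve where a stage sheet lands: ``<dir>/<sheet>.tsv`` or the workbook."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        return path
    return path / f"{sheet}.tsv"


def write_stage_output(rows: pd.DataFrame, path: str | Path, sheet: str) -> Path:
    """Write one stage's result table.

    ``path`` is a directory (one TSV per stage, named after the sheet) or an
    ``.xlsx`` workbook (one sheet per stage). Re-running replaces only that
    sheet/file. Returns the path written.
    """
    if sheet not in STAGE_SHEETS:
        raise ValueError(f"unknown stage sheet {sheet!r}; expected one of {STAGE_SHEETS}")
    if rows is None or len(rows) == 0:
        raise ValueError(f"refusing to write empty table for sheet {sheet!r}")
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        kwargs = {}
        if path.exists():
            kwargs = {"mode": "a", "if_sheet_exists": "replace"}
        with pd.ExcelWriter(path, engine="openpyxl", **kwargs) as writer:
            rows.to_excel(writer, sheet_name=sheet, index=False)
        return path
    path.mkdir(parents=True, exist_ok=True)
    out = path / f"{sheet}.tsv"
    rows.to_csv(out, sep="\t", index=False)
    return out


def read_stage_output(path: str | Path, sheet: str) -> pd.DataFrame:
    """Read back a stage sheet written by :func:`write_stage_output`."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        return pd.read_excel(path, sheet_name=sheet)
    # round_trip parser: written floats must read back bit-identical
    return pd.read_csv(path / f"{sheet}.tsv", sep="\t", float_precision="round_trip")
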