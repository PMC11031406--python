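"""Cohort data model and tabular I/O.

All tables are plain TSV with a fixed, documented dialect.  Mutant allele
frequencies are stored internally as fractions in [0, 1]; the variant table
declares its unit through the column name (``maf_fraction`` vs
``maf_percent``).  Coordinates are 1-based and VCF-style; indels are
left-normalized on ingest by trimming shared allele context.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError


class Material(str, enum.Enum):
    PLASMA = "PLASMA"
    WBC = "WBC"


class Timepoint(str, enum.Enum):
    BASELINE = "BASELINE"
    D14 = "D14"
    POST_ICI = "POST_ICI"
    PREOP = "PREOP"
    POSTOP = "POSTOP"


#: Chronological ordering of plasma timepoints.
TIMEPOINT_ORDER: tuple[Timepoint, ...] = (
    Timepoint.BASELINE,
    Timepoint.D14,
    Timepoint.POST_ICI,
    Timepoint.PREOP,
    Timepoint.POSTOP,
)


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize an allele pair by trimming shared context.

    Trailing shared bases are removed first, then leading shared bases
    (advancing ``pos``), always leaving at least one base on each side.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant within a patient (1-based, VCF-style)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str, gene: str = "") -> "VariantKey":
        pos, ref, alt = _trim_alleles(int(pos), str(ref), str(alt))
        return cls(chrom=str(chrom), pos=pos, ref=ref, alt=alt, gene=str(gene))


@dataclass(frozen=True)
class VariantObservation:
    """One variant seen in one sample."""

    key: VariantKey
    patient_id: str
    sample_id: str
    maf: float
    distinct_coverage: int | None = None
    super_mutant_count: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValidationError(f"maf must lie in [0, 1], got {self.maf}")
        if self.super_mutant_count is not None and self.super_mutant_count < 0:
            raise ValidationError(f"super_mutant_count must be >= 0, got {self.super_mutant_count}")
        if (
            self.super_mutant_count is not None
            and self.distinct_coverage is not None
            and self.super_mutant_count > self.distinct_coverage
        ):
            raise ValidationError(
                f"super_mutant_count {self.super_mutant_count} exceeds "
                f"distinct_coverage {self.distinct_coverage}"
            )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    material: Material
    timepoint: Timepoint
    collection_day: int


@dataclass(frozen=True)
class CosmicAnnotation:
    """Occurrence counts for a variant in a COSMIC-style registry."""

    key: VariantKey
    total_occurrences: int
    heme_lymphoid_occurrences: int

    def __post_init__(self) -> None:
        if self.total_occurrences < 0 or self.heme_lymphoid_occurrences < 0:
            raise ValidationError("occurrence counts must be nonnegative")
        if self.heme_lymphoid_occurrences > self.total_occurrences:
            raise ValidationError(
                f"heme_lymphoid_occurrences {self.heme_lymphoid_occurrences} exceeds "
                f"total_occurrences {self.total_occurrences} for {self.key}"
            )


class CosmicTable:
    """Mapping from variant identity to annotation; unknown keys get (0, 0)."""

    def __init__(self, annotations: Iterable[CosmicAnnotation] = ()) -> None:
        self._by_locus: dict[tuple[str, int, str, str], CosmicAnnotation] = {}
        for ann in annotations:
            self._by_locus[self._locus(ann.key)] = ann

    @staticmethod
    def _locus(key: VariantKey) -> tuple[str, int, str, str]:
        return (key.chrom, key.pos, key.ref, key.alt)

    def lookup(self, key: VariantKey) -> CosmicAnnotation:
        ann = self._by_locus.get(self._locus(key))
        if ann is None:
            return CosmicAnnotation(key=key, total_occurrences=0, heme_lymphoid_occurrences=0)
        return ann

    def __len__(self) -> int:
        return len(self._by_locus)

    def __iter__(self):
        return iter(self._by_locus.values())


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    arm: str
    resected: bool
    rfs_months: float
    rfs_event: bool
    os_months: float
    os_event: bool
    residual_viable_tumor_pct: float | None = None
    pd_l1_cps: float | None = None
    lag3_log2_expression: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("A", "B"):
            raise ValidationError(f"arm must be 'A' or 'B', got {self.arm!r}")
        if self.rfs_months < 0 or self.os_months < 0:
            raise ValidationError("survival times must be nonnegative")
        if self.residual_viable_tumor_pct is not None and not (
            0.0 <= self.residual_viable_tumor_pct <= 100.0
        ):
            raise ValidationError(
                f"residual_viable_tumor_pct must lie in [0, 100], "
                f"got {self.residual_viable_tumor_pct}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = (
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "distinct_coverage",
    "super_mutant_count",
)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return int(float(value))


def read_variant_table(path: str | Path, format_hint: str | None = None) -> list[VariantObservation]:
    """Parse a variant table (TSV dialect, or a single-sample VCF).

    The TSV must carry exactly one MAF column, named ``maf_fraction`` or
    ``maf_percent``; percent values are divided by 100 on ingest.
    """
    path = Path(path)
    fmt = format_hint or ("vcf" if path.suffix.lower() == ".vcf" else "tsv")
    if fmt == "vcf":
        return _read_variant_vcf(path)
    if fmt != "tsv":
        raise SchemaError(f"unknown variant-table format {fmt!r}")

    df = _read_tsv(path)
    _require_columns(df, _VARIANT_COLUMNS, path)
    if "maf_fraction" in df.columns:
        maf_col, scale = "maf_fraction", 1.0
    elif "maf_percent" in df.columns:
        maf_col, scale = "maf_percent", 0.01
    else:
        raise SchemaError(f"{path}: missing mandatory column(s): maf_fraction (or maf_percent)")

    observations: list[VariantObservation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = row._asdict()
        maf = float(rec[maf_col]) * scale
        if not 0.0 <= maf <= 1.0:
            raise ValidationError(f"{path}: line {idx}: maf {maf} outside [0, 1] after conversion")
        key = VariantKey.normalized(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"], rec["gene"])
        observations.append(
            VariantObservation(
                key=key,
                patient_id=str(rec["patient_id"]),
                sample_id=str(rec["sample_id"]),
                maf=maf,
                distinct_coverage=_opt_int(rec["distinct_coverage"]),
                super_mutant_count=_opt_int(rec["super_mutant_count"]),
            )
        )
    return observations


def _read_variant_vcf(path: Path) -> list[VariantObservation]:
    """Minimal single-sample VCF ingest.

    MAF is taken from FORMAT/AF when present, otherwise derived from
    FORMAT/AD as alt / (ref + alt).  DP supplies distinct coverage and the
    optional FORMAT/SMC field the super mutant count.  Sample and patient
    identifiers come from the VCF sample name (``patient:sample`` or a bare
    shared identifier).
    """
    import pysam  # optional dependency, only needed for VCF ingest

    observations: list[VariantObservation] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 1:
            raise SchemaError(f"{path}: VCF ingest expects exactly one sample, found {len(sample_names)}")
        name = sample_names[0]
        patient_id, _, sample_id = name.partition(":")
        sample_id = sample_id or name
        for rec in vcf:
            gene = rec.info.get("GENE", "") if "GENE" in rec.info else ""
            if isinstance(gene, tuple):
                gene = gene[0]
            fmt = rec.samples[name]
            for alt in rec.alts or ():
                if "AF" in fmt and fmt["AF"] is not None:
                    af = fmt["AF"]
                    maf = float(af[0] if isinstance(af, tuple) else af)
                elif "AD" in fmt and fmt["AD"] is not None:
                    ad = fmt["AD"]
                    total = sum(int(x) for x in ad if x is not None)
                    maf = int(ad[1]) / total if total else 0.0
                else:
                    raise SchemaError(f"{path}: neither AF nor AD present for {rec.chrom}:{rec.pos}")
                key = VariantKey.normalized(rec.chrom, rec.pos, rec.ref, alt, gene or "")
                dp = fmt.get("DP")
                smc = fmt.get("SMC") if "SMC" in fmt else None
                observations.append(
                    VariantObservation(
                        key=key,
                        patient_id=patient_id,
                        sample_id=sample_id,
                        maf=maf,
                        distinct_coverage=int(dp) if dp is not None else None,
                        super_mutant_count=int(smc) if smc is not None else None,
                    )
                )
    return observations


def read_sample_manifest(path: str | Path) -> list[SampleRecord]:
    """Parse the sample manifest and enforce per-patient uniqueness rules."""
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ("sample_id", "patient_id", "material", "timepoint", "collection_day"), path)

    records: list[SampleRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            material = Material(rec["material"])
        except ValueError:
            raise SchemaError(f"{path}: line {idx}: unknown material {rec['material']!r}") from None
        try:
            timepoint = Timepoint(rec["timepoint"])
        except ValueError:
            raise SchemaError(f"{path}: line {idx}: unknown timepoint {rec['timepoint']!r}") from None
        records.append(
            SampleRecord(
                sample_id=str(rec["sample_id"]),
                patient_id=str(rec["patient_id"]),
                material=material,
                timepoint=timepoint,
                collection_day=int(float(rec["collection_day"])),
            )
        )

    seen_wbc: set[str] = set()
    seen_plasma: set[tuple[str, Timepoint]] = set()
    sample_ids: set[str] = set()
    for rec in records:
        if rec.sample_id in sample_ids:
            raise ValidationError(f"{path}: duplicate sample_id {rec.sample_id!r}")
        sample_ids.add(rec.sample_id)
        if rec.material is Material.WBC:
            if rec.patient_id in seen_wbc:
                raise ValidationError(f"{path}: patient {rec.patient_id!r} has more than one WBC sample")
            seen_wbc.add(rec.patient_id)
            if rec.timepoint is not Timepoint.BASELINE:
                raise ValidationError(
                    f"{path}: WBC sample {rec.sample_id!r} must carry timepoint BASELINE"
                )
        else:
            k = (rec.patient_id, rec.timepoint)
            if k in seen_plasma:
                raise ValidationError(
                    f"{path}: duplicate plasma timepoint {rec.timepoint.value} "
                    f"for patient {rec.patient_id!r}"
                )
            seen_plasma.add(k)
    return records


def read_cosmic_annotations(path: str | Path) -> CosmicTable:
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ("chrom", "pos", "ref", "alt", "total_occurrences", "heme_lymphoid_occurrences"), path)
    annotations = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        key = VariantKey.normalized(rec["chrom"], int(rec["pos"]), rec["ref"], rec["alt"])
        try:
            annotations.append(
                CosmicAnnotation(
                    key=key,
                    total_occurrences=int(float(rec["total_occurrences"])),
                    heme_lymphoid_occurrences=int(float(rec["heme_lymphoid_occurrences"])),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {idx}: {exc}") from None
    return CosmicTable(annotations)


def _opt_float(value) -> float | None:
    if value is None or pd.isna(value):
        return None
    return float(value)


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(value, path: Path, idx: int, column: str) -> bool:
    try:
        return _BOOL_MAP[str(value).strip().lower()]
    except KeyError:
        raise ValidationError(f"{path}: line {idx}: {column} must be boolean, got {value!r}") from None


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(
        df,
        ("patient_id", "arm", "resected", "rfs_months", "rfs_event", "os_months", "os_event"),
        path,
    )
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        records.append(
            OutcomeRecord(
                patient_id=str(rec["patient_id"]),
                arm=str(rec["arm"]),
                resected=_parse_bool(rec["resected"], path, idx, "resected"),
                rfs_months=float(rec["rfs_months"]),
                rfs_event=_parse_bool(rec["rfs_event"], path, idx, "rfs_event"),
                os_months=float(rec["os_months"]),
                os_event=_parse_bool(rec["os_event"], path, idx, "os_event"),
                residual_viable_tumor_pct=_opt_float(rec.get("residual_viable_tumor_pct")),
                pd_l1_cps=_opt_float(rec.get("pd_l1_cps")),
                lag3_log2_expression=_opt_float(rec.get("lag3_log2_expression")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def variants_to_frame(observations: Iterable[VariantObservation]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": o.patient_id,
            "sample_id": o.sample_id,
            "chrom": o.key.chrom,
            "pos": o.key.pos,
            "ref": o.key.ref,
            "alt": o.key.alt,
            "gene": o.key.gene,
            "maf_fraction": repr(o.maf),
            "distinct_coverage": "" if o.distinct_coverage is None else o.distinct_coverage,
            "super_mutant_count": "" if o.super_mutant_count is None else o.super_mutant_count,
        }
        for o in observations
    ]
    df = pd.DataFrame(rows, columns=[
        "patient_id", "sample_id", "chrom", "pos", "ref", "alt", "gene",
        "maf_fraction", "distinct_coverage", "super_mutant_count",
    ])
    return df.sort_values(
        ["patient_id", "sample_id", "chrom", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)


def write_variant_table(observations: Iterable[VariantObservation], path: str | Path) -> None:
    _write_tsv(variants_to_frame(observations), Path(path))


def write_sample_manifest(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "material": r.material.value,
            "timepoint": r.timepoint.value,
            "collection_day": r.collection_day,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "material", "timepoint", "collection_day"])
    _write_tsv(df.sort_values(["patient_id", "sample_id"], kind="mergesort").reset_index(drop=True), Path(path))


def write_cosmic_table(table: CosmicTable, path: str | Path) -> None:
    rows = [
        {
            "chrom": a.key.chrom,
            "pos": a.key.pos,
            "ref": a.key.ref,
            "alt": a.key.alt,
            "total_occurrences": a.total_occurrences,
            "heme_lymphoid_occurrences": a.heme_lymphoid_occurrences,
        }
        for a in table
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "total_occurrences", "heme_lymphoid_occurrences"])
    _write_tsv(df.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True), Path(path))


def write_outcomes(records: Iterable[OutcomeRecord], path: str | Path) -> None:
    def fmt(v):
        return "" if v is None else repr(v) if isinstance(v, float) else v

    rows = [
        {
            "patient_id": r.patient_id,
            "arm": r.arm,
            "resected": str(r.resected).lower(),
            "residual_viable_tumor_pct": fmt(r.residual_viable_tumor_pct),
            "rfs_months": repr(r.rfs_months),
            "rfs_event": str(r.rfs_event).lower(),
            "os_months": repr(r.os_months),
            "os_event": str(r.os_event).lower(),
            "pd_l1_cps": fmt(r.pd_l1_cps),
            "lag3_log2_expression": fmt(r.lag3_log2_expression),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=[
        "patient_id", "arm", "resected", "residual_viable_tumor_pct",
        "rfs_months", "rfs_event", "os_months", "os_event",
        "pd_l1_cps", "lag3_log2_expression",
    ])
    _write_tsv(df.sort_values("patient_id", kind="mergesort").reset_index(drop=True), Path(path))


def write_results(
    origin_table: pd.DataFrame,
    trajectories: pd.DataFrame,
    outcome_stats: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write pipeline outputs with deterministic column order and row sort.

    Returns a mapping from logical name to written path.  Two calls with
    identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    origins_path = out_dir / "origins.tsv"
    _write_tsv(
        origin_table.sort_values(
            list(origin_table.columns[:5]), kind="mergesort"
        ).reset_index(drop=True)
        if len(origin_table)
        else origin_table,
        origins_path,
    )
    written["origins"] = origins_path

    traj_path = out_dir / "trajectories.tsv"
    _write_tsv(
        trajectories.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
        if len(trajectories)
        else trajectories,
        traj_path,
    )
    written["trajectories"] = traj_path

    for name in sorted(outcome_stats):
        path = out_dir / f"{name}.tsv"
        _write_tsv(outcome_stats[name], path)
        written[name] = path
    return written
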