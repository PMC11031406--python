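"""WBC-informed assignment of plasma variants to germline, clonal
hematopoiesis (CH), or tumor origin.

The decision tree runs per distinct patient-variant, in a fixed order:

1. hotspot annotation — a variant with >= 25 registry occurrences is a
   hotspot; hotspots are never eligible for the germline call;
2. germline rule — a nonhotspot with allele fraction >= 25% in the WBC
   sample and in every assessable plasma sample is germline;
3. blood-evidence bands on the WBC super mutant count ``s`` —
   ``s >= 3`` -> CH; ``s == 0`` -> tumor; ``s in {1, 2}`` -> CH for
   nonhotspots, and for hotspots CH when the hematologic/lymphoid share of
   registry occurrences is >= 10%, tumor otherwise.

Every rule evaluated is recorded in ``rule_path`` for auditability.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EvaluationError
from .io import (
    CosmicAnnotation,
    CosmicTable,
    Material,
    SampleRecord,
    VariantKey,
    VariantObservation,
)

HOTSPOT_MIN_OCCURRENCES = 25
GERMLINE_MIN_VAF = 0.25
CH_MIN_SUPER_MUTANTS = 3
HEME_FRACTION_CUTOFF = 0.10


class Origin(str, enum.Enum):
    GERMLINE = "GERMLINE"
    CH = "CH"
    TUMOR = "TUMOR"


@dataclass(frozen=True)
class HotspotStatus:
    is_hotspot: bool
    total_occurrences: int
    heme_fraction: float


@dataclass(frozen=True)
class OriginCall:
    key: VariantKey
    patient_id: str
    origin: Origin
    hotspot: HotspotStatus
    rule_path: tuple[str, ...]
    wbc_super_mutant_count: int


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable knobs of the decision tree.

    smc_source
        Where the discriminating super mutant count is read from:
        ``"wbc"`` (default) uses the matched WBC sample, ``"max_plasma"``
        the maximum across the patient's plasma samples.
    germline_coverage_floor
        Plasma samples with distinct coverage below this floor are excluded
        from the germline all-samples quantifier, so a dropout sample cannot
        veto an otherwise obvious germline variant.
    """

    smc_source: str = "wbc"
    germline_coverage_floor: int = 10

    def __post_init__(self) -> None:
        if self.smc_source not in ("wbc", "max_plasma"):
            raise ValueError(f"smc_source must be 'wbc' or 'max_plasma', got {self.smc_source!r}")


def annotate_hotspot(annotation: CosmicAnnotation) -> HotspotStatus:
    """Compute hotspot status; the 0/0 occurrence ratio is defined as 0."""
    total = annotation.total_occurrences
    heme_fraction = annotation.heme_lymphoid_occurrences / total if total > 0 else 0.0
    return HotspotStatus(
        is_hotspot=total >= HOTSPOT_MIN_OCCURRENCES,
        total_occurrences=total,
        heme_fraction=heme_fraction,
    )


def apply_germline_rule(
    plasma_observations: Sequence[VariantObservation],
    wbc_observation: VariantObservation | None,
    hotspot: HotspotStatus,
    config: ClassifierConfig = ClassifierConfig(),
) -> bool:
    """True iff the variant matches the germline pattern.

    Requires a nonhotspot with allele fraction >= 25% in the WBC sample and
    in every plasma sample where the locus is assessable (distinct coverage
    at or above the configured floor; samples with unknown coverage count
    as assessable).
    """
    if not plasma_observations:
        raise EvaluationError("germline rule needs at least one plasma observation")
    patient_id = plasma_observations[0].patient_id
    if wbc_observation is None:
        raise EvaluationError(f"no WBC observation available for patient {patient_id!r}")
    if hotspot.is_hotspot:
        return False
    if wbc_observation.maf < GERMLINE_MIN_VAF:
        return False
    assessable = [
        o
        for o in plasma_observations
        if o.distinct_coverage is None or o.distinct_coverage >= config.germline_coverage_floor
    ]
    return all(o.maf >= GERMLINE_MIN_VAF for o in assessable)


def classify_variant(
    plasma_observations: Sequence[VariantObservation],
    wbc_observation: VariantObservation | None,
    annotation: CosmicAnnotation,
    config: ClassifierConfig = ClassifierConfig(),
) -> OriginCall:
    """Assign a single patient-variant its cellular origin.

    ``wbc_observation`` is None when the variant was never seen in the
    matched WBC sample; its super mutant count is then 0 (tumor branch).
    The germline rule still needs the WBC sample to exist for the patient,
    so callers pass a zero-MAF placeholder observation when the WBC sample
    was assayed but the variant not found — see :func:`classify_cohort`.
    """
    if not plasma_observations:
        raise EvaluationError("classify_variant needs at least one plasma observation")
    key = plasma_observations[0].key
    patient_id = plasma_observations[0].patient_id

    rule_path: list[str] = []
    hotspot = annotate_hotspot(annotation)
    rule_path.append("hotspot" if hotspot.is_hotspot else "nonhotspot")

    if config.smc_source == "wbc":
        smc = 0
        if wbc_observation is not None and wbc_observation.super_mutant_count is not None:
            smc = wbc_observation.super_mutant_count
    else:  # max_plasma
        smc = max((o.super_mutant_count or 0 for o in plasma_observations), default=0)

    if hotspot.is_hotspot:
        rule_path.append("germline_rule_skipped_hotspot")
    else:
        if apply_germline_rule(plasma_observations, wbc_observation, hotspot, config):
            rule_path.append("germline_rule_pass")
            return OriginCall(
                key=key,
                patient_id=patient_id,
                origin=Origin.GERMLINE,
                hotspot=hotspot,
                rule_path=tuple(rule_path),
                wbc_super_mutant_count=smc,
            )
        rule_path.append("germline_rule_fail")

    if smc >= CH_MIN_SUPER_MUTANTS:
        rule_path.append("smc_ge3")
        origin = Origin.CH
    elif smc == 0:
        rule_path.append("smc_eq0")
        origin = Origin.TUMOR
    else:  # s in {1, 2}: residual band, resolved by hotspot context
        rule_path.append("smc_1_2")
        if not hotspot.is_hotspot:
            rule_path.append("residual_nonhotspot")
            origin = Origin.CH
        elif hotspot.heme_fraction >= HEME_FRACTION_CUTOFF:
            rule_path.append("residual_hotspot_heme_ge10pct")
            origin = Origin.CH
        else:
            rule_path.append("residual_hotspot_heme_lt10pct")
            origin = Origin.TUMOR

    return OriginCall(
        key=key,
        patient_id=patient_id,
        origin=origin,
        hotspot=hotspot,
        rule_path=tuple(rule_path),
        wbc_super_mutant_count=smc,
    )


@dataclass
class CohortClassification:
    calls: list[OriginCall]
    errors: list[str] = field(default_factory=list)

    @property
    def origin_counts(self) -> Counter:
        return Counter(c.origin for c in self.calls)

    def patients_with_origin(self, origin: Origin) -> set[str]:
        return {c.patient_id for c in self.calls if c.origin is origin}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": c.patient_id,
                "chrom": c.key.chrom,
                "pos": c.key.pos,
                "ref": c.key.ref,
                "alt": c.key.alt,
                "gene": c.key.gene,
                "origin": c.origin.value,
                "is_hotspot": str(c.hotspot.is_hotspot).lower(),
                "total_occurrences": c.hotspot.total_occurrences,
                "heme_fraction": repr(c.hotspot.heme_fraction),
                "wbc_super_mutant_count": c.wbc_super_mutant_count,
                "rule_path": ";".join(c.rule_path),
            }
            for c in self.calls
        ]
        df = pd.DataFrame(rows, columns=[
            "patient_id", "chrom", "pos", "ref", "alt", "gene", "origin",
            "is_hotspot", "total_occurrences", "heme_fraction",
            "wbc_super_mutant_count", "rule_path",
        ])
        return df.sort_values(
            ["patient_id", "chrom", "pos", "ref", "alt"], kind="mergesort"
        ).reset_index(drop=True)

    def summary(self) -> dict[str, int]:
        counts = self.origin_counts
        return {
            "n_variants": len(self.calls),
            "n_germline": counts.get(Origin.GERMLINE, 0),
            "n_ch": counts.get(Origin.CH, 0),
            "n_tumor": counts.get(Origin.TUMOR, 0),
            "n_patients_with_ch": len(self.patients_with_origin(Origin.CH)),
            "n_patients_with_tumor": len(self.patients_with_origin(Origin.TUMOR)),
        }


def classify_cohort(
    observations: Iterable[VariantObservation],
    manifest: Sequence[SampleRecord],
    cosmic: CosmicTable,
    config: ClassifierConfig = ClassifierConfig(),
) -> CohortClassification:
    """Classify every distinct (patient, variant) pair in the cohort.

    Per-variant evaluation errors are collected with the offending keys
    rather than aborting the whole run.
    """
    material_by_sample = {s.sample_id: s.material for s in manifest}
    wbc_sample_by_patient = {
        s.patient_id: s.sample_id for s in manifest if s.material is Material.WBC
    }

    grouped: dict[tuple[str, tuple], dict[str, list[VariantObservation]]] = {}
    for obs in observations:
        gk = (obs.patient_id, (obs.key.chrom, obs.key.pos, obs.key.ref, obs.key.alt))
        bucket = grouped.setdefault(gk, {"plasma": [], "wbc": []})
        material = material_by_sample.get(obs.sample_id)
        if material is None:
            raise EvaluationError(f"sample {obs.sample_id!r} not present in manifest")
        bucket["wbc" if material is Material.WBC else "plasma"].append(obs)

    calls: list[OriginCall] = []
    errors: list[str] = []
    for (patient_id, _), bucket in sorted(grouped.items()):
        plasma = sorted(bucket["plasma"], key=lambda o: o.sample_id)
        if not plasma:
            # variant seen only in WBC: not a plasma variant, nothing to classify
            continue
        key = plasma[0].key
        wbc = bucket["wbc"][0] if bucket["wbc"] else None
        if wbc is None and patient_id in wbc_sample_by_patient:
            # WBC sample assayed but variant absent there: zero-evidence placeholder
            wbc = VariantObservation(
                key=key,
                patient_id=patient_id,
                sample_id=wbc_sample_by_patient[patient_id],
                maf=0.0,
                super_mutant_count=0,
            )
        try:
            calls.append(classify_variant(plasma, wbc, cosmic.lookup(key), config))
        except EvaluationError as exc:
            errors.append(f"{patient_id} {key.chrom}:{key.pos}:{key.ref}>{key.alt}: {exc}")
    return CohortClassification(calls=calls, errors=errors)
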