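"""Per-timepoint ctDNA detection calls, cell-free tumor load, and
clearance/persistence trajectory summaries.

A timepoint is POSITIVE when at least one tumor-origin variant is detected
in that timepoint's plasma sample at any allele fraction, NEGATIVE when the
sample exists but carries no tumor-origin variant, and NOT_ASSESSED when no
plasma sample exists for the timepoint.  Patients with no POSITIVE call at
any assessed timepoint form the undetectable (UD) group and are
nonevaluable for clearance analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import CohortClassification, Origin, OriginCall
from .errors import ValidationError
from .io import (
    Material,
    SampleRecord,
    TIMEPOINT_ORDER,
    Timepoint,
    VariantObservation,
)


class Status(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NOT_ASSESSED = "NOT_ASSESSED"


class Pattern(str, enum.Enum):
    SUSTAINED_CLEARANCE = "SUSTAINED_CLEARANCE"
    CLEARED_POST_ICI = "CLEARED_POST_ICI"
    CLEARED_PREOP = "CLEARED_PREOP"
    CLEARED_POSTOP = "CLEARED_POSTOP"
    PERSISTENT = "PERSISTENT"
    MIXED = "MIXED"
    UD = "UD"


class Evaluability(str, enum.Enum):
    EVALUABLE = "EVALUABLE"
    UD = "UD"


#: How the scalar tumor-burden summary aggregates tumor-variant MAFs.
CFTL_MODES = ("max", "mean")


@dataclass(frozen=True)
class TimepointCall:
    patient_id: str
    timepoint: Timepoint
    status: Status
    n_tumor_variants_detected: int
    cftl: float


@dataclass(frozen=True)
class PatientTrajectory:
    patient_id: str
    calls: tuple[TimepointCall, ...]
    evaluability: Evaluability
    pattern: Pattern

    def call_at(self, timepoint: Timepoint) -> TimepointCall:
        for c in self.calls:
            if c.timepoint is timepoint:
                return c
        return TimepointCall(self.patient_id, timepoint, Status.NOT_ASSESSED, 0, 0.0)

    def status_at(self, timepoint: Timepoint) -> Status:
        return self.call_at(timepoint).status


def _tumor_keys(calls: Iterable[OriginCall], patient_id: str) -> set[tuple]:
    return {
        (c.key.chrom, c.key.pos, c.key.ref, c.key.alt)
        for c in calls
        if c.patient_id == patient_id and c.origin is Origin.TUMOR
    }


def call_timepoint(
    patient_id: str,
    timepoint: Timepoint,
    origin_calls: Sequence[OriginCall],
    observations: Sequence[VariantObservation],
    manifest: Sequence[SampleRecord],
    cftl_mode: str = "max",
) -> TimepointCall:
    """Call ctDNA status for one patient-timepoint.

    Detection requires maf > 0 for a tumor-origin variant in the plasma
    sample of that timepoint; there is no MAF floor.
    """
    if cftl_mode not in CFTL_MODES:
        raise ValidationError(f"cftl_mode must be one of {CFTL_MODES}, got {cftl_mode!r}")
    plasma_sample = next(
        (
            s
            for s in manifest
            if s.patient_id == patient_id
            and s.material is Material.PLASMA
            and s.timepoint is timepoint
        ),
        None,
    )
    if plasma_sample is None:
        return TimepointCall(patient_id, timepoint, Status.NOT_ASSESSED, 0, 0.0)

    tumor_keys = _tumor_keys(origin_calls, patient_id)
    mafs = [
        o.maf
        for o in observations
        if o.sample_id == plasma_sample.sample_id
        and (o.key.chrom, o.key.pos, o.key.ref, o.key.alt) in tumor_keys
        and o.maf > 0
    ]
    n = len(mafs)
    if n == 0:
        return TimepointCall(patient_id, timepoint, Status.NEGATIVE, 0, 0.0)
    cftl = max(mafs) if cftl_mode == "max" else sum(mafs) / n
    return TimepointCall(patient_id, timepoint, Status.POSITIVE, n, cftl)


def classify_evaluability(calls: Sequence[TimepointCall]) -> Evaluability:
    """UD iff no POSITIVE call across assessed timepoints; error when none assessed."""
    assessed = [c for c in calls if c.status is not Status.NOT_ASSESSED]
    if not assessed:
        raise ValidationError(
            f"patient {calls[0].patient_id if calls else '?'}: no assessed timepoints"
        )
    if any(c.status is Status.POSITIVE for c in assessed):
        return Evaluability.EVALUABLE
    return Evaluability.UD


_CLEARANCE_CANDIDATES = (
    (Timepoint.POST_ICI, Pattern.CLEARED_POST_ICI),
    (Timepoint.PREOP, Pattern.CLEARED_PREOP),
    (Timepoint.POSTOP, Pattern.CLEARED_POSTOP),
)


def summarize_clearance(calls: Sequence[TimepointCall]) -> Pattern:
    """Assign the trajectory pattern by precedence.

    UD -> UD; else PERSISTENT when every assessed post-baseline timepoint is
    POSITIVE; else SUSTAINED_CLEARANCE when they are all NEGATIVE; else a
    CLEARED_* label for the earliest timepoint from which every later
    assessed call is NEGATIVE, provided every assessed post-baseline call
    before it is POSITIVE (a monotone clearance; any re-positivity after a
    negative call is MIXED); else MIXED.
    """
    if classify_evaluability(calls) is Evaluability.UD:
        return Pattern.UD
    by_tp = {c.timepoint: c.status for c in calls}
    post_baseline = [
        by_tp.get(tp, Status.NOT_ASSESSED)
        for tp in TIMEPOINT_ORDER
        if tp is not Timepoint.BASELINE
    ]
    assessed = [s for s in post_baseline if s is not Status.NOT_ASSESSED]
    if assessed and all(s is Status.POSITIVE for s in assessed):
        return Pattern.PERSISTENT
    if assessed and all(s is Status.NEGATIVE for s in assessed):
        return Pattern.SUSTAINED_CLEARANCE
    for tp, pattern in _CLEARANCE_CANDIDATES:
        cut = TIMEPOINT_ORDER.index(tp)
        tail = [by_tp.get(t, Status.NOT_ASSESSED) for t in TIMEPOINT_ORDER[cut:]]
        head = [
            by_tp.get(t, Status.NOT_ASSESSED)
            for t in TIMEPOINT_ORDER[1:cut]  # post-baseline calls before the cut
        ]
        tail_assessed = [s for s in tail if s is not Status.NOT_ASSESSED]
        head_assessed = [s for s in head if s is not Status.NOT_ASSESSED]
        if (
            tail_assessed
            and all(s is Status.NEGATIVE for s in tail_assessed)
            and all(s is Status.POSITIVE for s in head_assessed)
        ):
            return pattern
    return Pattern.MIXED


def build_trajectory(
    patient_id: str,
    classification_calls: Sequence[OriginCall],
    observations: Sequence[VariantObservation],
    manifest: Sequence[SampleRecord],
    cftl_mode: str = "max",
) -> PatientTrajectory:
    calls = tuple(
        call_timepoint(patient_id, tp, classification_calls, observations, manifest, cftl_mode)
        for tp in TIMEPOINT_ORDER
    )
    evaluability = classify_evaluability(calls)
    pattern = summarize_clearance(calls)
    return PatientTrajectory(
        patient_id=patient_id, calls=calls, evaluability=evaluability, pattern=pattern
    )


def build_trajectories(
    classification: CohortClassification,
    observations: Sequence[VariantObservation],
    manifest: Sequence[SampleRecord],
    cftl_mode: str = "max",
) -> list[PatientTrajectory]:
    patient_ids = sorted({s.patient_id for s in manifest})
    return [
        build_trajectory(pid, classification.calls, observations, manifest, cftl_mode)
        for pid in patient_ids
    ]


_HEADLINE_TIMEPOINTS = (Timepoint.POST_ICI, Timepoint.PREOP, Timepoint.POSTOP)


def cohort_status_table(trajectories: Sequence[PatientTrajectory]) -> pd.DataFrame:
    """Clearance counts among baseline-positive patients.

    For each of the post-induction, preoperative, and postoperative
    timepoints: how many baseline-positive patients are NEGATIVE there.
    Patients NOT_ASSESSED at the queried timepoint are dropped from that
    denominator.
    """
    baseline_positive = [
        t for t in trajectories if t.status_at(Timepoint.BASELINE) is Status.POSITIVE
    ]
    rows = []
    for tp in _HEADLINE_TIMEPOINTS:
        assessed = [t for t in baseline_positive if t.status_at(tp) is not Status.NOT_ASSESSED]
        n_neg = sum(1 for t in assessed if t.status_at(tp) is Status.NEGATIVE)
        rows.append(
            {
                "timepoint": tp.value,
                "n_baseline_positive": len(baseline_positive),
                "n_assessed": len(assessed),
                "n_undetectable": n_neg,
            }
        )
    return pd.DataFrame(rows, columns=["timepoint", "n_baseline_positive", "n_assessed", "n_undetectable"])


def status_frame(trajectories: Sequence[PatientTrajectory]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "timepoint": c.timepoint.value,
            "status": c.status.value,
            "n_tumor_variants_detected": c.n_tumor_variants_detected,
            "cftl": repr(c.cftl),
        }
        for t in trajectories
        for c in t.calls
    ]
    return pd.DataFrame(rows, columns=["patient_id", "timepoint", "status", "n_tumor_variants_detected", "cftl"])


def trajectory_frame(trajectories: Sequence[PatientTrajectory]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": t.patient_id,
            "evaluability": t.evaluability.value,
            "pattern": t.pattern.value,
            "baseline_status": t.status_at(Timepoint.BASELINE).value,
            "post_ici_status": t.status_at(Timepoint.POST_ICI).value,
            "preop_status": t.status_at(Timepoint.PREOP).value,
            "postop_status": t.status_at(Timepoint.POSTOP).value,
        }
        for t in trajectories
    ]
    return pd.DataFrame(rows, columns=[
        "patient_id", "evaluability", "pattern", "baseline_status",
        "post_ici_status", "preop_status", "postop_status",
    ])


def evaluability_counts(trajectories: Sequence[PatientTrajectory]) -> Mapping[str, int]:
    n_ud = sum(1 for t in trajectories if t.evaluability is Evaluability.UD)
    return {"n_patients": len(trajectories), "n_ud": n_ud, "n_evaluable": len(trajectories) - n_ud}
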