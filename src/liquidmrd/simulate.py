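"""Synthetic trial cohorts with known ground truth.

Generates serial plasma/WBC variant tables, a sample manifest, a
COSMIC-style occurrence table, and clinical outcomes, with planted variant
origins, clearance times, and survival effects:

* germline variants sit near 50% allele fraction in every sample of a
  patient and are never hotspots;
* CH variants are present in the WBC sample with a nonzero super mutant
  count and a stable plasma allele fraction across timepoints;
* tumor variants carry a WBC super mutant count of 0 (or, for a configured
  fraction of hotspot variants, 1-2 with a hematologic occurrence share
  below 10%), with baseline MAF drawn log-uniformly across and below the
  assay sensitivity band and stepping to zero at the patient's clearance
  timepoint for responders;
* recurrence hazard is multiplied by ``hazard_ratio`` for patients who do
  not clear.

Detection applies a per-variant-per-timepoint false-negative rate that
ramps up below the sensitivity band.  The truth tables record planted
origins, planted clearance, and the realized detected/undetected flags so
downstream recovery can be scored without re-deriving anything from the
emitted analysis inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    CosmicAnnotation,
    CosmicTable,
    Material,
    OutcomeRecord,
    SampleRecord,
    TIMEPOINT_ORDER,
    Timepoint,
    VariantKey,
    VariantObservation,
    write_cosmic_table,
    write_outcomes,
    write_sample_manifest,
    write_variant_table,
)

_GENES = (
    "TP53", "KRAS", "PIK3CA", "APC", "ERBB2", "CDKN2A", "SMAD4", "ARID1A",
    "DNMT3A", "TET2", "ASXL1", "JAK2", "SF3B1", "PPM1D", "ATM", "CHEK2",
)

_TP_DAYS = {
    Timepoint.BASELINE: 0,
    Timepoint.D14: 14,
    Timepoint.POST_ICI: 28,
    Timepoint.PREOP: 70,
    Timepoint.POSTOP: 112,
}

_CLEARANCE_CHOICES = (Timepoint.D14, Timepoint.POST_ICI, Timepoint.PREOP, Timepoint.POSTOP)


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 60
    mean_germline_variants: float = 0.4
    mean_ch_variants: float = 0.85
    mean_tumor_variants: float = 1.1
    germline_vaf_mean: float = 0.5
    germline_vaf_sd: float = 0.03
    germline_vaf_bounds: tuple[float, float] = (0.3, 0.7)
    ch_vaf_range: tuple[float, float] = (0.005, 0.2)
    ch_p_smc_ge3: float = 0.8
    ch_hotspot_prob: float = 0.3
    tumor_maf_range: tuple[float, float] = (0.0005, 0.01)
    tumor_hotspot_prob: float = 0.5
    tumor_low_smc_prob: float = 0.15  # hotspot tumor variants with WBC smc 1-2
    p_clear: float = 0.5
    persistent_growth_per_timepoint: float = 1.5  # tumor burden rises when not clearing
    fn_rate_in_band: float = 0.05     # false-negative rate at MAF >= fn_band_maf
    fn_band_maf: float = 0.0025
    fn_rate_floor_maf: float = 0.0005
    fn_rate_at_floor: float = 0.50
    base_median_rfs_months: float = 12.0
    hazard_ratio: float = 3.0
    post_recurrence_mean_months: float = 12.0
    censor_horizon_months: float = 36.0

    def validate(self) -> None:
        for name in ("ch_p_smc_ge3", "ch_hotspot_prob", "tumor_hotspot_prob",
                     "tumor_low_smc_prob", "p_clear", "fn_rate_in_band", "fn_rate_at_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"SimConfig.{name} must lie in [0, 1], got {v}")
        if self.n_patients < 1:
            raise ValidationError("SimConfig.n_patients must be >= 1")
        if self.hazard_ratio <= 0:
            raise ValidationError("SimConfig.hazard_ratio must be > 0")
        if self.persistent_growth_per_timepoint <= 0:
            raise ValidationError("SimConfig.persistent_growth_per_timepoint must be > 0")
        for name in ("mean_germline_variants", "mean_ch_variants", "mean_tumor_variants",
                     "base_median_rfs_months", "post_recurrence_mean_months",
                     "censor_horizon_months"):
            if getattr(self, name) < 0:
                raise ValidationError(f"SimConfig.{name} must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown SimConfig field(s): {', '.join(sorted(unknown))}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        cfg.validate()
        return cfg


@dataclass
class CohortBundle:
    observations: list[VariantObservation]
    manifest: list[SampleRecord]
    cosmic: CosmicTable
    outcomes: list[OutcomeRecord]
    truth_variants: pd.DataFrame
    truth_patients: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": out_dir / "variants.tsv",
            "manifest": out_dir / "manifest.tsv",
            "cosmic": out_dir / "cosmic.tsv",
            "outcomes": out_dir / "outcomes.tsv",
            "truth_variants": out_dir / "truth_variants.tsv",
            "truth_patients": out_dir / "truth_patients.tsv",
        }
        write_variant_table(self.observations, paths["variants"])
        write_sample_manifest(self.manifest, paths["manifest"])
        write_cosmic_table(self.cosmic, paths["cosmic"])
        write_outcomes(self.outcomes, paths["outcomes"])
        self.truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False, lineterminator="\n")
        self.truth_patients.to_csv(paths["truth_patients"], sep="\t", index=False, lineterminator="\n")
        return paths


def _fn_rate(maf: float, config: SimConfig) -> float:
    """Per-variant-per-timepoint miss probability (linear ramp below band)."""
    if maf >= config.fn_band_maf:
        return config.fn_rate_in_band
    if maf <= config.fn_rate_floor_maf:
        return config.fn_rate_at_floor
    frac = (config.fn_band_maf - maf) / (config.fn_band_maf - config.fn_rate_floor_maf)
    return config.fn_rate_in_band + frac * (config.fn_rate_at_floor - config.fn_rate_in_band)


class _KeyFactory:
    """Globally unique variant loci so the occurrence table is unambiguous."""

    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._used: set[tuple[str, int]] = set()

    def new(self) -> VariantKey:
        bases = "ACGT"
        while True:
            chrom = f"chr{self._rng.integers(1, 23)}"
            pos = int(self._rng.integers(10_000, 50_000_000))
            if (chrom, pos) not in self._used:
                self._used.add((chrom, pos))
                break
        ref = bases[self._rng.integers(0, 4)]
        alt_choices = [b for b in bases if b != ref]
        alt = alt_choices[self._rng.integers(0, 3)]
        gene = _GENES[self._rng.integers(0, len(_GENES))]
        return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)


def generate_cohort(config: SimConfig = SimConfig(), seed: int = 0) -> CohortBundle:
    """Generate one synthetic cohort; identical (config, seed) pairs yield
    byte-identical output files."""
    config.validate()
    rng = np.random.default_rng(seed)
    keys = _KeyFactory(rng)

    observations: list[VariantObservation] = []
    manifest: list[SampleRecord] = []
    cosmic_rows: list[CosmicAnnotation] = []
    outcomes: list[OutcomeRecord] = []
    truth_var_rows: list[dict] = []
    truth_pat_rows: list[dict] = []

    base_rate = math.log(2.0) / config.base_median_rfs_months
    horizon = config.censor_horizon_months

    for i in range(config.n_patients):
        pid = f"SYN{i + 1:03d}"
        plasma_ids = {tp: f"{pid}_{tp.value}" for tp in TIMEPOINT_ORDER}
        wbc_id = f"{pid}_WBC"
        for tp in TIMEPOINT_ORDER:
            manifest.append(SampleRecord(plasma_ids[tp], pid, Material.PLASMA, tp, _TP_DAYS[tp]))
        manifest.append(SampleRecord(wbc_id, pid, Material.WBC, Timepoint.BASELINE, 0))

        n_germ = rng.poisson(config.mean_germline_variants)
        n_ch = rng.poisson(config.mean_ch_variants)
        n_tumor = rng.poisson(config.mean_tumor_variants)

        responder = bool(rng.random() < config.p_clear)
        clearance_tp = (
            _CLEARANCE_CHOICES[rng.integers(0, len(_CLEARANCE_CHOICES))] if responder else None
        )
        clearance_idx = (
            TIMEPOINT_ORDER.index(clearance_tp) if clearance_tp is not None else len(TIMEPOINT_ORDER)
        )

        def emit(sample_id: str, key: VariantKey, maf: float, coverage: int, smc: int) -> None:
            observations.append(
                VariantObservation(
                    key=key,
                    patient_id=pid,
                    sample_id=sample_id,
                    maf=round(maf, 6),
                    distinct_coverage=coverage,
                    super_mutant_count=smc,
                )
            )

        # --- germline: ~50% VAF everywhere, never a hotspot -------------
        for _ in range(n_germ):
            key = keys.new()
            cosmic_rows.append(CosmicAnnotation(key, int(rng.integers(0, 5)), 0))
            wbc_vaf = _truncated_normal(rng, config.germline_vaf_mean, config.germline_vaf_sd,
                                        *config.germline_vaf_bounds)
            cov = int(rng.integers(1500, 3000))
            emit(wbc_id, key, wbc_vaf, cov, int(round(wbc_vaf * cov)))
            for tp in TIMEPOINT_ORDER:
                vaf = _truncated_normal(rng, config.germline_vaf_mean, config.germline_vaf_sd,
                                        *config.germline_vaf_bounds)
                cov = int(rng.integers(1500, 3000))
                emit(plasma_ids[tp], key, vaf, cov, int(round(vaf * cov)))
            truth_var_rows.append(_truth_var(pid, key, "GERMLINE"))

        # --- clonal hematopoiesis: in WBC, stable plasma VAF ------------
        for _ in range(n_ch):
            key = keys.new()
            hotspot = rng.random() < config.ch_hotspot_prob
            if hotspot:
                total = int(rng.integers(25, 200))
                heme = int(math.ceil(total * float(rng.uniform(0.10, 0.6))))
                heme = min(heme, total)
            else:
                total = int(rng.integers(0, 25))
                heme = int(rng.integers(0, total + 1)) if total else 0
            cosmic_rows.append(CosmicAnnotation(key, total, heme))
            if rng.random() < config.ch_p_smc_ge3:
                smc = 3 + int(rng.poisson(3.0))
            else:
                smc = int(rng.integers(1, 3))
            vaf0 = float(rng.uniform(*config.ch_vaf_range))
            cov = int(rng.integers(1500, 3000))
            emit(wbc_id, key, vaf0, cov, smc)
            for tp in TIMEPOINT_ORDER:
                vaf = max(1e-4, vaf0 * float(rng.uniform(0.8, 1.2)))
                cov = int(rng.integers(1500, 3000))
                emit(plasma_ids[tp], key, min(vaf, 0.24), cov, smc)
            truth_var_rows.append(_truth_var(pid, key, "CH"))

        # --- tumor: decays to zero at clearance, noisy detection --------
        tumor_detected = {tp: False for tp in TIMEPOINT_ORDER}
        any_tumor_emitted = False
        for _ in range(n_tumor):
            key = keys.new()
            hotspot = rng.random() < config.tumor_hotspot_prob
            if hotspot:
                total = int(rng.integers(25, 500))
                heme = int(math.floor(total * float(rng.uniform(0.0, 0.0999))))
            else:
                total = int(rng.integers(0, 25))
                heme = 0
            cosmic_rows.append(CosmicAnnotation(key, total, heme))
            low, high = config.tumor_maf_range
            maf0 = float(np.exp(rng.uniform(math.log(low), math.log(high))))
            if hotspot and rng.random() < config.tumor_low_smc_prob:
                wbc_smc = int(rng.integers(1, 3))
                emit(wbc_id, key, 1e-4, int(rng.integers(1500, 3000)), wbc_smc)
            emitted_any = False
            growth = 1.0 if responder else config.persistent_growth_per_timepoint
            for idx, tp in enumerate(TIMEPOINT_ORDER):
                if idx >= clearance_idx:
                    continue  # cleared: signal steps to zero
                maf = min(0.2, maf0 * growth**idx * float(rng.uniform(0.7, 1.3)))
                if rng.random() < _fn_rate(maf, config):
                    continue  # missed by the assay
                cov = int(rng.integers(1500, 3000))
                emit(plasma_ids[tp], key, maf, cov, 0)
                tumor_detected[tp] = True
                emitted_any = True
            if emitted_any:
                any_tumor_emitted = True
                truth_var_rows.append(_truth_var(pid, key, "TUMOR"))

        # --- outcomes ---------------------------------------------------
        good_prognosis = responder or n_tumor == 0
        rate = base_rate if good_prognosis else base_rate * config.hazard_ratio
        t_recur = float(rng.exponential(1.0 / rate))
        rfs_event = t_recur <= horizon
        rfs_months = min(t_recur, horizon)
        if rfs_event:
            t_death = t_recur + float(rng.exponential(config.post_recurrence_mean_months))
            os_event = t_death <= horizon
            os_months = min(t_death, horizon)
        else:
            os_event = False
            os_months = horizon
        if good_prognosis:
            residual = float(rng.choice([0.0, 0.0, 5.0, 10.0]))
        else:
            residual = float(rng.choice(np.arange(20.0, 95.0, 5.0)))
        outcomes.append(
            OutcomeRecord(
                patient_id=pid,
                arm="A" if i % 2 == 0 else "B",
                resected=True,
                residual_viable_tumor_pct=residual,
                rfs_months=round(rfs_months, 4),
                rfs_event=rfs_event,
                os_months=round(os_months, 4),
                os_event=os_event,
                pd_l1_cps=float(rng.integers(0, 50)),
            )
        )

        truth_pat_rows.append(
            {
                "patient_id": pid,
                "responder": str(responder).lower(),
                "clearance_timepoint": clearance_tp.value if clearance_tp else "NONE",
                "n_tumor_variants_planted": n_tumor,
                "any_tumor_emitted": str(any_tumor_emitted).lower(),
                "rfs_uncensored_months": round(t_recur, 4),
                **{
                    f"detected_{tp.value.lower()}": str(tumor_detected[tp]).lower()
                    for tp in TIMEPOINT_ORDER
                },
            }
        )

    truth_variants = pd.DataFrame(
        truth_var_rows,
        columns=["patient_id", "chrom", "pos", "ref", "alt", "gene", "true_origin"],
    ).sort_values(["patient_id", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    truth_patients = pd.DataFrame(truth_pat_rows).sort_values("patient_id", kind="mergesort").reset_index(drop=True)

    return CohortBundle(
        observations=observations,
        manifest=manifest,
        cosmic=CosmicTable(cosmic_rows),
        outcomes=outcomes,
        truth_variants=truth_variants,
        truth_patients=truth_patients,
    )


def _truth_var(pid: str, key: VariantKey, origin: str) -> dict:
    return {
        "patient_id": pid,
        "chrom": key.chrom,
        "pos": key.pos,
        "ref": key.ref,
        "alt": key.alt,
        "gene": key.gene,
        "true_origin": origin,
    }
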