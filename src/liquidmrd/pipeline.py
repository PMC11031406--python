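"""End-to-end orchestration: ingest -> classify -> status -> outcomes ->
monitoring, with a run manifest and a Markdown summary report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, classify_cohort
from .errors import ValidationError
from .io import (
    Timepoint,
    read_cosmic_annotations,
    read_outcomes,
    read_sample_manifest,
    read_variant_table,
    write_results,
)
from .monitoring import Direction, MonitoringRule, stopping_boundary
from .stats import SurvivalComparison, comparison_frame, km_frame, survival_by_ctdna
from .status import (
    build_trajectories,
    cohort_status_table,
    evaluability_counts,
    status_frame,
    trajectory_frame,
)

log = logging.getLogger("liquidmrd")

_HEADLINE = (Timepoint.POST_ICI, Timepoint.PREOP, Timepoint.POSTOP)


@dataclass(frozen=True)
class PipelineConfig:
    variants: Path
    manifest: Path
    cosmic: Path
    outcomes: Path | None = None
    out_dir: Path = Path("liquidmrd_out")
    smc_source: str = "wbc"
    germline_coverage_floor: int = 10
    cftl_mode: str = "max"
    endpoints: tuple[str, ...] = ("RFS", "OS")
    monitoring_rules: tuple[MonitoringRule, ...] = ()
    monitoring_n_max: int = 32
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rules = tuple(
            MonitoringRule(
                prior_a=float(r["prior_a"]),
                prior_b=float(r["prior_b"]),
                rate_threshold=float(r["rate_threshold"]),
                posterior_trigger=float(r["posterior_trigger"]),
                direction=Direction(r.get("direction", "ABOVE")),
                name=str(r.get("name", "")),
            )
            for r in raw.pop("monitoring_rules", [])
        )
        kwargs: dict[str, Any] = {}
        for key in ("variants", "manifest", "cosmic", "outcomes", "out_dir"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        for key in ("smc_source", "cftl_mode"):
            if key in raw:
                kwargs[key] = str(raw.pop(key))
        for key in ("germline_coverage_floor", "monitoring_n_max", "seed"):
            if key in raw:
                kwargs[key] = int(raw.pop(key))
        if "endpoints" in raw:
            kwargs["endpoints"] = tuple(raw.pop("endpoints"))
        if raw:
            raise ValidationError(f"unknown pipeline config field(s): {', '.join(sorted(raw))}")
        return cls(monitoring_rules=rules, **kwargs)

    def validate(self) -> None:
        for name in ("variants", "manifest", "cosmic"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"input path for {name!r} does not exist: {p}")
        if self.outcomes is not None and not Path(self.outcomes).exists():
            raise ValidationError(f"input path for 'outcomes' does not exist: {self.outcomes}")
        for ep in self.endpoints:
            if ep not in ("RFS", "OS"):
                raise ValidationError(f"unknown endpoint {ep!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    origin_summary: dict
    evaluability: Mapping[str, int]
    status_table: pd.DataFrame
    comparisons: list[SurvivalComparison] = field(default_factory=list)
    written: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("stage=ingest variants=%s", config.variants)
    observations = read_variant_table(config.variants)
    manifest = read_sample_manifest(config.manifest)
    cosmic = read_cosmic_annotations(config.cosmic)
    outcomes = read_outcomes(config.outcomes) if config.outcomes else []
    log.info(
        "stage=ingest rows_variants=%d rows_manifest=%d rows_cosmic=%d rows_outcomes=%d",
        len(observations), len(manifest), len(cosmic), len(outcomes),
    )

    classifier_cfg = ClassifierConfig(
        smc_source=config.smc_source,
        germline_coverage_floor=config.germline_coverage_floor,
    )
    classification = classify_cohort(observations, manifest, cosmic, classifier_cfg)
    if classification.errors:
        raise ValidationError(
            "stage=classify failed for: " + "; ".join(classification.errors)
        )
    log.info("stage=classify %s", classification.summary())

    trajectories = build_trajectories(classification, observations, manifest, config.cftl_mode)
    status_tbl = cohort_status_table(trajectories)
    log.info("stage=status %s", evaluability_counts(trajectories))

    comparisons: list[SurvivalComparison] = []
    extra_tables: dict[str, pd.DataFrame] = {
        "status": status_frame(trajectories),
        "clearance_counts": status_tbl,
    }
    if outcomes:
        for tp in _HEADLINE:
            for ep in config.endpoints:
                for three_way in (False, True):
                    cmp_ = survival_by_ctdna(trajectories, outcomes, tp, ep, three_way=three_way)
                    comparisons.append(cmp_)
        extra_tables["survival_comparisons"] = comparison_frame(comparisons)
        for cmp_ in comparisons:
            for lab, curve in cmp_.groups.items():
                name = f"km_{cmp_.endpoint.lower()}_{cmp_.timepoint.value.lower()}_{lab.lower()}"
                extra_tables[name] = km_frame(curve)

    for i, rule in enumerate(config.monitoring_rules):
        name = rule.name or f"rule{i + 1}"
        extra_tables[f"boundary_{name}"] = stopping_boundary(rule, config.monitoring_n_max)

    written = write_results(
        classification.to_frame(), trajectory_frame(trajectories), extra_tables, out_dir
    )

    result = PipelineResult(
        origin_summary=classification.summary(),
        evaluability=evaluability_counts(trajectories),
        status_table=status_tbl,
        comparisons=comparisons,
        written=written,
    )
    _write_run_manifest(config, result, out_dir)
    _write_report(result, out_dir)
    return result


def _write_run_manifest(config: PipelineConfig, result: PipelineResult, out_dir: Path) -> None:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "origin_summary": result.origin_summary,
        "evaluability": dict(result.evaluability),
        "outputs": {k: str(v) for k, v in sorted(result.written.items())},
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_report(result: PipelineResult, out_dir: Path) -> None:
    lines = ["# liquidmrd report", ""]
    s = result.origin_summary
    lines += [
        "## Variant origins",
        "",
        f"- distinct patient-variants: {s['n_variants']}",
        f"- germline: {s['n_germline']}, CH: {s['n_ch']}, tumor: {s['n_tumor']}",
        f"- patients with >=1 CH variant: {s['n_patients_with_ch']}",
        f"- patients with >=1 tumor variant: {s['n_patients_with_tumor']}",
        "",
        "## Evaluability",
        "",
        f"- patients: {result.evaluability['n_patients']}, "
        f"evaluable: {result.evaluability['n_evaluable']}, UD: {result.evaluability['n_ud']}",
        "",
        "## Clearance among baseline-positive patients",
        "",
        result.status_table.to_string(index=False),
        "",
    ]
    if result.comparisons:
        lines += ["## Survival comparisons", ""]
        for cmp_ in result.comparisons:
            med = {
                lab: ("NR" if c.median is None else f"{c.median:.2f}")
                for lab, c in cmp_.groups.items()
            }
            p = "n/a" if cmp_.logrank is None else f"{cmp_.logrank.p_value:.4f}"
            lines.append(
                f"- {cmp_.endpoint} at {cmp_.timepoint.value} "
                f"({'/'.join(sorted(cmp_.groups))}): medians {med}, log-rank p={p}"
            )
        lines.append("")
    (out_dir / "report.md").write_text("\n".join(lines))
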