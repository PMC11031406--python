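"""Trial outcome statistics.

Pathological regression grading, Kaplan-Meier estimation with Greenwood
variance and complementary log-log confidence bounds, the k-sample log-rank
test, exact (Clopper-Pearson) binomial confidence intervals, Fisher's exact
test, the Wilcoxon rank-sum test, and survival comparisons grouped by
ctDNA detection status.

All tests are two-sided.  Median survival is reported as ``None``
(NOT_REACHED) when the survival curve never drops to 0.5 or below.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import OutcomeRecord, Timepoint
from .status import Evaluability, PatientTrajectory, Status

DAYS_PER_MONTH = 30.4375


def months_from_days(days: float) -> float:
    return days / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# pathological response
# ---------------------------------------------------------------------------


class CapGrade(str, enum.Enum):
    G0 = "G0"
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"


@dataclass(frozen=True)
class PathResponse:
    residual_viable_tumor_pct: float
    cap_grade: CapGrade
    pcr: bool
    mpr: bool


def grade_regression(residual_viable_tumor_pct: float) -> PathResponse:
    """Map % residual viable tumor onto the four-level regression grade.

    0% -> G0 (complete response), (0, 10] -> G1, (10, 50] -> G2,
    (50, 100] -> G3.  pCR is G0; MPR is residual <= 10%.  Boundary values
    (exactly 10, exactly 50) fall in the lower-numbered band.
    """
    pct = float(residual_viable_tumor_pct)
    if not 0.0 <= pct <= 100.0:
        raise ValidationError(f"residual viable tumor % must lie in [0, 100], got {pct}")
    if pct == 0.0:
        grade = CapGrade.G0
    elif pct <= 10.0:
        grade = CapGrade.G1
    elif pct <= 50.0:
        grade = CapGrade.G2
    else:
        grade = CapGrade.G3
    return PathResponse(
        residual_viable_tumor_pct=pct,
        cap_grade=grade,
        pcr=grade is CapGrade.G0,
        mpr=pct <= 10.0,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KmCurve:
    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float | None  # None encodes NOT_REACHED

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(
    times: Sequence[float], events: Sequence[bool], conf: float = 0.95
) -> KmCurve:
    """Product-limit estimate with Greenwood variance and log-log CI.

    The pointwise interval applies the complementary log-log transform:
    bounds are S(t) ** exp(-/+ z * se(log(-log S(t)))) with the delta-method
    standard error on the transformed scale.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("km_estimate needs at least one subject")
    if np.any(t < 0):
        raise ValidationError("negative survival time")
    if t.shape != e.shape:
        raise ValidationError("times and events must have equal length")

    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = t.size

    event_times: list[float] = []
    at_risk: list[int] = []
    d_list: list[int] = []
    survival: list[float] = []
    greenwood_terms: list[float] = []
    lower: list[float] = []
    upper: list[float] = []

    s = 1.0
    gw = 0.0  # running sum d / (n (n - d))
    z = sps.norm.ppf(0.5 + conf / 2.0)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        n_at_risk = n - i
        if d > 0:
            s *= 1.0 - d / n_at_risk
            if n_at_risk > d:
                gw += d / (n_at_risk * (n_at_risk - d))
            event_times.append(float(t[i]))
            at_risk.append(n_at_risk)
            d_list.append(d)
            survival.append(s)
            greenwood_terms.append(gw)
            if 0.0 < s < 1.0:
                se_loglog = math.sqrt(gw) / abs(math.log(s))
                lower.append(s ** math.exp(z * se_loglog))
                upper.append(s ** math.exp(-z * se_loglog))
            else:
                lower.append(s)
                upper.append(s)
        i = j

    surv_arr = np.asarray(survival)
    median: float | None = None
    for tt, ss in zip(event_times, survival):
        if ss <= 0.5:
            median = tt
            break
    return KmCurve(
        event_times=np.asarray(event_times),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(d_list, dtype=int),
        survival=surv_arr,
        ci_lower=np.asarray(lower),
        ci_upper=np.asarray(upper),
        median=median,
    )


def km_frame(curve: KmCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "at_risk": curve.at_risk,
            "events": curve.events,
            "survival": curve.survival,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    df: int


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> LogrankResult:
    """Unweighted k-sample log-rank test with the hypergeometric tie
    correction; two-sided p from chi-square with k - 1 df."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if not (t.size == e.size == g.size):
        raise ValidationError("times, events, groups must have equal length")
    labels = np.unique(g)
    k = labels.size
    if k < 2:
        raise ValidationError("logrank_test needs at least two groups")
    for lab in labels:
        if not np.any(g == lab):
            raise ValidationError(f"group {lab!r} has zero subjects")

    group_idx = np.searchsorted(labels, g)
    event_times = np.unique(t[e])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for tj in event_times:
        at_risk_mask = t >= tj
        nj = int(at_risk_mask.sum())
        if nj == 0:
            continue
        dj_mask = (t == tj) & e
        dj = int(dj_mask.sum())
        nij = np.bincount(group_idx[at_risk_mask], minlength=k).astype(float)
        dij = np.bincount(group_idx[dj_mask], minlength=k).astype(float)
        observed += dij
        expected += dj * nij / nj
        if nj > 1:
            frac = nij / nj
            scale = dj * (nj - dj) / (nj - 1)
            cov += scale * (np.diag(frac) - np.outer(frac, frac))

    z = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(v) @ z)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return LogrankResult(chi_square=chi2, p_value=p, df=k - 1)


# ---------------------------------------------------------------------------
# exact tests and intervals
# ---------------------------------------------------------------------------


def exact_binomial_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval by beta-quantile inversion, as fractions."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValidationError(f"x must lie in [0, n], got x={x}, n={n}")
    alpha = 1.0 - conf
    lower = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(sps.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities no
    larger than that of the observed table (with a relative tolerance for
    floating-point ties, as in the conventional implementations)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("fisher_exact_2x2 expects a 2x2 table")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValidationError("table cells must be nonnegative integers")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValidationError("degenerate table: all cells zero")
    row1, col1 = a + b, a + c
    support_lo = max(0, row1 + col1 - n)
    support_hi = min(row1, col1)
    xs = np.arange(support_lo, support_hi + 1)
    pmf = sps.hypergeom.pmf(xs, n, col1, row1)
    p_obs = sps.hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


WILCOXON_EXACT_MAX_N = 20  # combined-sample switch to the normal approximation


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when the combined sample is small (n <= 20) and tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction is used.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= WILCOXON_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# survival grouped by ctDNA status
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalComparison:
    timepoint: Timepoint
    endpoint: str
    groups: Mapping[str, KmCurve]
    group_sizes: Mapping[str, int]
    logrank: LogrankResult | None
    warning: str | None = None


def survival_by_ctdna(
    trajectories: Sequence[PatientTrajectory],
    outcomes: Sequence[OutcomeRecord],
    timepoint: Timepoint,
    endpoint: str = "RFS",
    three_way: bool = False,
) -> SurvivalComparison:
    """Compare survival between patients detected vs undetected at a
    timepoint; with ``three_way`` the UD patients form their own stratum
    instead of being excluded."""
    if endpoint not in ("RFS", "OS"):
        raise ValidationError(f"endpoint must be 'RFS' or 'OS', got {endpoint!r}")
    outcome_by_patient = {o.patient_id: o for o in outcomes}

    def endpoint_of(rec: OutcomeRecord) -> tuple[float, bool]:
        if endpoint == "RFS":
            return rec.rfs_months, rec.rfs_event
        return rec.os_months, rec.os_event

    times: list[float] = []
    events: list[bool] = []
    labels: list[str] = []
    for traj in trajectories:
        rec = outcome_by_patient.get(traj.patient_id)
        if rec is None:
            continue
        if traj.evaluability is Evaluability.UD:
            if not three_way:
                continue
            label = "UD"
        else:
            status = traj.status_at(timepoint)
            if status is Status.NOT_ASSESSED:
                continue
            label = "DETECTED" if status is Status.POSITIVE else "UNDETECTED"
        tt, ev = endpoint_of(rec)
        times.append(tt)
        events.append(ev)
        labels.append(label)

    present = sorted(set(labels))
    groups = {
        lab: km_estimate(
            [t for t, l in zip(times, labels) if l == lab],
            [e for e, l in zip(events, labels) if l == lab],
        )
        for lab in present
    }
    sizes = {lab: labels.count(lab) for lab in present}
    if len(present) < 2:
        return SurvivalComparison(
            timepoint=timepoint,
            endpoint=endpoint,
            groups=groups,
            group_sizes=sizes,
            logrank=None,
            warning="fewer than two nonempty groups; comparison skipped",
        )
    return SurvivalComparison(
        timepoint=timepoint,
        endpoint=endpoint,
        groups=groups,
        group_sizes=sizes,
        logrank=logrank_test(times, events, labels),
    )


def comparison_frame(comparisons: Sequence[SurvivalComparison]) -> pd.DataFrame:
    rows = []
    for cmp_ in comparisons:
        for lab in sorted(cmp_.groups):
            curve = cmp_.groups[lab]
            rows.append(
                {
                    "timepoint": cmp_.timepoint.value,
                    "endpoint": cmp_.endpoint,
                    "group": lab,
                    "n": cmp_.group_sizes[lab],
                    "median": "NOT_REACHED" if curve.median is None else repr(curve.median),
                    "logrank_p": "" if cmp_.logrank is None else repr(cmp_.logrank.p_value),
                }
            )
    return pd.DataFrame(rows, columns=["timepoint", "endpoint", "group", "n", "median", "logrank_p"])
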