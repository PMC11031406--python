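"""Bayesian beta-binomial safety and feasibility monitoring.

A monitoring rule triggers when the posterior probability that the true
event rate exceeds (or, for BELOW-direction feasibility rules, falls short
of) a threshold reaches the configured trigger level.  Priors are
calibrated from a stated prior mean and a stated tail probability on the
one-parameter family b = a (1 - mean) / mean.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import CalibrationError, ValidationError


class Direction(str, enum.Enum):
    ABOVE = "ABOVE"
    BELOW = "BELOW"


@dataclass(frozen=True)
class MonitoringRule:
    prior_a: float
    prior_b: float
    rate_threshold: float
    posterior_trigger: float
    direction: Direction = Direction.ABOVE
    name: str = ""

    def __post_init__(self) -> None:
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValidationError("beta hyperparameters must be positive")
        if not 0 < self.rate_threshold < 1:
            raise ValidationError("rate_threshold must lie in (0, 1)")
        if not 0 < self.posterior_trigger < 1:
            raise ValidationError("posterior_trigger must lie in (0, 1)")


@dataclass(frozen=True)
class CalibratedPrior:
    """Raw numerical solution plus an integer-snapped version when one is
    within tolerance of the stated tail probability."""

    a: float
    b: float
    a_raw: float
    b_raw: float
    tail_prob: float  # direct beta tail at the returned (a, b)
    snapped: bool


_CAL_BRACKET = (1e-3, 1e3)
_SNAP_TOL = 0.02


def calibrate_beta_prior(
    prior_mean: float,
    tail_point: float,
    tail_prob: float,
    snap_integer: bool = True,
) -> CalibratedPrior:
    """Solve for Beta(a, b) with a/(a+b) = prior_mean and
    P(p >= tail_point) = tail_prob.

    The search runs over a alone with b = a (1 - mean) / mean, so the mean
    constraint holds exactly.  The tail is not monotone in a, so sign
    changes are located on a logarithmic grid and each bracketed root is
    refined; when several roots exist the largest (most concentrated prior)
    is returned.  When the problem is degenerate (the tail is flat in a,
    e.g. mean 0.5 with tail_point 0.5 and tail_prob 0.5), the unit-scale
    solution a = 1 is returned.  With ``snap_integer``, nearest integer
    hyperparameters on the same mean line are reported instead whenever
    their direct tail evaluation is within 0.02 of the stated probability.
    """
    for nm, v in (("prior_mean", prior_mean), ("tail_point", tail_point), ("tail_prob", tail_prob)):
        if not 0.0 < v < 1.0:
            raise ValidationError(f"{nm} must lie in (0, 1), got {v}")
    ratio = (1.0 - prior_mean) / prior_mean

    def tail(a: float) -> float:
        return float(sps.beta.sf(tail_point, a, a * ratio))

    def f(a: float) -> float:
        return tail(a) - tail_prob

    lo, hi = _CAL_BRACKET
    grid = np.logspace(np.log10(lo), np.log10(hi), 601)
    fg = np.array([f(a) for a in grid])
    if np.all(np.abs(fg) < 1e-9):  # flat/degenerate family: fix the scale at a = 1
        a_raw = 1.0
    else:
        roots: list[float] = []
        for a0, a1, f0, f1 in zip(grid[:-1], grid[1:], fg[:-1], fg[1:]):
            if f0 == 0.0:
                roots.append(float(a0))
            elif f0 * f1 < 0:
                roots.append(float(optimize.brentq(f, a0, a1, xtol=1e-12, rtol=8.9e-16)))
        if fg[-1] == 0.0:
            roots.append(float(grid[-1]))
        if not roots:
            raise CalibrationError(
                f"no root for a in ({lo}, {hi}): tail range "
                f"[{fg.min() + tail_prob:.4g}, {fg.max() + tail_prob:.4g}], target {tail_prob}"
            )
        a_raw = max(roots)
    b_raw = a_raw * ratio

    a_out, b_out, snapped = a_raw, b_raw, False
    if snap_integer:
        best_err = _SNAP_TOL
        for a_int in {int(np.floor(a_raw)), int(np.ceil(a_raw))}:
            if a_int < 1:
                continue
            b_exact = a_int * ratio
            b_int = round(b_exact)
            if b_int < 1 or abs(b_exact - b_int) > 1e-9:  # mean not preserved
                continue
            err = abs(float(sps.beta.sf(tail_point, a_int, b_int)) - tail_prob)
            if err <= best_err:
                a_out, b_out, snapped = float(a_int), float(b_int), True
                best_err = err
    return CalibratedPrior(
        a=a_out,
        b=b_out,
        a_raw=a_raw,
        b_raw=b_raw,
        tail_prob=float(sps.beta.sf(tail_point, a_out, b_out)),
        snapped=snapped,
    )


@dataclass(frozen=True)
class ExceedanceResult:
    probability: float
    trigger: bool
    posterior_a: float
    posterior_b: float


def posterior_exceedance(rule: MonitoringRule, x_events: int, n_patients: int) -> ExceedanceResult:
    """Posterior probability that the rate lies past the threshold, and
    whether the rule triggers."""
    if n_patients < 0 or x_events < 0 or x_events > n_patients:
        raise ValidationError(f"need 0 <= x <= n, got x={x_events}, n={n_patients}")
    a = rule.prior_a + x_events
    b = rule.prior_b + n_patients - x_events
    p_above = float(sps.beta.sf(rule.rate_threshold, a, b))
    prob = p_above if rule.direction is Direction.ABOVE else 1.0 - p_above
    return ExceedanceResult(
        probability=prob,
        trigger=prob >= rule.posterior_trigger,
        posterior_a=a,
        posterior_b=b,
    )


def stopping_boundary(rule: MonitoringRule, n_max: int) -> pd.DataFrame:
    """Minimal triggering event count per enrolled n (ABOVE direction).

    For each n in 1..n_max, the smallest x with a triggered rule, or no
    value when no x in 0..n triggers.  The boundary is non-decreasing in n.
    """
    if n_max < 1:
        raise ValidationError("n_max must be >= 1")
    rows = []
    prev_min = 0
    for n in range(1, n_max + 1):
        found: int | None = None
        for x in range(prev_min, n + 1):  # monotone in n: start from last boundary
            res = posterior_exceedance(rule, x, n)
            if res.trigger:
                found = x
                break
        if found is not None:
            prev_min = found
            posterior = posterior_exceedance(rule, found, n).probability
            rows.append({"n": n, "min_trigger_events": found, "posterior_at_boundary": posterior})
        else:
            rows.append({"n": n, "min_trigger_events": np.nan, "posterior_at_boundary": np.nan})
    return pd.DataFrame(rows, columns=["n", "min_trigger_events", "posterior_at_boundary"])
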