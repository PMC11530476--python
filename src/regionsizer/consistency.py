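"""Per-replicate consistency criteria and their Monte-Carlo aggregation.

A region is "consistent" in a replicate when its estimated effect preserves
at least a fraction pi of the overall estimated effect.  The ratio criteria
are evaluated literally as stated (no algebraic rearrangement): with a
near-null or harmful overall estimate the ratio flips sign, and rearranging
would silently change the semantics.  Replicates whose ratio denominator is
zero are not evaluable; they are excluded from the probability denominators
and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import Direction

NOT_EVALUABLE = None  # tri-state criterion outcome


def superiority_criterion(
    theta_region: float, theta_all: float, pi: float
) -> bool:
    """Strict preservation inequality theta_R > pi * theta_All on the
    beneficially oriented scale."""
    return theta_region > pi * theta_all


def tte_criteria(
    hr_region: float, hr_all: float, pi: float
) -> tuple[Optional[bool], Optional[bool]]:
    """Superiority consistency for hazard ratios, both conventions:

    (1) log-hazard-ratio ratio: log(HR_R) / log(HR_All) > pi
    (2) risk-reduction ratio:   (1 - HR_R) / (1 - HR_All) > pi

    ``None`` marks a not-evaluable criterion (zero denominator, i.e.
    HR_All = 1 exactly, or an undefined estimate).
    """
    if not (np.isfinite(hr_region) and np.isfinite(hr_all)) or hr_region <= 0 or hr_all <= 0:
        return NOT_EVALUABLE, NOT_EVALUABLE
    log_all = math.log(hr_all)
    loghr_ok = (
        NOT_EVALUABLE if log_all == 0.0 else math.log(hr_region) / log_all > pi
    )
    riskred_ok = (
        NOT_EVALUABLE
        if hr_all == 1.0
        else (1.0 - hr_region) / (1.0 - hr_all) > pi
    )
    return loghr_ok, riskred_ok


def ni_criterion(
    theta_region: float,
    theta_all: float,
    margin: float,
    direction: Direction,
    pi: float,
) -> Optional[bool]:
    """Non-inferiority consistency on the raw effect scale:
    (theta_R - margin)/(theta_All - margin) > pi when higher is worse,
    (theta_R + margin)/(theta_All + margin) > pi when higher is better."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    shift = -margin if direction == Direction.higher_worse else margin
    denom = theta_all + shift
    if denom == 0.0 or not np.isfinite(denom):
        return NOT_EVALUABLE
    return (theta_region + shift) / denom > pi


def ni_tte_criteria(
    hr_region: float, hr_all: float, margin: float, pi: float
) -> tuple[Optional[bool], Optional[bool]]:
    """Margin-shifted hazard-ratio consistency for non-inferiority:

    (1) (log HR_R - log margin) / (log HR_All - log margin) > pi
    (2) (1 - HR_R / margin) / (1 - HR_All / margin) > pi
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    if not (np.isfinite(hr_region) and np.isfinite(hr_all)) or hr_region <= 0 or hr_all <= 0:
        return NOT_EVALUABLE, NOT_EVALUABLE
    log_denom = math.log(hr_all) - math.log(margin)
    loghr_ok = (
        NOT_EVALUABLE
        if log_denom == 0.0
        else (math.log(hr_region) - math.log(margin)) / log_denom > pi
    )
    rr_denom = 1.0 - hr_all / margin
    riskred_ok = (
        NOT_EVALUABLE
        if rr_denom == 0.0
        else (1.0 - hr_region / margin) / rr_denom > pi
    )
    return loghr_ok, riskred_ok


@dataclass
class ConsistencyRow:
    """One row of the result table: Monte-Carlo estimates for one
    subpopulation percentage."""

    subpop_pct: float
    n_region: int
    power: float
    uncond_prob: Optional[float]
    cond_prob: Optional[float]
    n_sims: int
    n_not_evaluable: int = 0
    # second criterion pair (TTE risk-reduction convention)
    uncond_prob_alt: Optional[float] = None
    cond_prob_alt: Optional[float] = None
    n_not_evaluable_alt: Optional[int] = None
    # binary-endpoint diagnostics
    low_cell_count_all: Optional[int] = None
    low_cell_count_region: Optional[int] = None
    # TTE duration summaries (means over replicates)
    mean_time_to_target_events: Optional[float] = None
    mean_median_duration_global: Optional[float] = None
    mean_median_duration_region: Optional[float] = None
    extras: dict = field(default_factory=dict)


def aggregate_probabilities(
    criteria: Sequence[Optional[bool]], significant: Sequence[bool]
) -> tuple[Optional[float], Optional[float], int]:
    """Monte-Carlo probabilities from per-replicate outcomes.

    unconditional = #(C) / #evaluable; conditional = #(C and S) /
    #(S and evaluable), missing (``None``) when no evaluable replicate is
    significant.  Returns (uncond, cond, n_not_evaluable)."""
    crit = list(criteria)
    sig = list(significant)
    if len(crit) != len(sig):
        raise ValueError("criteria and significance sequences differ in length")
    evaluable = [c is not NOT_EVALUABLE for c in crit]
    n_eval = sum(evaluable)
    n_ne = len(crit) - n_eval
    if n_eval == 0:
        return None, None, n_ne
    n_c = sum(bool(c) for c in crit if c is not NOT_EVALUABLE)
    n_s_eval = sum(s for s, e in zip(sig, evaluable) if e)
    n_cs = sum(
        bool(c) and s for c, s, e in zip(crit, sig, evaluable) if e
    )
    uncond = n_c / n_eval
    cond = n_cs / n_s_eval if n_s_eval > 0 else None
    return uncond, cond, n_ne
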