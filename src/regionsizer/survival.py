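"""Time-to-event machinery: hazard-scale conversions, accrual scheduling,
exponential event-time simulation, the event-driven analysis cutoff,
administrative censoring, and follow-up duration summaries.

The survival model is exponential in both arms (proportional hazards with a
constant baseline): the design is parameterized only by the control arm's
median survival or yearly event rate plus a hazard ratio, which pins down
exactly this model.  There is no loss to follow-up; censoring is purely
administrative at the event-driven cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import AccrualPattern
from .simulate import EXPERIMENTAL, StratumPlan, SubjectTable, _membership


@dataclass
class TteTable(SubjectTable):
    """Subject table with entry/event information.  ``outcome`` aliases the
    observed (possibly censored) time from entry; times are in months."""

    entry_time: np.ndarray = None
    latent_event_time: np.ndarray = None
    event: np.ndarray = None

    @property
    def observed_time(self) -> np.ndarray:
        return self.outcome


@dataclass
class TteSummaries:
    time_to_target_events: float
    shortfall: bool
    median_duration_global: float
    median_duration_region: Optional[float]


def median_to_hazard(median: float) -> float:
    """Exponential hazard per month from a median survival time in months:
    lambda = ln 2 / median."""
    if median <= 0:
        raise ValueError("median must be positive")
    return math.log(2.0) / median


def hazard_to_median(hazard: float) -> float:
    if hazard <= 0:
        raise ValueError("hazard must be positive")
    return math.log(2.0) / hazard


def yearly_rate_to_hazard(rate: float) -> float:
    """Hazard per month from the fraction of subjects with an event within a
    year: lambda = -ln(1 - rate) / 12."""
    if not (0 < rate < 1):
        raise ValueError("yearly event rate must be in (0, 1)")
    return -math.log1p(-rate) / 12.0


def hazard_to_yearly_rate(hazard: float) -> float:
    return 1.0 - math.exp(-12.0 * hazard)


def schedule_entries(
    pattern: AccrualPattern, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Calendar entry times (months from study start) for ``n`` subjects.

    Uniform mode spreads entries i.i.d. over [start, start + duration];
    custom mode places each month's count i.i.d. within that month, offset by
    ``start_month``.
    """
    s = pattern.start_month
    if pattern.mode == "uniform":
        return s + rng.uniform(0.0, pattern.duration_months, size=n)
    counts = pattern.monthly_counts
    total = int(sum(counts))
    if total != n:
        raise ValueError(
            f"custom accrual accounts for {total} subjects but {n} are required "
            f"({n - total:+d} shortfall)"
        )
    months = np.repeat(np.arange(len(counts), dtype=float), counts)
    return s + months + rng.uniform(0.0, 1.0, size=n)


def simulate_tte(
    plan: StratumPlan,
    hazard_ctrl: float,
    hazard_ratio: float,
    entry_global: np.ndarray | None = None,
    entry_region: np.ndarray | None = None,
    *,
    rng: np.random.Generator,
) -> TteTable:
    """Exponential latent event times: rate ``hazard_ctrl`` in control and
    ``hazard_ctrl * hazard_ratio`` in the experimental arm.

    ``entry_region`` (length = region stratum size) and ``entry_global``
    (length = rest-of-world stratum size) give calendar entry times; both
    default to simultaneous entry at time 0.  Observed times and the event
    flag are filled later by :func:`censor_at`.
    """
    if hazard_ctrl <= 0 or hazard_ratio <= 0:
        raise ValueError("hazards must be positive")
    arm, in_region, in_global = _membership(plan)
    n_region = plan.region_exp + plan.region_ctrl
    n_row = plan.row_exp + plan.row_ctrl

    # random assignment of entry slots to subjects so entry time is
    # independent of the arm / in-global block layout
    entry = np.zeros(len(arm))
    if entry_region is not None:
        entry[:n_region] = rng.permutation(entry_region)
    if entry_global is not None:
        entry[n_region:] = rng.permutation(entry_global)

    rate = np.where(arm == EXPERIMENTAL, hazard_ctrl * hazard_ratio, hazard_ctrl)
    latent = rng.exponential(1.0 / rate)
    return TteTable(
        arm=arm,
        in_region=in_region,
        in_global=in_global,
        outcome=np.full(len(arm), np.nan),
        entry_time=entry,
        latent_event_time=latent,
        event=np.zeros(len(arm), dtype=bool),
    )


def analysis_cutoff(table: TteTable, target_events: int) -> tuple[float, bool]:
    """Calendar time at which the in-global event count reaches
    ``target_events``: the target-th order statistic of entry + latent event
    time over the global analysis set.  If fewer events can ever occur,
    returns the last event time with a shortfall flag."""
    if target_events < 1:
        raise ValueError("target_events must be >= 1")
    cal = table.entry_time[table.in_global] + table.latent_event_time[table.in_global]
    if cal.size == 0:
        raise ValueError("no in-global subjects")
    cal = np.sort(cal)
    if target_events > cal.size:
        return float(cal[-1]), True
    return float(cal[target_events - 1]), False


def censor_at(table: TteTable, cutoff: float) -> TteTable:
    """Administrative censoring at calendar ``cutoff``: observed time is
    min(latent event time, cutoff - entry); subjects not yet enrolled at the
    cutoff get negative follow-up and are dropped from the analysis set
    (``in_global``/``in_region`` cleared, with the count available as
    ``table.n_not_enrolled``)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    follow = cutoff - table.entry_time
    observed = np.minimum(table.latent_event_time, follow)
    event = table.latent_event_time <= follow
    enrolled = follow > 0
    out = TteTable(
        arm=table.arm,
        in_region=table.in_region & enrolled,
        in_global=table.in_global & enrolled,
        outcome=observed,
        entry_time=table.entry_time,
        latent_event_time=table.latent_event_time,
        event=event,
    )
    out.n_not_enrolled = int(np.count_nonzero(~enrolled))
    return out


def duration_summaries(table: TteTable, cutoff: float, shortfall: bool = False) -> TteSummaries:
    """Median follow-up duration (cutoff - entry) over the global and
    regional analysis sets, plus the time taken to reach the target events."""
    follow = cutoff - table.entry_time
    g = follow[table.in_global & (follow > 0)]
    r = follow[table.in_region & (follow > 0)]
    return TteSummaries(
        time_to_target_events=cutoff,
        shortfall=shortfall,
        median_duration_global=float(np.median(g)) if g.size else float("nan"),
        median_duration_region=float(np.median(r)) if r.size else None,
    )
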