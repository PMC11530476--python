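"""Replicate generation for continuous and binary endpoints.

One replicate is a :class:`SubjectTable`: per-subject arm, region membership,
a global-inclusion flag (false only for region subjects withheld from the
global analysis under partial/excluded joining), and the outcome.  Arm sizes
are deterministic per stratum - conventional in sample-size simulation, and it
removes allocation noise - and the treatment effect is common across strata:
the consistency framework quantifies sampling variability of the regional
estimate, not effect modification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .config import BinaryEffects, ContinuousEffects

EXPERIMENTAL = 1
CONTROL = 0


@dataclass
class StratumPlan:
    """Arm counts for the region stratum and the rest-of-world stratum,
    plus how many region subjects per arm count toward the global analysis."""

    region_exp: int
    region_ctrl: int
    row_exp: int
    row_ctrl: int
    region_in_global_exp: int
    region_in_global_ctrl: int


@dataclass
class SubjectTable:
    """Column-oriented subject-level replicate (arm codes 1=experimental,
    0=control)."""

    arm: np.ndarray  # int8
    in_region: np.ndarray  # bool
    in_global: np.ndarray  # bool
    outcome: np.ndarray  # float (continuous) or bool (binary)

    def __len__(self) -> int:
        return len(self.arm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arm": np.where(self.arm == EXPERIMENTAL, "experimental", "control"),
                "in_region": self.in_region,
                "in_global": self.in_global,
                "outcome": self.outcome,
            }
        )


class InfeasiblePlanError(ValueError):
    """The stratum arithmetic produced a negative rest-of-world arm count."""


def allocate_arms(n: int, ratio: Tuple[int, int]) -> Tuple[int, int]:
    """Split ``n`` subjects between arms by ``ratio`` (experimental:control),
    rounding the experimental count to nearest with ties toward experimental.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    r_e, r_c = ratio
    x = n * r_e / (r_e + r_c)
    n_exp = int(np.floor(x + 0.5))
    return n_exp, n - n_exp


def build_strata(
    n_total: int,
    global_ratio: Tuple[int, int],
    n_region: int,
    regional_ratio: Tuple[int, int],
    joining_mode: str = "complete",
    include_fraction: float | None = None,
) -> StratumPlan:
    """Derive deterministic arm counts for the region and rest-of-world
    strata.

    Under complete joining the in-global arm totals equal
    ``allocate_arms(n_total, global_ratio)`` exactly; under partial joining
    only ``round(q * n_region)`` region subjects count toward the global
    analysis and rest-of-world is topped up so the global analysis set stays
    at ``n_total``; under excluded joining the region stratum is simulated in
    addition to the ``n_total`` global subjects.
    """
    g_exp, g_ctrl = allocate_arms(n_total, global_ratio)
    r_exp, r_ctrl = allocate_arms(n_region, regional_ratio)

    if joining_mode == "complete":
        ig_exp, ig_ctrl = r_exp, r_ctrl
    elif joining_mode == "partial":
        if include_fraction is None:
            raise ValueError("partial joining requires include_fraction")
        n_in = int(np.floor(include_fraction * n_region + 0.5))
        ig_exp, ig_ctrl = allocate_arms(n_in, regional_ratio)
        ig_exp = min(ig_exp, r_exp)
        ig_ctrl = min(ig_ctrl, r_ctrl)
    elif joining_mode == "excluded":
        ig_exp = ig_ctrl = 0
    else:
        raise ValueError(f"unknown joining mode {joining_mode!r}")

    row_exp = g_exp - ig_exp
    row_ctrl = g_ctrl - ig_ctrl
    if row_exp < 0 or row_ctrl < 0:
        raise InfeasiblePlanError(
            f"rest-of-world arm counts ({row_exp}, {row_ctrl}) negative: region "
            f"stratum ({r_exp}, {r_ctrl}) with ratio {regional_ratio} is "
            f"incompatible with global totals ({g_exp}, {g_ctrl})"
        )
    return StratumPlan(r_exp, r_ctrl, row_exp, row_ctrl, ig_exp, ig_ctrl)


def _membership(plan: StratumPlan) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subject order: region-experimental, region-control, ROW-experimental,
    ROW-control.  Within each region arm the first in-global subjects carry
    the flag (exchangeable under i.i.d. outcomes)."""
    arm = np.concatenate(
        [
            np.full(plan.region_exp, EXPERIMENTAL, dtype=np.int8),
            np.full(plan.region_ctrl, CONTROL, dtype=np.int8),
            np.full(plan.row_exp, EXPERIMENTAL, dtype=np.int8),
            np.full(plan.row_ctrl, CONTROL, dtype=np.int8),
        ]
    )
    n_region = plan.region_exp + plan.region_ctrl
    in_region = np.zeros(len(arm), dtype=bool)
    in_region[:n_region] = True
    in_global = np.ones(len(arm), dtype=bool)
    in_global[plan.region_in_global_exp : plan.region_exp] = False
    in_global[
        plan.region_exp + plan.region_in_global_ctrl : n_region
    ] = False
    return arm, in_region, in_global


def simulate_continuous(
    plan: StratumPlan, effects: ContinuousEffects, rng: np.random.Generator
) -> SubjectTable:
    """Draw independent normal outcomes with the arm's assumed mean and SD;
    region and rest-of-world share the same distributions."""
    arm, in_region, in_global = _membership(plan)
    mean = np.where(arm == EXPERIMENTAL, effects.mean_exp, effects.mean_ctrl)
    sd = np.where(arm == EXPERIMENTAL, effects.sd_exp, effects.sd_ctrl)
    outcome = rng.normal(mean, sd)
    return SubjectTable(arm, in_region, in_global, outcome)


def simulate_binary(
    plan: StratumPlan, effects: BinaryEffects, rng: np.random.Generator
) -> SubjectTable:
    """Draw Bernoulli responses with the arm's assumed rate."""
    arm, in_region, in_global = _membership(plan)
    p = np.where(arm == EXPERIMENTAL, effects.p_exp, effects.p_ctrl)
    outcome = rng.random(len(arm)) < p
    return SubjectTable(arm, in_region, in_global, outcome)
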