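"""Declarative study configuration: typed parameter model, JSON persistence,
and the pre-run logic checks.

A :class:`StudyConfig` fully describes one planning exercise: the global trial
design (design type, endpoint, total sample size, randomization ratio,
two-sided significance level and assumed effects), the regional plan
(subpopulation percentages, regional ratio, joining strategy, preservation
fraction pi, and - for time-to-event endpoints - the regional accrual), and
the simulation settings.  Structural validity (types, ranges, which blocks may
coexist) is enforced at parse time; cross-parameter "logic checks" that a user
should see all at once are returned as data by :func:`validate_config`.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import List, Literal, Optional, Tuple, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator


class DesignType(str, Enum):
    superiority = "superiority"
    noninferiority = "noninferiority"
    mcpmod = "mcpmod"


class EndpointType(str, Enum):
    continuous = "continuous"
    binary = "binary"
    tte = "tte"


class Direction(str, Enum):
    """Which direction of the raw effect scale is clinically beneficial
    (non-inferiority designs make this explicit; superiority infers it from
    the assumed effects)."""

    higher_better = "higher_better"
    higher_worse = "higher_worse"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AccrualPattern(_Strict):
    """Enrollment-over-time schedule: uniform over a duration, or explicit
    per-month counts; ``start_month`` offsets the whole schedule."""

    mode: Literal["uniform", "custom"]
    duration_months: Optional[float] = None
    monthly_counts: Optional[List[int]] = None
    start_month: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "AccrualPattern":
        if self.start_month < 0:
            raise ValueError("start_month must be non-negative")
        if self.mode == "uniform":
            if self.duration_months is None or self.duration_months <= 0:
                raise ValueError("uniform accrual requires duration_months > 0")
            if self.monthly_counts is not None:
                raise ValueError("uniform accrual must not set monthly_counts")
        else:
            if not self.monthly_counts:
                raise ValueError("custom accrual requires monthly_counts")
            if any(c < 0 for c in self.monthly_counts):
                raise ValueError("monthly_counts must be non-negative")
            if self.duration_months is not None:
                raise ValueError("custom accrual must not set duration_months")
        return self

    @property
    def total(self) -> Optional[int]:
        """Number of participants the schedule accounts for (custom mode)."""
        if self.mode == "custom":
            return int(sum(self.monthly_counts))
        return None


class ContinuousEffects(_Strict):
    mean_exp: float
    mean_ctrl: float
    sd_exp: float = Field(gt=0)
    sd_ctrl: float = Field(gt=0)


class BinaryEffects(_Strict):
    # closed bounds so degenerate all/none-responder scenarios remain expressible
    p_exp: float = Field(ge=0, le=1)
    p_ctrl: float = Field(ge=0, le=1)


class TteEffects(_Strict):
    """Exponential survival parameterized by the control arm's median (months)
    OR its yearly event rate, plus the experimental:control hazard ratio.
    Analysis is event-driven at ``target_events`` events."""

    control_median: Optional[float] = Field(default=None, gt=0)
    yearly_event_rate: Optional[float] = Field(default=None, gt=0, lt=1)
    hazard_ratio: float = Field(gt=0)
    target_events: int = Field(ge=1)
    accrual: AccrualPattern

    @model_validator(mode="after")
    def _exactly_one_scale(self) -> "TteEffects":
        if (self.control_median is None) == (self.yearly_event_rate is None):
            raise ValueError(
                "exactly one of control_median / yearly_event_rate must be given"
            )
        return self


class GlobalDesign(_Strict):
    design: DesignType
    endpoint: EndpointType
    n_total: int = Field(ge=1)
    ratio: Tuple[int, int]  # experimental : control
    alpha: float = Field(gt=0, lt=1)  # two-sided significance level
    effects: Union[ContinuousEffects, BinaryEffects, TteEffects]
    ni_margin: Optional[float] = Field(default=None, gt=0)
    direction: Optional[Direction] = None

    @model_validator(mode="after")
    def _cross_checks(self) -> "GlobalDesign":
        if self.ratio[0] <= 0 or self.ratio[1] <= 0:
            raise ValueError("randomization ratio parts must be positive")
        expected = {
            EndpointType.continuous: ContinuousEffects,
            EndpointType.binary: BinaryEffects,
            EndpointType.tte: TteEffects,
        }[self.endpoint]
        if not isinstance(self.effects, expected):
            raise ValueError(
                f"effects block must be {expected.__name__} for endpoint "
                f"{self.endpoint.value}"
            )
        if self.design == DesignType.noninferiority:
            if self.ni_margin is None:
                raise ValueError("non-inferiority design requires ni_margin")
            if self.endpoint != EndpointType.tte and self.direction is None:
                raise ValueError("non-inferiority design requires direction")
        else:
            if self.ni_margin is not None:
                raise ValueError("ni_margin only allowed for non-inferiority design")
            if self.direction is not None:
                raise ValueError("direction only allowed for non-inferiority design")
        if isinstance(self.effects, TteEffects):
            if self.effects.target_events > self.n_total:
                raise ValueError("target_events cannot exceed n_total")
        return self


class JoiningStrategy(_Strict):
    """How the region's participants relate to the global analysis set:
    completely included, partially included (a fraction), or fully excluded
    (region simulated on top of the global study)."""

    mode: Literal["complete", "partial", "excluded"]
    include_fraction: Optional[float] = Field(default=None, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "JoiningStrategy":
        if self.mode == "partial" and self.include_fraction is None:
            raise ValueError("partial joining requires include_fraction")
        if self.mode != "partial" and self.include_fraction is not None:
            raise ValueError("include_fraction only allowed for partial joining")
        return self


class RegionalPlan(_Strict):
    percentages: List[float]  # subpopulation percentages in (0, 100]
    regional_ratio: Tuple[int, int]
    joining: JoiningStrategy
    pi: float = Field(default=0.5, gt=0, le=1)  # preservation fraction
    regional_accrual: Optional[AccrualPattern] = None

    @model_validator(mode="after")
    def _check(self) -> "RegionalPlan":
        if not self.percentages:
            raise ValueError("at least one subpopulation percentage required")
        for p in self.percentages:
            if not (0 < p <= 100):
                raise ValueError(f"percentage {p} outside (0, 100]")
        if self.regional_ratio[0] <= 0 or self.regional_ratio[1] <= 0:
            raise ValueError("regional ratio parts must be positive")
        return self


class DoseResponseModelSpec(_Strict):
    """Candidate dose-response shape; anchored downstream so the curve passes
    through (0, E0) and attains E0 + emax_effect at the top dose."""

    family: Literal["linear", "emax", "sigmoid_emax", "quadratic", "exponential"]
    ed50: Optional[float] = Field(default=None, gt=0)
    hill: Optional[float] = Field(default=None, gt=0)
    delta: Optional[float] = None  # quadratic b2/|b1| ratio
    rate: Optional[float] = Field(default=None, gt=0)  # exponential scale

    @model_validator(mode="after")
    def _check(self) -> "DoseResponseModelSpec":
        need = {
            "linear": [],
            "emax": ["ed50"],
            "sigmoid_emax": ["ed50", "hill"],
            "quadratic": [],
            "exponential": ["rate"],
        }[self.family]
        for name in need:
            if getattr(self, name) is None:
                raise ValueError(f"{self.family} model requires {name}")
        return self


class McpmodSpec(_Strict):
    doses: List[float]
    n_per_dose: List[int]
    e0: float
    emax_effect: float
    sd: Optional[float] = Field(default=None, ge=0)  # continuous only; 0 = noiseless limit
    delta: Optional[float] = Field(default=None, gt=0)  # clinically relevant effect
    candidate_models: List[DoseResponseModelSpec]
    true_model_index: int = 0
    signal_type: Literal[1, 2, 3] = 1
    alpha_mct: float = Field(default=0.025, gt=0, lt=0.5)  # one-sided

    @model_validator(mode="after")
    def _check(self) -> "McpmodSpec":
        if len(self.doses) < 2:
            raise ValueError("at least two dose levels (incl. placebo) required")
        if self.doses[0] != 0:
            raise ValueError("first dose level must be 0 (placebo)")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if len(self.n_per_dose) != len(self.doses):
            raise ValueError("n_per_dose must match doses in length")
        if any(n < 1 for n in self.n_per_dose):
            raise ValueError("n_per_dose entries must be positive")
        if not self.candidate_models:
            raise ValueError("at least one candidate model required")
        if not (0 <= self.true_model_index < len(self.candidate_models)):
            raise ValueError("true_model_index out of range")
        if self.signal_type in (2, 3) and self.delta is None:
            raise ValueError("signal types 2 and 3 require delta")
        return self


class SimulationSettings(_Strict):
    n_sims: int = Field(ge=1)
    seed: Optional[int] = None


class StudyConfig(_Strict):
    global_design: GlobalDesign = Field(alias="global")
    regional: RegionalPlan
    mcpmod: Optional[McpmodSpec] = None
    sim: SimulationSettings

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        is_mcpmod = self.global_design.design == DesignType.mcpmod
        if is_mcpmod and self.mcpmod is None:
            raise ValueError("mcpmod design requires an mcpmod block")
        if not is_mcpmod and self.mcpmod is not None:
            raise ValueError("mcpmod block only allowed for mcpmod design")
        if is_mcpmod:
            if (
                self.global_design.endpoint == EndpointType.continuous
                and self.mcpmod.sd is None
            ):
                raise ValueError("continuous mcpmod design requires sd")
            if self.global_design.endpoint == EndpointType.tte:
                raise ValueError("tte endpoint not supported in mcpmod design")
        return self


class ValidationIssue(BaseModel):
    severity: Literal["error", "warning"]
    field: str
    message: str


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Parse a JSON configuration file into a typed :class:`StudyConfig`.

    Unknown keys are rejected; structural violations raise pydantic
    ``ValidationError`` naming the offending key.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return StudyConfig.model_validate(data)


def save_config(cfg: StudyConfig, path: Union[str, Path]) -> None:
    """Write ``cfg`` as JSON (deterministic key order, round-trips through
    :func:`load_config`)."""
    payload = cfg.model_dump(mode="json", by_alias=True, exclude_none=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def derive_region_sizes(n_total: int, percentages: List[float]) -> List[int]:
    """Regional sample sizes from subpopulation percentages: each size is
    ceiling(n_total * pct / 100), the convention under which 554 at
    10/15/20/25/30 percent yields 56/84/111/139/167."""
    return [int(math.ceil(n_total * p / 100.0)) for p in percentages]


def validate_config(cfg: StudyConfig) -> List[ValidationIssue]:
    """Cross-parameter logic checks; an empty list means the config is
    runnable.  Issues are data, not exceptions, so a front end can show every
    problem at once."""
    issues: List[ValidationIssue] = []

    def err(field: str, message: str) -> None:
        issues.append(ValidationIssue(severity="error", field=field, message=message))

    pcts = cfg.regional.percentages
    if any(b <= a for a, b in zip(pcts, pcts[1:])):
        err("regional.percentages", "percentages must be strictly increasing")

    sizes = derive_region_sizes(cfg.global_design.n_total, pcts)
    if cfg.regional.joining.mode == "complete":
        for pct, size in zip(pcts, sizes):
            if size > cfg.global_design.n_total:
                err(
                    "regional.percentages",
                    f"regional size {size} at {pct}% exceeds n_total "
                    f"{cfg.global_design.n_total}",
                )

    eff = cfg.global_design.effects
    if isinstance(eff, TteEffects):
        if eff.target_events > cfg.global_design.n_total:
            err(
                "global.effects.target_events",
                "target_events exceeds n_total",
            )
        if eff.accrual.mode == "custom":
            short = cfg.global_design.n_total - eff.accrual.total
            if short != 0:
                word = "unallocated" if short > 0 else "over-allocated"
                err(
                    "global.effects.accrual.monthly_counts",
                    f"{abs(short)} participants {word}: custom accrual sums to "
                    f"{eff.accrual.total}, n_total is {cfg.global_design.n_total}",
                )
        ra = cfg.regional.regional_accrual
        if ra is not None and ra.mode == "custom":
            for pct, size in zip(pcts, sizes):
                if ra.total != size:
                    err(
                        "regional.regional_accrual.monthly_counts",
                        f"regional accrual sums to {ra.total} but the region at "
                        f"{pct}% has {size} participants",
                    )
    elif cfg.regional.regional_accrual is not None:
        err(
            "regional.regional_accrual",
            "regional accrual only applies to time-to-event endpoints",
        )

    if cfg.mcpmod is not None:
        m = cfg.mcpmod
        if sum(m.n_per_dose) != cfg.global_design.n_total:
            err(
                "mcpmod.n_per_dose",
                f"per-dose sizes sum to {sum(m.n_per_dose)}, n_total is "
                f"{cfg.global_design.n_total}",
            )
        if m.signal_type in (2, 3) and m.delta is None:
            err("mcpmod.delta", "signal types 2 and 3 require delta")

    return issues
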