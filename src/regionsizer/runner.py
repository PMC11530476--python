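"""Pipeline driver: replicate loop, result-table assembly, CSV output and
the consistency-vs-subpopulation plot.

For each subpopulation percentage the study is simulated ``n_sims`` times,
per-replicate estimates and consistency criteria are computed, and the
Monte-Carlo probabilities are aggregated into one result row.  Replicate RNG
streams are derived from (seed, percentage index, replicate index), so any
single percentage reproduces its row from the full run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    BinaryEffects,
    ContinuousEffects,
    DesignType,
    Direction,
    EndpointType,
    StudyConfig,
    TteEffects,
    derive_region_sizes,
    validate_config,
)
from .consistency import (
    ConsistencyRow,
    aggregate_probabilities,
    ni_criterion,
    ni_tte_criteria,
    superiority_criterion,
    tte_criteria,
)
from .inference import chi_square_test, logrank_and_hr, overall_significance, t_test
from .mcpmod import (
    mct_critical_value,
    model_means,
    optimal_contrasts,
    simulate_mcpmod,
)
from .simulate import (
    EXPERIMENTAL,
    build_strata,
    simulate_binary,
    simulate_continuous,
)
from .survival import (
    analysis_cutoff,
    censor_at,
    duration_summaries,
    median_to_hazard,
    schedule_entries,
    simulate_tte,
    yearly_rate_to_hazard,
)

logger = logging.getLogger("regionsizer")


class ConfigurationError(ValueError):
    def __init__(self, issues):
        self.issues = issues
        lines = "; ".join(f"{i.field}: {i.message}" for i in issues)
        super().__init__(f"configuration not runnable: {lines}")


@dataclass
class RunResult:
    rows: List[ConsistencyRow]
    config: StudyConfig
    seed: Optional[int]
    n_sims: int
    version: str = __version__
    wall_time_s: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([_row_to_dict(r, self.config) for r in self.rows])


def _replicate_rng(seed: Optional[int], pct_index: int, rep: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(pct_index, rep))
    return np.random.default_rng(ss)


def _benefit_sign(effects) -> float:
    """Orient the effect scale so the assumed overall effect is positive."""
    if isinstance(effects, ContinuousEffects):
        raw = effects.mean_exp - effects.mean_ctrl
    else:
        raw = effects.p_exp - effects.p_ctrl
    return -1.0 if raw < 0 else 1.0


def run_study(cfg: StudyConfig) -> RunResult:
    """Execute the full simulation for every subpopulation percentage."""
    issues = validate_config(cfg)
    if any(i.severity == "error" for i in issues):
        raise ConfigurationError(issues)

    t0 = time.perf_counter()
    g = cfg.global_design
    seed = cfg.sim.seed
    n_sims = cfg.sim.n_sims
    sizes = derive_region_sizes(g.n_total, cfg.regional.percentages)

    rows: List[ConsistencyRow] = []
    for idx, (pct, n_region) in enumerate(zip(cfg.regional.percentages, sizes)):
        if g.design == DesignType.mcpmod:
            row = _run_mcpmod_pct(cfg, idx, pct, n_sims, seed)
        elif g.endpoint == EndpointType.tte:
            row = _run_tte_pct(cfg, idx, pct, n_region, n_sims, seed)
        else:
            row = _run_meanlike_pct(cfg, idx, pct, n_region, n_sims, seed)
        logger.info(
            "pct=%s n_region=%s power=%.4f cond=%s uncond=%s not_evaluable=%d",
            pct, row.n_region, row.power, row.cond_prob, row.uncond_prob,
            row.n_not_evaluable,
        )
        rows.append(row)

    return RunResult(
        rows=rows,
        config=cfg,
        seed=seed,
        n_sims=n_sims,
        wall_time_s=time.perf_counter() - t0,
    )


# ---------------------------------------------------------------------------
# continuous / binary superiority and non-inferiority


def _run_meanlike_pct(
    cfg: StudyConfig, idx: int, pct: float, n_region: int, n_sims: int, seed
) -> ConsistencyRow:
    g = cfg.global_design
    plan = build_strata(
        g.n_total,
        g.ratio,
        n_region,
        cfg.regional.regional_ratio,
        cfg.regional.joining.mode,
        cfg.regional.joining.include_fraction,
    )
    is_ni = g.design == DesignType.noninferiority
    sign = _benefit_sign(g.effects)
    pi = cfg.regional.pi

    crits, sigs = [], []
    low_all = low_reg = n_degenerate = 0
    for rep in range(n_sims):
        rng = _replicate_rng(seed, idx, rep)
        if isinstance(g.effects, ContinuousEffects):
            tab = simulate_continuous(plan, g.effects, rng)
            ga = tab.in_global
            ra = tab.in_region
            th_all, p_all, se_all = t_test(
                tab.outcome[ga & (tab.arm == EXPERIMENTAL)],
                tab.outcome[ga & (tab.arm != EXPERIMENTAL)],
            )
            th_reg, _, _ = t_test(
                tab.outcome[ra & (tab.arm == EXPERIMENTAL)],
                tab.outcome[ra & (tab.arm != EXPERIMENTAL)],
            )
        else:
            tab = simulate_binary(plan, g.effects, rng)
            ga, ra = tab.in_global, tab.in_region
            exp_g = ga & (tab.arm == EXPERIMENTAL)
            ctl_g = ga & (tab.arm != EXPERIMENTAL)
            exp_r = ra & (tab.arm == EXPERIMENTAL)
            ctl_r = ra & (tab.arm != EXPERIMENTAL)
            th_all, p_all, flag_a, se_all = chi_square_test(
                int(tab.outcome[exp_g].sum()), int(exp_g.sum()),
                int(tab.outcome[ctl_g].sum()), int(ctl_g.sum()),
            )
            th_reg, _, flag_r, _ = chi_square_test(
                int(tab.outcome[exp_r].sum()), int(exp_r.sum()),
                int(tab.outcome[ctl_r].sum()), int(ctl_r.sum()),
            )
            low_all += flag_a
            low_reg += flag_r

        if not (np.isfinite(th_all) and np.isfinite(th_reg)):
            n_degenerate += 1
            crits.append(None)
            sigs.append(False)
            continue

        if is_ni:
            crit = ni_criterion(th_reg, th_all, g.ni_margin, g.direction, pi)
            sig = overall_significance(
                design="noninferiority", alpha=g.alpha, theta=th_all,
                se=se_all, ni_margin=g.ni_margin, direction=g.direction,
            )
        else:
            crit = superiority_criterion(sign * th_reg, sign * th_all, pi)
            sig = overall_significance(
                design="superiority", alpha=g.alpha, theta=th_all,
                p_two_sided=p_all, benefit_sign=sign,
            )
        crits.append(crit)
        sigs.append(sig)

    uncond, cond, n_ne = aggregate_probabilities(crits, sigs)
    row = ConsistencyRow(
        subpop_pct=pct,
        n_region=n_region,
        power=sum(sigs) / n_sims,
        uncond_prob=uncond,
        cond_prob=cond,
        n_sims=n_sims,
        n_not_evaluable=n_ne,
    )
    if isinstance(g.effects, BinaryEffects):
        row.low_cell_count_all = low_all
        row.low_cell_count_region = low_reg
    if n_degenerate:
        row.extras["n_degenerate"] = n_degenerate
    return row


# ---------------------------------------------------------------------------
# time-to-event


def _draw_entries(pattern, k: int, rng: np.random.Generator) -> np.ndarray:
    """k entry times following ``pattern``.  A custom monthly schedule whose
    counts exceed k is subsampled without replacement, so a stratum smaller
    than the population the schedule describes still follows its shape."""
    if pattern.mode == "uniform":
        return schedule_entries(pattern, k, rng)
    total = pattern.total
    if total == k:
        return schedule_entries(pattern, k, rng)
    if total < k:
        raise ValueError(
            f"custom accrual accounts for {total} subjects but {k} are required"
        )
    pool = schedule_entries(pattern, total, rng)
    return rng.choice(pool, size=k, replace=False)


def _tte_entries(eff, reg_accrual, n_total, n_reg, n_row, rng):
    """Calendar entry times for the region and rest-of-world strata.

    With no regional accrual and the region inside the global study, one
    global schedule is drawn and split at random, preserving the overall
    monthly totals exactly; otherwise the region follows its own (or the
    global) pattern independently."""
    if reg_accrual is not None:
        entry_region = _draw_entries(reg_accrual, n_reg, rng)
        entry_row = _draw_entries(eff.accrual, n_row, rng)
    elif n_reg + n_row <= n_total and eff.accrual.mode == "custom":
        pool = rng.permutation(_draw_entries(eff.accrual, n_reg + n_row, rng))
        entry_region, entry_row = pool[:n_reg], pool[n_reg:]
    else:
        entry_region = _draw_entries(eff.accrual, n_reg, rng)
        entry_row = _draw_entries(eff.accrual, n_row, rng)
    return entry_region, entry_row


def _run_tte_pct(
    cfg: StudyConfig, idx: int, pct: float, n_region: int, n_sims: int, seed
) -> ConsistencyRow:
    g = cfg.global_design
    eff: TteEffects = g.effects
    plan = build_strata(
        g.n_total, g.ratio, n_region, cfg.regional.regional_ratio,
        cfg.regional.joining.mode, cfg.regional.joining.include_fraction,
    )
    hazard = (
        median_to_hazard(eff.control_median)
        if eff.control_median is not None
        else yearly_rate_to_hazard(eff.yearly_event_rate)
    )
    is_ni = g.design == DesignType.noninferiority
    pi = cfg.regional.pi
    n_reg_total = plan.region_exp + plan.region_ctrl
    n_row_total = plan.row_exp + plan.row_ctrl
    reg_accrual = cfg.regional.regional_accrual

    crits1, crits2, sigs = [], [], []
    ttes, med_g, med_r = [], [], []
    for rep in range(n_sims):
        rng = _replicate_rng(seed, idx, rep)
        entry_region, entry_row = _tte_entries(
            eff, reg_accrual, g.n_total, n_reg_total, n_row_total, rng
        )

        tab = simulate_tte(
            plan, hazard, eff.hazard_ratio,
            entry_global=entry_row, entry_region=entry_region, rng=rng,
        )
        cutoff, shortfall = analysis_cutoff(tab, eff.target_events)
        obs = censor_at(tab, cutoff)
        summ = duration_summaries(obs, cutoff, shortfall)
        ttes.append(summ.time_to_target_events)
        med_g.append(summ.median_duration_global)
        if summ.median_duration_region is not None:
            med_r.append(summ.median_duration_region)

        ga, ra = obs.in_global, obs.in_region
        grp = (obs.arm == EXPERIMENTAL).astype(float)
        hr_all, se_all, p_all, _ = logrank_and_hr(
            obs.outcome[ga], obs.event[ga], grp[ga]
        )
        hr_reg, _, _, _ = logrank_and_hr(obs.outcome[ra], obs.event[ra], grp[ra])

        if is_ni:
            c1, c2 = ni_tte_criteria(hr_reg, hr_all, g.ni_margin, pi)
            sig = overall_significance(
                design="noninferiority", alpha=g.alpha,
                hr=hr_all, se_log_hr=se_all, ni_margin=g.ni_margin,
            )
        else:
            c1, c2 = tte_criteria(hr_reg, hr_all, pi)
            sig = overall_significance(
                design="superiority", alpha=g.alpha, hr=hr_all, p_two_sided=p_all,
            )
        crits1.append(c1)
        crits2.append(c2)
        sigs.append(sig)

    u1, c1_, ne1 = aggregate_probabilities(crits1, sigs)
    u2, c2_, ne2 = aggregate_probabilities(crits2, sigs)
    return ConsistencyRow(
        subpop_pct=pct,
        n_region=n_region,
        power=sum(sigs) / n_sims,
        uncond_prob=u1,
        cond_prob=c1_,
        n_sims=n_sims,
        n_not_evaluable=ne1,
        uncond_prob_alt=u2,
        cond_prob_alt=c2_,
        n_not_evaluable_alt=ne2,
        mean_time_to_target_events=float(np.mean(ttes)),
        mean_median_duration_global=float(np.nanmean(med_g)),
        mean_median_duration_region=float(np.mean(med_r)) if med_r else None,
    )


# ---------------------------------------------------------------------------
# MCP-Mod


def _run_mcpmod_pct(
    cfg: StudyConfig, idx: int, pct: float, n_sims: int, seed
) -> ConsistencyRow:
    spec = cfg.mcpmod
    g = cfg.global_design
    endpoint = g.endpoint.value
    doses = np.asarray(spec.doses, dtype=float)
    n = np.asarray(spec.n_per_dose, dtype=int)
    mu0 = [model_means(m, doses, spec.e0, spec.emax_effect) for m in spec.candidate_models]
    if endpoint == "binary":
        mu0 = [np.log(v / (1 - v)) for v in mu0]
    contrasts = optimal_contrasts(mu0, n)
    df = int(n.sum() - len(doses))
    cval = mct_critical_value(
        contrasts, n, spec.alpha_mct, df if endpoint == "continuous" else None
    )

    fraction = pct / 100.0
    crits, sigs, meds = [], [], []
    n_fallback = 0
    for rep in range(n_sims):
        rng = _replicate_rng(seed, idx, rep)
        r = simulate_mcpmod(
            spec, endpoint, fraction, rng,
            contrasts=contrasts, critical_value=cval, pi=cfg.regional.pi,
        )
        sigs.append(r.signal)
        crits.append(r.consistency if r.signal else False)
        n_fallback += r.fit_fallback
        if r.signal and r.med is not None:
            meds.append(r.med)

    # only the conditional probability is defined for this design
    _, cond, n_ne = aggregate_probabilities(crits, sigs)
    n_region_total = sum(
        int(np.ceil(fraction * ni)) for ni in spec.n_per_dose
    )
    row = ConsistencyRow(
        subpop_pct=pct,
        n_region=n_region_total,
        power=sum(sigs) / n_sims,
        uncond_prob=None,
        cond_prob=cond,
        n_sims=n_sims,
        n_not_evaluable=n_ne,
    )
    if spec.delta is not None:
        row.extras["median_med"] = float(np.median(meds)) if meds else None
    if n_fallback:
        row.extras["n_fit_fallback"] = n_fallback
    return row


# ---------------------------------------------------------------------------
# output


_PROB_COLS = (
    "power", "uncond_prob", "cond_prob", "uncond_prob_alt", "cond_prob_alt",
)


def _row_to_dict(row: ConsistencyRow, cfg: StudyConfig) -> dict:
    g = cfg.global_design
    d = {
        "subpop_pct": row.subpop_pct,
        "n_region": row.n_region,
        "power": row.power,
        "n_sims": row.n_sims,
        "seed": cfg.sim.seed,
        "pi": cfg.regional.pi,
        "design": g.design.value,
        "endpoint": g.endpoint.value,
        "n_total": g.n_total,
        "alpha": g.alpha,
    }
    if g.endpoint == EndpointType.tte:
        d["uncond_loghr"] = row.uncond_prob
        d["cond_loghr"] = row.cond_prob
        d["uncond_riskred"] = row.uncond_prob_alt
        d["cond_riskred"] = row.cond_prob_alt
        d["n_not_evaluable_loghr"] = row.n_not_evaluable
        d["n_not_evaluable_riskred"] = row.n_not_evaluable_alt
        d["mean_time_to_target_events"] = row.mean_time_to_target_events
        d["mean_median_duration_global"] = row.mean_median_duration_global
        d["mean_median_duration_region"] = row.mean_median_duration_region
    else:
        d["uncond_prob"] = row.uncond_prob
        d["cond_prob"] = row.cond_prob
        d["n_not_evaluable"] = row.n_not_evaluable
    if row.low_cell_count_all is not None:
        d["n_low_expected_cells_all"] = row.low_cell_count_all
        d["n_low_expected_cells_region"] = row.low_cell_count_region
    d.update(row.extras)
    return d


def write_csv(result: RunResult, path: Union[str, Path]) -> None:
    """Result table as UTF-8 CSV: one row per subpopulation percentage,
    probabilities to 4 decimal places, missing values as empty cells."""
    df = result.to_frame()
    for col in df.columns:
        if df[col].dtype.kind == "f" and (
            col in _PROB_COLS or col.startswith(("uncond", "cond", "power"))
        ):
            df[col] = df[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "")
    df.to_csv(path, index=False, encoding="utf-8")


def plot_consistency(result: RunResult, path: Union[str, Path]) -> None:
    """Scatter of conditional/unconditional consistency probability against
    subpopulation percentage (superiority and non-inferiority designs)."""
    cfg = result.config
    if cfg.global_design.design == DesignType.mcpmod:
        raise ValueError("plot not available for MCP-Mod design")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pcts = [r.subpop_pct for r in result.rows]
    fig, ax = plt.subplots(figsize=(7, 5))
    is_tte = cfg.global_design.endpoint == EndpointType.tte
    series = (
        [
            ("unconditional (log HR)", [r.uncond_prob for r in result.rows]),
            ("conditional (log HR)", [r.cond_prob for r in result.rows]),
            ("unconditional (risk reduction)", [r.uncond_prob_alt for r in result.rows]),
            ("conditional (risk reduction)", [r.cond_prob_alt for r in result.rows]),
        ]
        if is_tte
        else [
            ("unconditional", [r.uncond_prob for r in result.rows]),
            ("conditional", [r.cond_prob for r in result.rows]),
        ]
    )
    for label, ys in series:
        xs = [x for x, y in zip(pcts, ys) if y is not None]
        vals = [y for y in ys if y is not None]
        ax.scatter(xs, vals, label=label)
    ax.set_xlabel("subpopulation percentage")
    ax.set_ylabel("consistency probability")
    ax.set_ylim(0.0, 1.0)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
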