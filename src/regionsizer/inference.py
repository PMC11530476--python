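"""Per-replicate estimation and significance testing.

Covers the pooled-variance two-sample t-test, the Pearson chi-square test
with expected-cell diagnostics, the two-sided log-rank test with an
unadjusted proportional-hazards hazard-ratio fit, and the margin-shifted
non-inferiority rules.  The log-rank statistic and the two-group Cox fit
share one vectorized risk-set sweep (Breslow tie handling, Newton-Raphson on
the partial likelihood) so that simulations with thousands of replicates stay
fast; tests cross-check both against an independent survival library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .config import Direction


@dataclass
class TrialEstimates:
    """Per-replicate summaries on the raw effect scale.

    ``theta_*`` are mean/proportion differences (experimental minus control);
    ``hr_*`` are hazard ratios.  ``significant`` is the overall conditioning
    event (two-sided rejection in the beneficial direction for superiority;
    the margin test for non-inferiority).
    """

    theta_all: Optional[float] = None
    theta_region: Optional[float] = None
    hr_all: Optional[float] = None
    hr_region: Optional[float] = None
    se_all: Optional[float] = None
    se_log_hr_all: Optional[float] = None
    p_overall: Optional[float] = None
    significant: bool = False
    low_cell_flag_all: bool = False
    low_cell_flag_region: bool = False
    degenerate: bool = False
    hr_fallback: bool = False
    extras: dict = field(default_factory=dict)


def t_test(x_exp: np.ndarray, x_ctrl: np.ndarray) -> Tuple[float, float, float]:
    """Pooled-variance two-sample t-test.

    Returns ``(theta, p_two_sided, se)`` with theta the raw mean difference
    (experimental minus control).  A degenerate pooled variance yields
    ``p = nan`` so the replicate can be flagged and excluded.
    """
    n1, n2 = len(x_exp), len(x_ctrl)
    if n1 < 2 or n2 < 2:
        return float("nan"), float("nan"), float("nan")
    m1, m2 = x_exp.mean(), x_ctrl.mean()
    v1 = x_exp.var(ddof=1)
    v2 = x_ctrl.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    theta = m1 - m2
    if sp2 <= 0:
        if theta == 0.0:
            return 0.0, 1.0, 0.0
        return theta, float("nan"), 0.0
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = theta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return theta, p, se


def chi_square_test(
    x_exp: int, n_exp: int, x_ctrl: int, n_ctrl: int
) -> Tuple[float, float, bool, float]:
    """Pearson chi-square on the 2x2 responder table, without continuity
    correction.

    Returns ``(theta, p_two_sided, low_cell_flag, se)``: theta is the raw
    proportion difference, ``low_cell_flag`` marks any expected cell count
    below 5 (the caveat surfaced in the result table in place of switching to
    an exact test), and ``se`` is the unpooled Wald standard error used by
    the non-inferiority rule.  A degenerate margin (all responders or none)
    gives p = 1 with the flag set.
    """
    if n_exp < 1 or n_ctrl < 1:
        raise ValueError("both arms must be non-empty")
    p1, p0 = x_exp / n_exp, x_ctrl / n_ctrl
    theta = p1 - p0
    n = n_exp + n_ctrl
    resp = x_exp + x_ctrl
    nonresp = n - resp
    se = math.sqrt(
        max(p1 * (1 - p1), 0.0) / n_exp + max(p0 * (1 - p0), 0.0) / n_ctrl
    )
    if resp == 0 or nonresp == 0:
        return theta, 1.0, True, se
    expected = np.outer([n_exp, n_ctrl], [resp, nonresp]) / n
    observed = np.array(
        [[x_exp, n_exp - x_exp], [x_ctrl, n_ctrl - x_ctrl]], dtype=float
    )
    chi2 = ((observed - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, 1)
    flag = bool((expected < 5).any())
    return theta, float(p), flag, se


def _risk_sets(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Distinct event times' (d, d1, n, n1): total/group-1 event counts and
    at-risk counts, for right-censored data."""
    ut, inv = np.unique(time, return_inverse=True)
    k = len(ut)
    ev = event.astype(float)
    g = group.astype(float)
    leaving = np.bincount(inv, minlength=k)
    leaving1 = np.bincount(inv, weights=g, minlength=k)
    d = np.bincount(inv, weights=ev, minlength=k)
    d1 = np.bincount(inv, weights=ev * g, minlength=k)
    n_at = leaving[::-1].cumsum()[::-1].astype(float)
    n1_at = leaving1[::-1].cumsum()[::-1]
    mask = d > 0
    return d[mask], d1[mask], n_at[mask], n1_at[mask]


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> Tuple[float, float, float]:
    """Unstratified two-group log-rank: returns (O - E, V, p_two_sided) for
    group 1 (experimental)."""
    if not event.any():
        return 0.0, 0.0, float("nan")
    d, d1, n, n1 = _risk_sets(time, event, group)
    frac = n1 / n
    o_minus_e = float((d1 - d * frac).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(n > 1, (n - d) / (n - 1), 0.0)
    v = float((d * frac * (1.0 - frac) * corr).sum())
    if v <= 0:
        return o_minus_e, v, float("nan")
    chi2 = o_minus_e**2 / v
    return o_minus_e, v, float(stats.chi2.sf(chi2, 1))


def cox_binary_hr(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> Tuple[float, float, bool]:
    """Maximum-partial-likelihood hazard ratio (group 1 vs group 0) for a
    single binary covariate, Breslow ties, Newton-Raphson.

    Returns ``(hr, se_log_hr, fallback)``.  When an arm has no events the ML
    estimate diverges; the (O-E)/V log-rank approximation of log HR is used
    instead and flagged."""
    d, d1, n, n1 = _risk_sets(time, event, group)
    d_tot, d1_tot = d.sum(), d1.sum()
    o_minus_e, v, _ = logrank_statistic(time, event, group)
    if d_tot == 0 or v <= 0 or d1_tot == 0 or d1_tot == d_tot:
        log_hr = o_minus_e / v if v > 0 else float("nan")
        se = 1.0 / math.sqrt(v) if v > 0 else float("nan")
        return math.exp(log_hr) if np.isfinite(log_hr) else float("nan"), se, True
    n0 = n - n1
    beta = 0.0
    info = v
    for _ in range(50):
        eb = math.exp(beta)
        denom = n0 + n1 * eb
        p = n1 * eb / denom
        score = float((d1 - d * p).sum())
        info = float((d * p * (1.0 - p)).sum())
        if info <= 0:
            return math.exp(o_minus_e / v), 1.0 / math.sqrt(v), True
        step = score / info
        beta += max(min(step, 2.0), -2.0)
        if abs(step) < 1e-12:
            break
    return math.exp(beta), 1.0 / math.sqrt(info), False


def logrank_and_hr(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> Tuple[float, float, float, bool]:
    """Two-sided log-rank p-value plus the unadjusted proportional-hazards
    hazard ratio and its log-scale standard error.

    Returns ``(hr, se_log_hr, p_two_sided, fallback_flag)``."""
    _, _, p = logrank_statistic(time, event, group)
    hr, se, fallback = cox_binary_hr(time, event, group)
    return hr, se, p, fallback


def overall_significance(
    *,
    design: str,
    alpha: float,
    theta: Optional[float] = None,
    p_two_sided: Optional[float] = None,
    se: Optional[float] = None,
    benefit_sign: float = 1.0,
    hr: Optional[float] = None,
    se_log_hr: Optional[float] = None,
    ni_margin: Optional[float] = None,
    direction: Optional[Direction] = None,
) -> bool:
    """The conditioning event "the overall result is statistically
    significant".

    Superiority: two-sided p < alpha AND the estimate favors the experimental
    arm (beneficially oriented theta > 0, or hr < 1) - a rejection in the
    harmful direction does not count.  Non-inferiority: one-sided test at
    alpha/2 via the confidence-interval-vs-margin rule; for hazard ratios the
    upper (1 - alpha) two-sided CI limit must fall below the margin."""
    if design == "superiority":
        if p_two_sided is None or not np.isfinite(p_two_sided):
            return False
        if hr is not None:
            return p_two_sided < alpha and hr < 1.0
        return p_two_sided < alpha and benefit_sign * theta > 0
    if design == "noninferiority":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        if hr is not None:
            if se_log_hr is None or not np.isfinite(se_log_hr) or hr <= 0:
                return False
            return math.exp(math.log(hr) + z * se_log_hr) < ni_margin
        if se is None or not np.isfinite(se) or theta is None:
            return False
        if direction == Direction.higher_worse:
            return theta + z * se < ni_margin
        return theta - z * se > -ni_margin
    raise ValueError(f"unknown design {design!r}")
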