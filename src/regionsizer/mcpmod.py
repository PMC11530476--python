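"""Dose-finding (MCP-Mod) design: candidate dose-response models, optimal
contrasts, the multiple contrast test with an equicoordinate critical value,
minimum-effective-dose prediction, the three significant-signal criteria, and
the contrast-based regional consistency criterion.

Candidate curves are anchored so each passes through (0, E0) and attains
E0 + emax_effect at the top dose; shape parameters (ED50, Hill, ...) fix only
the shape.  For binary endpoints the analysis runs on empirical logits with
(x + 0.5)/(n + 1) shrinkage, so the consistency probability is interpreted on
the logit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .config import DoseResponseModelSpec, McpmodSpec


# ---------------------------------------------------------------------------
# candidate model curves


def _standardized(model: DoseResponseModelSpec, d: np.ndarray, d_max: float) -> np.ndarray:
    if model.family == "linear":
        return d
    if model.family == "emax":
        return d / (model.ed50 + d)
    if model.family == "sigmoid_emax":
        h = model.hill
        with np.errstate(divide="ignore"):
            return np.where(d > 0, d**h / (model.ed50**h + d**h), 0.0)
    if model.family == "quadratic":
        delta = model.delta if model.delta is not None else -1.0 / (2.0 * d_max)
        return d + delta * d * d
    if model.family == "exponential":
        return np.expm1(d / model.rate)
    raise ValueError(f"unknown family {model.family!r}")


def model_means(
    model: DoseResponseModelSpec,
    doses: Sequence[float],
    e0: float,
    emax_effect: float,
) -> np.ndarray:
    """Mean response at each dose for an anchored candidate model: the curve
    passes through (0, e0) and reaches e0 + emax_effect at the top dose."""
    d = np.asarray(doses, dtype=float)
    d_max = float(d.max())
    f0 = _standardized(model, d, d_max)
    f0_0 = _standardized(model, np.array([0.0]), d_max)[0]
    f0_top = _standardized(model, np.array([d_max]), d_max)[0]
    span = f0_top - f0_0
    if span == 0:
        raise ValueError(f"{model.family} model is flat over the dose range")
    return e0 + emax_effect * (f0 - f0_0) / span


# ---------------------------------------------------------------------------
# optimal contrasts and the multiple contrast test


def optimal_contrasts(
    mu0_list: Sequence[np.ndarray], n_per_dose: Sequence[int]
) -> np.ndarray:
    """Power-optimal contrast per candidate mean vector.

    With S = diag(1/n_i), c is proportional to S^-1 (mu0 - wbar) where wbar
    is the n-weighted mean of mu0; contrasts are unit-norm with sign fixed so
    c'mu0 > 0.  For equal group sizes this reduces to the centered,
    normalized mean vector."""
    n = np.asarray(n_per_dose, dtype=float)
    out = []
    for mu0 in mu0_list:
        mu0 = np.asarray(mu0, dtype=float)
        wbar = float(n @ mu0 / n.sum())
        c = n * (mu0 - wbar)
        norm = np.linalg.norm(c)
        if norm == 0:
            raise ValueError("constant candidate mean vector gives a degenerate contrast")
        c = c / norm
        if c @ mu0 < 0:
            c = -c
        out.append(c)
    return np.vstack(out)


def contrast_correlation(contrasts: np.ndarray, n_per_dose: Sequence[int]) -> np.ndarray:
    """Correlation of the contrast statistics: R_mk = c_m'S c_k normalized,
    S = diag(1/n_i)."""
    s = 1.0 / np.asarray(n_per_dose, dtype=float)
    g = contrasts @ (contrasts * s).T
    d = np.sqrt(np.diag(g))
    return g / np.outer(d, d)


@lru_cache(maxsize=64)
def _critical_value_cached(
    corr_key: tuple, alpha: float, df: Optional[int]
) -> float:
    m = int(round(math.sqrt(len(corr_key))))
    corr = np.array(corr_key).reshape(m, m)
    if m == 1:
        return float(stats.t.ppf(1 - alpha, df)) if df else float(stats.norm.ppf(1 - alpha))

    target = 1.0 - alpha

    def cdf(q: float) -> float:
        x = np.full(m, q)
        if df:
            return float(
                stats.multivariate_t.cdf(
                    x, loc=np.zeros(m), shape=corr, df=df,
                    maxpts=1_000_000, random_state=987654321,
                )
            )
        return float(
            stats.multivariate_normal.cdf(
                x, mean=np.zeros(m), cov=corr, abseps=1e-7, releps=0.0
            )
        )

    lo = float(stats.norm.ppf(target)) - 0.5
    hi = (
        float(stats.t.ppf(1 - alpha / m, df))
        if df
        else float(stats.norm.ppf(1 - alpha / m))
    ) + 0.5
    return float(optimize.brentq(lambda q: cdf(q) - target, lo, hi, xtol=5e-5))


def mct_critical_value(
    contrasts: np.ndarray,
    n_per_dose: Sequence[int],
    alpha_mct: float,
    df: Optional[int],
) -> float:
    """Equicoordinate (1 - alpha) quantile of the maximum of the correlated
    contrast t statistics (``df=None`` for the normal limit).  Numerically
    identical contrasts are de-duplicated before inverting the joint CDF."""
    corr = contrast_correlation(np.atleast_2d(contrasts), n_per_dose)
    keep: List[int] = []
    for i in range(corr.shape[0]):
        if not any(abs(corr[i, j] - 1.0) < 1e-12 for j in keep):
            keep.append(i)
    corr = corr[np.ix_(keep, keep)]
    return _critical_value_cached(tuple(corr.ravel()), float(alpha_mct), df)


def run_mct(
    means: np.ndarray,
    contrasts: np.ndarray,
    n_per_dose: Sequence[int],
    critical_value: float,
    *,
    pooled_variance: Optional[float] = None,
    mean_variances: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, Optional[int]]:
    """Contrast t statistics and proof-of-concept decision.

    Continuous: t_m = c_m'Ybar / sqrt(s2 * c_m'S c_m) with S = diag(1/n_i).
    Binary (logit scale): per-dose variances of the empirical logits replace
    s2/n_i.  Returns (t statistics, significant mask, selected model index or
    None); the best model is the largest t among significant contrasts, ties
    broken toward the lowest index."""
    c = np.atleast_2d(contrasts)
    if pooled_variance is not None:
        s = pooled_variance / np.asarray(n_per_dose, dtype=float)
    elif mean_variances is not None:
        s = np.asarray(mean_variances, dtype=float)
    else:
        raise ValueError("need pooled_variance or mean_variances")
    denom = np.sqrt((c * c * s).sum(axis=1))
    tstats = (c @ means) / denom
    sig = tstats > critical_value
    if not sig.any():
        return tstats, sig, None
    best = int(np.argmax(np.where(sig, tstats, -np.inf)))
    return tstats, sig, best


# ---------------------------------------------------------------------------
# model fitting and minimum effective dose


def _curve(family: str, d: np.ndarray, params: np.ndarray) -> np.ndarray:
    if family == "linear":
        e0, b = params
        return e0 + b * d
    if family == "quadratic":
        e0, b1, b2 = params
        return e0 + b1 * d + b2 * d * d
    if family == "emax":
        e0, emax, ed50 = params
        return e0 + emax * d / (ed50 + d)
    if family == "sigmoid_emax":
        e0, emax, ed50, h = params
        with np.errstate(divide="ignore"):
            return e0 + np.where(d > 0, emax * d**h / (ed50**h + d**h), 0.0)
    if family == "exponential":
        e0, b, rate = params
        return e0 + b * np.expm1(d / rate)
    raise ValueError(family)


def fit_dose_response(
    family: str,
    doses: np.ndarray,
    means: np.ndarray,
    weights: np.ndarray,
    model: DoseResponseModelSpec,
) -> Tuple[np.ndarray, bool]:
    """Weighted least-squares fit of one family to dose-group means, with
    bounded nonlinear parameters (ED50 in [doses[1]/100, 100 * top dose],
    Hill in [0.5, 10]).  Linear and quadratic are solved exactly; returns
    (parameters, converged)."""
    d = np.asarray(doses, dtype=float)
    y = np.asarray(means, dtype=float)
    w = np.sqrt(np.asarray(weights, dtype=float))
    d_max = float(d.max())

    if family == "linear":
        X = np.column_stack([np.ones_like(d), d])
        beta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        return beta, True
    if family == "quadratic":
        X = np.column_stack([np.ones_like(d), d, d * d])
        beta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        return beta, True

    lo_shape = d[1] / 100.0
    hi_shape = 100.0 * d_max
    span = float(y.max() - y.min()) or 1.0
    amp_lo, amp_hi = -10.0 * span - 1.0, 10.0 * span + 1.0

    if family == "emax":
        p0 = [y[0], y[-1] - y[0], model.ed50 or d_max / 4]
        lb = [-np.inf, amp_lo, lo_shape]
        ub = [np.inf, amp_hi, hi_shape]
    elif family == "sigmoid_emax":
        p0 = [y[0], y[-1] - y[0], model.ed50 or d_max / 4, model.hill or 1.0]
        lb = [-np.inf, amp_lo, lo_shape, 0.5]
        ub = [np.inf, amp_hi, hi_shape, 10.0]
    elif family == "exponential":
        p0 = [y[0], y[-1] - y[0], model.rate or d_max / 2]
        lb = [-np.inf, amp_lo, lo_shape]
        ub = [np.inf, amp_hi, hi_shape]
    else:
        raise ValueError(family)
    p0 = np.clip(p0, lb, ub)

    def resid(p: np.ndarray) -> np.ndarray:
        return w * (_curve(family, d, p) - y)

    try:
        res = optimize.least_squares(resid, p0, bounds=(lb, ub), max_nfev=200)
        return res.x, bool(res.success)
    except Exception:
        return np.asarray(p0, dtype=float), False


def med_from_curve(
    family: str,
    params: np.ndarray,
    delta: float,
    d_max: float,
    benefit_sign: float = 1.0,
    tol: float = 1e-4,
) -> Optional[float]:
    """Smallest dose in (0, d_max] whose predicted effect over placebo
    reaches ``delta`` in the beneficial direction; ``None`` when no dose in
    range qualifies.  Located by a dense grid scan refined by bisection."""
    grid = np.linspace(0.0, d_max, 2001)
    eff = benefit_sign * (_curve(family, grid, params) - _curve(family, np.array([0.0]), params)[0])
    hit = np.nonzero(eff >= delta)[0]
    hit = hit[grid[hit] > 0]
    if hit.size == 0:
        return None
    i = int(hit[0])
    lo, hi = grid[max(i - 1, 0)], grid[i]

    def f(x: float) -> float:
        return float(
            benefit_sign
            * (_curve(family, np.array([x]), params)[0] - _curve(family, np.array([0.0]), params)[0])
            - delta
        )

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# replicate simulation, signal criteria, consistency


@dataclass
class McpmodReplicate:
    means_all: np.ndarray  # analysis scale (raw means, or empirical logits)
    means_region: np.ndarray
    tstats: np.ndarray
    poc: bool
    selected: Optional[int]
    signal: bool
    med: Optional[float] = None
    fit_fallback: bool = False
    consistency: Optional[bool] = None
    extras: dict = field(default_factory=dict)


def region_n_per_dose(n_per_dose: Sequence[int], fraction: float) -> List[int]:
    """Regional per-dose sizes, ceiling(fraction * n_i) - the same rounding
    convention as the overall regional size derivation."""
    return [int(math.ceil(fraction * n)) for n in n_per_dose]


def empirical_logit(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Shrunk empirical logit logit((x + 0.5)/(n + 1)), finite at 0 and n."""
    p = (x + 0.5) / (n + 1.0)
    return np.log(p / (1.0 - p))


def contrast_consistency(
    means_region: np.ndarray,
    means_all: np.ndarray,
    contrast: np.ndarray,
    pi: float,
) -> Optional[bool]:
    """Regional-to-overall contrast ratio criterion
    (sum c*_i Ybar_i^R) / (sum c*_i Ybar_i) > pi, literal evaluation;
    ``None`` when the overall contrast is zero."""
    denom = float(contrast @ means_all)
    if denom == 0.0:
        return None
    return float(contrast @ means_region) / denom > pi


def signal_criterion(
    *,
    poc: bool,
    means_all: np.ndarray,
    signal_type: int,
    delta: Optional[float],
    med: Optional[float],
    d_max: float,
    benefit_sign: float = 1.0,
) -> bool:
    """Three nested definitions of a significant overall dose-response
    signal: (1) proof of concept; (2) additionally an observed effect over
    placebo beyond delta at some active dose; (3) additionally a modelled
    minimum effective dose inside the designed dose range."""
    if signal_type == 1:
        return poc
    if delta is None:
        raise ValueError("signal types 2 and 3 require delta")
    effects = benefit_sign * (means_all[1:] - means_all[0])
    type2 = poc and bool((effects > delta).any())
    if signal_type == 2:
        return type2
    if signal_type == 3:
        return type2 and med is not None and 0 < med <= d_max
    raise ValueError(f"signal_type must be 1, 2 or 3, got {signal_type}")


def simulate_mcpmod(
    spec: McpmodSpec,
    endpoint: str,
    fraction: float,
    rng: np.random.Generator,
    *,
    contrasts: Optional[np.ndarray] = None,
    critical_value: Optional[float] = None,
    pi: float = 0.5,
    true_means: Optional[np.ndarray] = None,
) -> McpmodReplicate:
    """One replicate of the dose-finding trial with a regional subset.

    Continuous: per-dose sample means are drawn for the region and
    rest-of-world strata (normal, variance sd^2/n) and combined by size;
    the pooled residual variance is drawn from its scaled chi-square law.
    Binary: per-stratum responder counts are binomial and the analysis runs
    on shrunk empirical logits.  The contrast test, best-model selection, MED
    prediction and the consistency criterion are evaluated on the overall
    data; the selected model's contrast is reused for the region."""
    doses = np.asarray(spec.doses, dtype=float)
    n = np.asarray(spec.n_per_dose, dtype=int)
    d_max = float(doses.max())
    df = int(n.sum() - len(doses))
    benefit_sign = 1.0 if spec.emax_effect >= 0 else -1.0

    if true_means is not None:
        mu = np.asarray(true_means, dtype=float)
    else:
        true_model = spec.candidate_models[spec.true_model_index]
        mu = model_means(true_model, doses, spec.e0, spec.emax_effect)
    if endpoint == "binary" and ((mu <= 0) | (mu >= 1)).any():
        raise ValueError("true response rates must lie in (0, 1)")

    if contrasts is None:
        mu0 = [
            model_means(m, doses, spec.e0, spec.emax_effect)
            for m in spec.candidate_models
        ]
        if endpoint == "binary":
            mu0 = [np.log(v / (1 - v)) for v in mu0]
        contrasts = optimal_contrasts(mu0, n)
    if critical_value is None:
        critical_value = mct_critical_value(
            contrasts, n, spec.alpha_mct, df if endpoint == "continuous" else None
        )

    n_r = np.asarray(region_n_per_dose(n, fraction), dtype=int)
    n_row = n - n_r

    if endpoint == "continuous":
        sd = spec.sd
        mean_r = mu + rng.standard_normal(len(n)) * sd / np.sqrt(n_r)
        noise_row = rng.standard_normal(len(n)) * sd / np.sqrt(np.maximum(n_row, 1))
        mean_row = np.where(n_row > 0, mu + noise_row, 0.0)
        means_all = (n_r * mean_r + n_row * mean_row) / n
        s2 = sd**2 * rng.chisquare(df) / df if sd > 0 else 0.0
        tstats, sig, selected = run_mct(
            means_all, contrasts, n, critical_value, pooled_variance=max(s2, 1e-300)
        )
        means_region = mean_r
        fit_means, fit_weights = means_all, n
    else:
        x_r = rng.binomial(n_r, mu)
        x_row = rng.binomial(n_row, mu)
        x = x_r + x_row
        means_all = empirical_logit(x, n)
        means_region = empirical_logit(x_r, n_r)
        v = 1.0 / (x + 0.5) + 1.0 / (n - x + 0.5)
        tstats, sig, selected = run_mct(
            means_all, contrasts, n, critical_value, mean_variances=v
        )
        fit_means, fit_weights = means_all, 1.0 / np.maximum(v, 1e-12)

    poc = selected is not None

    med = None
    fallback = False
    if poc and spec.delta is not None:
        fam = spec.candidate_models[selected].family
        params, ok = fit_dose_response(
            fam, doses, fit_means, fit_weights, spec.candidate_models[selected]
        )
        if not ok:
            fallback = True
        delta_scale = spec.delta
        med = med_from_curve(fam, params, delta_scale, d_max, benefit_sign)

    signal = signal_criterion(
        poc=poc,
        means_all=means_all,
        signal_type=spec.signal_type,
        delta=spec.delta,
        med=med,
        d_max=d_max,
        benefit_sign=benefit_sign,
    )

    consistency = None
    if signal and selected is not None:
        consistency = contrast_consistency(
            means_region, means_all, contrasts[selected], pi
        )

    return McpmodReplicate(
        means_all=means_all,
        means_region=means_region,
        tstats=tstats,
        poc=poc,
        selected=selected,
        signal=signal,
        med=med,
        fit_fallback=fallback,
        consistency=consistency,
    )
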