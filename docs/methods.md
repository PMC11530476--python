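# Methods

This note documents the statistical model behind `regionsizer`, the
parameters it exposes, the numerical conventions it adopts, and the design
decisions that were genuinely open.

## 1. Problem and model

A multi-regional clinical trial (MRCT) is designed once, globally: a total
sample size `n_total`, an allocation ratio, a significance level α, and a
test appropriate to the endpoint. A planner then asks: *if one region
contributes a given share of that trial, how likely is the region's own
estimate to look consistent with the overall result?* Because the regional
estimate is a noisy subsample of the same data that produces the overall
estimate, the two are correlated and the question has no general closed
form; the package answers it by Monte Carlo.

Each replicate:

1. simulates individual outcomes for the full trial under the assumed
   effects;
2. marks which participants belong to the region and which enter the global
   analysis set (these can differ, see joining strategies);
3. computes the overall estimate θ̂_All, its significance, and the regional
   estimate θ̂_R;
4. evaluates the consistency criterion.

Aggregating over replicates gives the **unconditional** probability
Pr(criterion) and the **conditional** probability Pr(criterion | overall
significance). Replicates where a criterion is not evaluable (a zero
denominator, see §4) are excluded from both numerator and denominator and
their count is reported.

### Consistency criteria

With preservation fraction π (default 0.5, the conventional "half the
effect" reading of preservation-of-effect):

- continuous/binary superiority: θ̂_R > π·θ̂_All, with θ̂ oriented so that
  benefit is positive (the beneficial direction is inferred from the
  assumed effects);
- continuous/binary non-inferiority with margin Δ: the margin-shifted ratio
  (θ̂_R ∓ Δ)/(θ̂_All ∓ Δ) > π, the sign chosen by whether higher responses
  are worse or better;
- time-to-event superiority: two conventions are reported side by side,
  log(HR_R)/log(HR_All) > π and (1 − HR_R)/(1 − HR_All) > π, because both
  are in regulatory use and they can disagree for the same data;
- time-to-event non-inferiority with margin Δ (an upper HR bound):
  (log HR_R − log Δ)/(log HR_All − log Δ) > π and
  (1 − HR_R/Δ)/(1 − HR_All/Δ) > π.

All criteria use strict inequality and are evaluated literally on the
estimates — no sign gating beyond what the formula itself implies. The
conditional probability additionally requires the overall test to pass:
two-sided p < α *and* the estimate pointing in the beneficial direction for
superiority; a (1 − α) two-sided confidence bound clearing the margin for
non-inferiority (equivalently a one-sided α/2 test).

### Joining strategies

- **complete**: every regional participant is in the global analysis set;
  the rest of the world (ROW) contributes `n_total − n_region`.
- **partial(q)**: only `round(q · n_region)` regional participants enter
  the global set; ROW is topped up so the global set still totals
  `n_total`. The regional estimate still uses all regional participants.
- **excluded**: the region is run in parallel and contributes nothing to
  the global set (ROW alone totals `n_total`).

Regional sample sizes are derived from percentages as
`ceil(n_total · pct / 100)` — rounding up so the region never undershoots
its nominal share. Within any group of size n at ratio r:1, the
experimental arm gets `floor(n·r/(r+1) + 0.5)` participants (round half
toward the experimental arm).

## 2. Endpoints and generators

- **Continuous**: normal outcomes per arm with user-specified means and
  SDs; effect = difference in means; pooled-variance two-sample t-test.
- **Binary**: Bernoulli outcomes; effect = risk difference; Pearson χ²
  without continuity correction. Expected cell counts below 5 are flagged
  and their frequency reported per run, since the χ² approximation degrades
  there.
- **Time-to-event**: exponential event times in both arms (control hazard
  from a median or a yearly event rate via λ = ln 2/median or
  λ = −ln(1 − rate)/12; experimental hazard = λ·HR). Staggered entry
  follows a uniform or custom monthly accrual schedule (the region may have
  its own, possibly delayed schedule). The analysis cutoff is event-driven:
  the calendar time of the target-th event among globally analyzed
  participants, with administrative censoring at that time; participants
  not yet enrolled at cutoff are dropped and counted. The effect is the
  log hazard ratio from a two-group Cox partial likelihood; significance
  from the log-rank test. Reported alongside: mean time to reach the event
  target and mean median follow-up, which planners need for timelines.

What the generator deliberately does *not* emulate: dropout and
non-administrative censoring, non-proportional hazards, covariates,
region-by-treatment interaction (regions share the same true effect —
consistency probabilities here quantify pure sampling noise, which is the
planning question), interim analyses, and over-running accrual. These are
the standard idealizations for design-stage calculations; §6 returns to
them.

## 3. MCP-Mod dose-finding designs

For a dose-finding trial analyzed by MCP-Mod, "the overall result" is a
dose-response signal rather than a two-arm contrast, so the machinery
changes:

- Candidate curves (linear, Emax, sigmoid Emax, quadratic, exponential) are
  **anchored**: each passes through (0, E0) and attains E0 + `emax_effect`
  at the top dose, so all candidates share the same placebo response and
  the same maximal effect and differ only in shape. The quadratic's shape
  parameter defaults to δ = −1/(2·d_max), placing its peak at the top dose.
- Optimal contrasts maximize the non-centrality under each candidate:
  c ∝ nᵢ(μ⁰ᵢ − μ̄), unit-normalized, signed so c·μ⁰ > 0; duplicate
  contrasts are de-duplicated. The max-contrast test compares
  max tᵢ against the equicoordinate critical value of the multivariate t
  distribution with the contrast correlation matrix (one-sided α_MCT,
  default 0.025).
- Simulation works on group sufficient statistics (dose-group means for the
  region and ROW strata, pooled variance ~ σ²χ²_df/df) rather than subject
  level, which is exact for normal outcomes and fast. Binary dose-finding
  works on shrunken empirical logits logit((x+½)/(n+1)) with variances
  1/(x+½) + 1/(n−x+½) and the normal-limit critical value.
- Regional consistency is contrast-based: Σc*ᵢȲᵢᴿ / Σc*ᵢȲᵢ > π using the
  contrast selected overall (largest t-statistic; ties to the lowest
  index). Only the conditional probability is reported — an unconditional
  version would condition consistency on a contrast that was never
  selected.
- Three nested signal definitions are available: (1) proof of concept (any
  contrast significant); (2) PoC and the best fitted model attains a
  clinically relevant effect Δ within the dose range; (3) additionally the
  minimum effective dose (MED) is estimable. Power is reported for the
  chosen definition; nesting guarantees power(3) ≤ power(2) ≤ power(1)
  replicate-by-replicate.
- The MED is the smallest dose whose fitted mean exceeds E0 + Δ, obtained
  by inverting the best fitted curve (grid of 2001 points plus bisection to
  tolerance 1e-4 in dose units).

## 4. Numerical conventions

- **Degenerate inputs.** Zero pooled variance in the t-test yields p = NaN
  (treated as non-significant). A degenerate 2×2 margin (no responders or
  all responders) yields p = 1 with the low-cell flag. If one arm has no
  events, the Cox Newton iteration diverges; the estimate falls back to
  the score approximation exp((O−E)/V) and is flagged. If the log-rank
  variance is zero (the arms are never concurrently at risk at an event
  time), no hazard ratio is estimable and NaN is returned. A zero
  denominator in any consistency ratio makes that replicate not evaluable
  (excluded and counted) rather than forcing a truth value.
- **Cox fit.** Two-group Newton–Raphson on the Breslow partial likelihood,
  steps clipped to ±2 on the log scale, convergence at |score step|
  < 1e-12. The log-rank and Cox computations share one risk-set sweep
  (unique event times + reverse cumulative sums), which keeps a replicate
  near 1 ms and 5,000-replicate runs in seconds.
- **Multivariate t critical value.** Solved by Brent's method (xtol 5e-5)
  on the equicoordinate CDF, which is evaluated by `scipy`'s
  quasi–Monte Carlo integration with a fixed internal `random_state` so
  the value is deterministic; cached per (correlation, df, α). The CDF
  noise is ~1e-5, far below any power or consistency resolution at the
  replicate counts used.
- **Dose-response fitting.** Linear and quadratic by exact least squares;
  Emax-type by bounded `least_squares` (ED50 ∈ [d₁/100, 100·d_max],
  Hill ∈ [0.5, 10]); non-converged fits fall back to the candidate's
  anchored curve and are counted.
- **Reproducibility.** All randomness derives from one integer seed via
  `numpy.random.SeedSequence` with spawn key (percentage index, replicate),
  so every percentage's result is independent of which other percentages
  run alongside it, and a run is bit-reproducible. Re-running one
  percentage alone reproduces its row from a full run exactly.

## 5. Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| π (preservation fraction) | 0.5 | the conventional "half the overall effect" consistency reading |
| α (overall test) | 0.05 two-sided | standard confirmatory level; NI uses the equivalent one-sided α/2 |
| α_MCT | 0.025 one-sided | standard for MCP-Mod proof of concept |
| allocation ratio | 1:1 | most common; any r:1 supported globally and regionally |
| joining | complete | the default MRCT reading: the region is part of the trial |
| n_sims | 10,000 | Monte-Carlo SE of a probability ≤ 0.005, below planning resolution; runs in ~20 s for the 554-participant example on one CPU |
| quadratic δ | −1/(2·d_max) | peak at the top dose, the natural anchored shape |
| TTE rate convention | yearly rate over 12 months | matches how event rates are quoted in protocols |

Problem sizes are the package's own choice: it is built for design-stage
trials of tens to a few thousand participants, a handful of region
percentages per run, and 10³–10⁵ replicates; nothing in the implementation
targets larger scales.

## 6. Validation and limitations

The primary correctness check is analytical: for continuous superiority
with complete inclusion the unconditional consistency probability has the
closed form Φ((1−π)·θ / √(Var_R + (π² − 2π)·Var_All)) (using
Cov(θ̂_R, θ̂_All) = Var_All for a subsample). The test suite requires the
10,000-replicate simulation to match this within one percentage point at
every percentage, and `scripts/acceptance.py` recomputes the maximum
discrepancy for any seed. The suite also checks type-I error calibration
of every overall test under its null, trivial limits (a 100% region is
always conditionally consistent; a noiseless MCP-Mod run always succeeds
and recovers the true MED), hand-computed small fixtures, and cross-checks
against `scipy` and `lifelines`.

Known limitations:

- Consistency probabilities quantify sampling variability only; a true
  region-by-treatment interaction is outside the model (by design — this
  is the planning baseline against which observed inconsistency is
  judged).
- Exponential survival and proportional hazards are assumed; heavy
  departures change both the event-driven timelines and the HR criteria.
- The χ² test's small-sample behaviour is flagged, not corrected; for very
  small regions an exact test would differ.
- Binary MCP-Mod relies on the empirical-logit normal approximation, which
  is rough below ~10 subjects per dose per stratum.
- The conditional probability is reported as empty when no replicate
  reaches overall significance; it is then simply not estimable at the
  chosen replicate count.
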