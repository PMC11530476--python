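# regionsizer

Monte-Carlo planning of **regional sample sizes in multi-regional clinical
trials (MRCTs)**.

When a single trial enrolls across regions under one protocol, regulators
(in the spirit of ICH E17's preservation-of-effect thinking) often ask how
likely a region of a given size is to show a treatment effect *consistent*
with the overall result. `regionsizer` answers that question by simulation:
it repeatedly simulates the globally designed trial, subsamples a region,
and estimates

- **unconditional consistency**: Pr(θ̂_R > π·θ̂_All) — the regional estimate
  preserves at least a fraction π of the overall estimate;
- **conditional consistency**: the same probability given that the overall
  result is statistically significant,

where θ̂_R and θ̂_All are the regional and overall treatment-effect
estimates and π (default 0.5) is the preservation fraction.

Supported designs and endpoints:

| design | continuous | binary | time-to-event |
|---|---|---|---|
| superiority (t-test / χ² / log-rank) | ✓ | ✓ | ✓ (log-HR and risk-reduction criteria) |
| non-inferiority (margin Δ, direction-aware) | ✓ | ✓ | ✓ (margin-shifted criteria) |
| MCP-Mod dose finding (contrast-based, conditional only) | ✓ | ✓ (logit scale) | — |

For hazard ratios two consistency conventions are reported side by side,
log(HR_R)/log(HR_All) > π and (1−HR_R)/(1−HR_All) > π (margin-shifted
versions for non-inferiority). For MCP-Mod the criterion is the ratio of the
regional to the overall optimal-contrast value, Σc*ᵢȲᵢᴿ / Σc*ᵢȲᵢ > π,
conditional on a significant overall dose-response signal.

Time-to-event designs support uniform or custom monthly accrual (with a
separate, possibly delayed regional schedule), event-driven analysis at a
target event count, and administrative censoring. Regions can be completely
included in, partially included in, or completely excluded from the global
analysis set.

## Worked example

The bundled template reproduces a 554-participant continuous superiority
design: 1:1 allocation, two-sided α = 0.05, experimental mean 3.5 vs control
4.5 (SD 2.5 in both arms, lower is better), regions of 10–30% of the trial,
π = 0.5.

```bash
regionsizer init superiority continuous --out cfg.json
regionsizer check cfg.json
regionsizer run cfg.json --out results.csv --plot plot.png --sims 10000 --seed 20240808
```

The result table (`results.csv`) contains one row per subpopulation
percentage. With the settings above:

| subpop % | n_region | power | uncond. consistency | cond. consistency |
|---|---|---|---|---|
| 10 | 56  | 0.9977 | 0.7803 | 0.7811 |
| 15 | 84  | 0.9966 | 0.8315 | 0.8323 |
| 20 | 111 | 0.9965 | 0.8767 | 0.8772 |
| 25 | 139 | 0.9970 | 0.9100 | 0.9102 |
| 30 | 167 | 0.9967 | 0.9321 | 0.9331 |

Reading: a region contributing 15% of the trial (84 participants) has about
an 83% chance of retaining at least half of the overall estimated effect;
the overall design itself has 99.7% power, so conditioning on overall
significance barely moves the probabilities. For this design the
unconditional probability also has a normal-theory closed form
Φ((1−π)θ / √(Var_R + (π²−2π)·Var_All)); the simulation above agrees with it
to well under one percentage point at every percentage, which is the
package's primary validation check.

The same workflow drives the other designs (`regionsizer init mcpmod
continuous`, `... noninferiority tte`, and so on); MCP-Mod runs report the
type-1/2/3 signal power, the conditional contrast-based consistency, and the
median minimum effective dose (MED) when a clinically relevant effect Δ is
given.

As a library:

```python
from regionsizer import load_config, run_study, write_csv
result = run_study(load_config("cfg.json"))
write_csv(result, "results.csv")
```

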