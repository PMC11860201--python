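# mprisk

Probabilistic human-health risk assessment of di(2-ethylhexyl)
phthalate (DEHP) carried by polyvinyl chloride (PVC) microplastics in
groundwater used for drinking.

Groundwater surveys report microplastic loads as particle counts in a
few size classes; translating those counts into a chemical dose
requires the particle **volume**, which depends strongly on shape
(morphology): at the same length, a fragment (ellipsoid), a fiber
(cylinder) and a film (thin box) differ by orders of magnitude in
volume and hence in plasticizer burden. `mprisk` propagates that
diversity probabilistically:

1. **Size spectrum** — fit the abundance-vs-size power law
   `y = b·x⁻ᵅ` per survey site by log–log least squares, aggregate α
   across sites, and build a continuous truncated power-law size
   distribution on 20–5000 μm with analytic CDF/quantile
   `F(x) = (x_min^(1−α) − x^(1−α)) / (x_min^(1−α) − x_max^(1−α))`.
2. **Shape → volume** — map sizes to volumes per shape via
   length:width:height aspect-ratio bounds (fragment `4πabc/3`, fiber
   `πr²H`, film `LWH`, sphere), or span a uniform envelope between the
   smallest fiber and largest fragment volume.
3. **Exposure and risk** — two-pathway leaching model
   `C_w = C_mp·(ρV)·R·(L1 + L2)` (mg/L), drinking-water dose
   `ADD = C_w·CR_w·EF·ED/(BW·AT)` (mg/kg-day), hazard quotient
   `HQ = ADD/RfD0` and excess cancer risk `ECR = SF0·ADD`.
4. **Monte Carlo engine** — 50,000 seeded iterations over the published
   input distributions (triangular, truncated-normal, Gumbel-minimum,
   power law), percentile and exceedance summaries, and
   contribution-to-variance sensitivity analysis (normalized squared
   Spearman rank correlations).

The package is aimed at exposure/risk modellers who want a reproducible,
testable version of this assessment — every stage is also generable
synthetically with known ground truth (`mprisk.synthetic_data`), so the
whole pipeline is testable offline.

## Worked example

```python
from mprisk import (SyntheticSurveySpec, generate_survey, fit_power_law,
                    aggregate_alpha, baseline_scenario, run_simulation,
                    percentile, exceedance_probability, sensitivity_analysis)

# 1. fit per-site power laws to (synthetic) survey abundance tables
spec = SyntheticSurveySpec(noise_sd=0.1, seed=7)
fits = [fit_power_law(t) for t in generate_survey(spec)]
mean_a, sd_a = aggregate_alpha(fits)
print(f"aggregate alpha = {mean_a:.2f} +/- {sd_a:.2f}")

# 2. run the baseline 50,000-iteration risk simulation (uniform volume)
cfg = baseline_scenario(n_iterations=50_000, seed=42)
res = run_simulation(cfg)
for r in ("adult", "child"):
    print(f"{r}: ECR95={percentile(res,'ECR',r,0.95):.2e}  "
          f"HQ95={percentile(res,'HQ',r,0.95):.2e}  "
          f"P(ECR>1e-6)={100*exceedance_probability(res,'ECR',r,1e-6):.1f}%")
```

prints

```
aggregate alpha = 1.74 +/- 0.49
adult: ECR95=8.75e-07  HQ95=3.12e-03  P(ECR>1e-6)=3.6%
child: ECR95=2.92e-06  HQ95=1.04e-02  P(ECR>1e-6)=23.3%
```

Reading: the five synthetic sites (true exponents 1.97, 1.81, 0.99,
2.28, 1.62 with 10 % lognormal noise) recover an aggregate size
exponent of 1.74 ± 0.49 — small particles dominate. Under the
conservative uniform-volume scenario, the 95th-percentile excess
cancer risk is below the 10⁻⁶–10⁻⁴ regulatory band for adults and just
inside it for children, while HQ ≪ 1 means no non-carcinogenic concern;
children's values exceed adults' by ≈ 3× because their intake per kg
body weight is higher. Sensitivity analysis
(`sensitivity_analysis(res, "adult")`) attributes 47.7 % of ECR
variance to the particle concentration and 34.3 % to particle volume —
the shape-dependent quantity, which is the point: re-running with
per-shape volume models (`shape_scenario("fragment")`, `"fiber"`,
`"film"`) gives adult 95th-percentile ECRs of 1.43 × 10⁻⁹,
2.94 × 10⁻¹⁰ and 3.83 × 10⁻¹¹ — a ~40-fold spread from morphology
alone.

## Command line

```sh
mprisk example-config scenario.yaml          # write the baseline scenario
mprisk simulate scenario.yaml -o run/        # draws + summary CSVs
mprisk fit-sizes abundance.csv fits.csv      # per-site power-law fits
mprisk sensitivity run/ -o sens.csv
mprisk report run/ -o summaries/
```

Scenario YAML binds one key per model symbol (`C_mp`, `rho`, `R`, `L1`,
`L2`, `CR_w`, `EF`, `ED`, `BW`, `AT`, `RfD0`, `SF0`, the volume model
and the size spectrum); see `docs/methods.md` for the schema semantics,
including the `density_unit` switch.

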