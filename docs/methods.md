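# Methods

`mprisk` implements a probabilistic human-health risk assessment for
di(2-ethylhexyl) phthalate (DEHP) carried by polyvinyl chloride (PVC)
microplastics (MPs) in groundwater used as drinking water. This note
records the model, its assumptions, the parameter choices, and the
numerical and design decisions, in the package's own terms.

## Model

### Exposure concentration

A load of `C_mp` particles per litre, each of volume `V` (μm³) and
density `ρ` (g/cm³), carries DEHP at mass fraction `R` (w/w). Two
independent pathways release that burden into the ingested water:

    C_w = C_w1 + C_w2
    C_w1 = C_mp · (ρ·V) · R · L1      (leaching into groundwater)
    C_w2 = C_mp · (ρ·V) · R · L2      (leaching into digestive fluids)

with `L1`, `L2` the leached fractions of the particle's DEHP burden.
`L1 = 4.37 μg/g ÷ (0.341 · 10⁶ μg/g) ≈ 1.2815 × 10⁻⁵` (≈ 0.0013 %)
derives from a 48-h batch leaching measurement on PVC containing 34.1 %
DEHP; `L2 = 0.25 %` comes from digestive-fluid leaching reported in
prior work. The particle mass ρ·V is converted from (g/cm³ · μm³) to mg
exactly once, inside `exposure_concentration` (1 μm³ = 10⁻¹² cm³), to
preclude double-scaling.

### Dose and risk

    ADD = C_w · CR_w · EF · ED / (BW · AT)      [mg/kg-day]
    HQ  = ADD / RfD0          RfD0 = 0.02 mg/kg-day
    ECR = SF0 · ADD           SF0  = 0.014 (mg/kg-day)⁻¹

Both risk metrics derive from the same ADD, so `ECR = SF0·RfD0·HQ =
2.8 × 10⁻⁴ · HQ` holds per iteration by construction; the test suite
asserts it elementwise. `AT` is taken exactly as tabulated for each
receptor (adults 9125 d over ED = 25 y, children 2190 d over ED = 6 y)
for **both** HQ and ECR — there is no 70-year lifetime re-averaging for
the carcinogenic metric, which departs from common regulatory practice
but matches the source assessment; users wanting lifetime-averaged ECR
can set `AT` accordingly in the scenario.

### Particle size

Survey abundance tables (% of particles per size class, each class
labelled by its largest particle size x in μm) follow a power law
`y = b·x^-α`. Per site, α is estimated by ordinary least squares on
(ln x, ln y) — the standard "power trendline", with R² reported from
that regression. Zero-abundance classes are dropped (log undefined);
rescaling all abundances only moves `b`, never α. Site exponents are
aggregated by unweighted mean ± sample sd (n−1); the five-site survey
gives 1.73 ± 0.48 from the rounded per-site values. The continuous
spectrum then uses the aggregate α on 20–5000 μm with the bounded CDF

    F(x) = (x_min^(1−α) − x^(1−α)) / (x_min^(1−α) − x_max^(1−α)),

sampled by analytic inversion. The bounded form is valid for any
α ≠ 1 — including a sub-unity site exponent such as 0.99, for which the
unbounded-support normalizer `b = (α−1)·x_min^(α−1)` does not exist
(the package stores NaN for `b` in that case and never uses it for
sampling). α = 1 is rejected rather than special-cased; observed
exponents do not hit it.

### Shape and volume

Shapes are idealized solids parameterized by the longest dimension L
and dimensionless width and height ratios W/L, H/L ∈ (0, 1]:

- fragment: ellipsoid, (4π/3)(L/2)(W/2)(H/2)
- fiber: cylinder of radius W/2 and length L, π(W/2)²L
- film: hexahedron, L·W·H
- sphere: (4π/3)(L/2)³

Per-shape volume distributions map power-law size draws through these
formulas with ratios fixed at each shape's **upper** bounds (the
configuration under which the shape-resolved risks were computed; the
sphere is then redundant because its volume equals the fragment's).
Uniform sampling of ratios within bounds is available as
`ratio_policy="uniform"`.

**Ratio table.** The packaged default
(`src/mprisk/data/default_shape_ratios.csv`) is a package-constructed
table, not a transcription: the survey-derived table used in the
original assessment is only available in a supplement we do not
redistribute. The defaults are pinned by internal constraints — the
fragment upper bounds must be (1, 1) to make the sphere redundant, and
the fiber (W/L ≤ 0.37) and film (H/L ≤ 0.014) upper bounds are set so
the max-ratio volume coefficients are spaced like the reported
shape-resolved risk ratios (fragment : fiber : film ≈ 1 : 1/4.9 : 1/37.6)
— with field-plausible lower bounds. Any alternative table can be
supplied as a CSV with the same columns.

**Uniform envelope.** The headline scenario replaces the per-shape
volume model with a uniform distribution between the smallest fiber
volume and the largest fragment volume. Whether that envelope is global
(fiber at 20 μm with minimum ratios → fragment at 5000 μm with maximum
ratios) or conditional on the sampled size is ambiguous in the source;
both are implemented (`uniform_envelope`, `size_conditional_envelope`)
and the global reading is the default, consistent with the source's own
remark that the uniform treatment overestimates risk. No claim is made
that either mode is exactly the original computation.

### Monte Carlo engine

50,000 iterations by default, simple random sampling (no Latin
hypercube — matching the referenced spreadsheet tool's default), all
inputs independent, one seeded `numpy` generator consumed in a fixed
draw order, so a scenario is bit-reproducible. Adults and children
share the concentration-side draws and the exposure-frequency draw
within an iteration (common random numbers), so receptor contrasts are
not inflated by sampling noise; water intake and body weight are drawn
per receptor. Quantiles use linear interpolation between order
statistics (`numpy.quantile` default); exceedance probabilities count
iterations strictly above the threshold.

Input distributions of the baseline scenario:

| symbol | distribution | values | unit |
|---|---|---|---|
| C_mp | triangular | 0 / 0 / 79.23 | particles/L |
| ρ | triangular | 1.10 / 1.34 / 1.58 | see below |
| R | minimum extreme | mode 0.29, scale 0.08, truncated to (0, 1] | w/w |
| V | scenario volume model | — | μm³ |
| L1, L2 | point | 1.2815 × 10⁻⁵, 2.5 × 10⁻³ | — |
| CR_w | normal, truncated at 0 | adult 1.95 ± 0.64, child 1.25 ± 0.57 | L/day |
| EF | triangular | 180 / 345 / 365 | days/yr |
| ED, AT | point | adult 25 y / 9125 d, child 6 y / 2190 d | — |
| BW | normal, truncated at 0 | adult 70 ± 14, child 16.67 ± 5.987 | kg |

Choices the source leaves open, made here once:

- **Minimum extreme** is the Gumbel distribution for minima with
  location = mode, pdf `(1/β)·e^((x−μ)/β)·e^(−e^((x−μ)/β))`; mean =
  mode − γβ (γ the Euler–Mascheroni constant). Because R is a mass
  fraction, its unbounded left tail is truncated to (0, 1] by
  resampling (≈ 2.6 % of parent mass removed at these parameters).
- **Normals are truncated at 0** by resampling; the child body-weight
  normal (16.67 ± 5.987) has ≈ 0.27 % negative mass, the others less.
  Resampling (rejection) is used rather than inverse-CDF truncation so
  the draws are literally "redrawn until physical", and is
  distributionally identical.
- **ρ's triangular has no stated mode**; the midpoint 1.34 is used
  (symmetric triangular, the minimal assumption for a bare range).

### Density unit

The tabulated PVC density range 1.10–1.58 is printed with the unit
mg/cm³. Physically PVC density is on the g/cm³ scale, and the package's
core equation takes ρ in g/cm³. However, propagating the distributions
above with ρ read as g/cm³ yields risk percentiles ~1.4 × 10³ times the
published ones, while taking the printed unit literally (mass in mg =
ρ · V with V in cm³) lands within a factor ≈ 1.4 of every published
percentile. `ScenarioConfig.density_unit` therefore supports both
readings, and `baseline_scenario()` uses `"mg/cm3"` so that the
published computation is what the package reproduces by default. Users
assessing physical risk (rather than reproducing the published numbers)
should set `density_unit="g/cm3"` and expect proportionally higher
values.

### Sensitivity analysis

Contribution to variance in the convention of spreadsheet Monte Carlo
tools: for each varying input, the Spearman rank correlation r with the
per-iteration ECR; contributions are `100·r²/Σr²`, signed by r, so
absolute contributions sum to 100 %. Constant inputs report 0. For
per-shape scenarios the sampled volume enters as a single input (not
size and ratios separately). Rank correlations are invariant under
monotone transforms of an input's scale, which the tests assert.

Under the uniform-volume scenario this reproduces the published shares
(volume ≈ 33 % vs published 32.4 % for adults, ≈ 29 % vs 28.6 % for
children, with concentration first and DEHP content third). Under the
per-shape scenarios it does **not** reproduce the published ≈ 40 %
volume shares: a power-law volume (∝ L³, heavy-tailed) dominates the
variance and contributes ≈ 84 % here. No configuration of this model
yields ≈ 40 % for the per-shape case; the discrepancy is reported, not
tuned away.

## Synthetic data

`generate_abundance_table` emulates a survey site: class abundances
proportional to the size spectrum evaluated at each class's upper edge
(the same abscissa the log-log fit uses), multiplied by lognormal(0, σ)
noise and renormalized to 100 %. With σ = 0 the table is an exact power
law and fitting recovers α to machine precision; with σ = 0.1 the
recovery is unbiased (mean error < 0.05 over 100 seeds). A
`bin_integrated=True` option instead integrates the spectrum over each
class — closer to how counts arise physically — but regressing
integrated masses of wide classes against their upper edges biases α̂
low by ≈ 1.2 on the default edges {20, 45, 100, 500, 1000, 5000} μm;
the bias is measured in the test suite rather than hidden, and the
point-evaluated form is the default precisely because the package uses
the generator for parameter-recovery testing. What the synthetic tables
do **not** emulate: detection-limit censoring of small sizes, counting
(Poisson) noise, inter-class correlation, or site-specific bin schemes —
so passing recovery tests demonstrates correctness of the estimator,
not robustness to real survey pathologies.

`generate_particle_population` draws sizes from the spectrum, shapes
multinomially from a mix, and volumes from the ratio table; it feeds
distributional tests (KS of sizes against the analytic CDF, binomial
counts of shapes).

## Problem sizes and tolerances

Simulations in tests and in the acceptance script use the full 50,000
iterations (each run takes well under a second); distributional
goodness-of-fit tests use 10⁵ draws with a KS-statistic threshold of
0.01; the quantile∘CDF identity is checked to 10⁻⁹; deterministic
compositions to 10⁻¹² relative. The aggregate-exponent check allows
±0.01 because the five per-site inputs are themselves rounded to two
decimals (their mean is 1.734; rounding slack of the inputs propagates
±0.005 to the mean).

## Known limitations

- The aspect-ratio table is reconstructed, not transcribed; per-shape
  absolute volumes (and hence per-shape risks) inherit that uncertainty,
  though orderings and ratios are pinned.
- The remaining ≈ 1.4× overshoot of the published percentiles under the
  literal density unit is unexplained (plausibly the original envelope
  bounds or ratio values); all reproduced stochastic values should be
  read at order-of-magnitude precision.
- Inputs are independent; no correlation structure, no variance
  reduction, no separation of variability from uncertainty (2-D Monte
  Carlo).
- Ingestion of groundwater is the only route (no dermal/inhalation),
  DEHP does not degrade, and the dissolved pathway scales with the same
  particle concentration as the particulate one, exactly as the
  exposure equations are written.
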