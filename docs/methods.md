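# Methods

## The closed-loop experiment and what the markers measure

An in situ closed loop is a ligated intestinal segment (10 cm of jejunum or
ileum, 7 cm of colon) filled with 1 mL of test solution and recovered in
full at a single time point. Sampling is destructive: each animal
contributes exactly one (region, time) observation, so time courses are
cross-animal means and all animal-level inference must respect that design.

Two markers are dosed in separate animals:

* **FD-4**, non-absorbable, 10 µM in 1 mL (0.01 µmol). The marker amount is
  conserved, so the total luminal volume is its dilution,
  `V_app = X_out/C_out` (µmol/µM = L, reported in mL). Runs with FD-4
  recovery below 80%, blood-contaminated samples, or inadequate loop
  lengths are excluded; tracer runs are never excluded on recovery because
  recovered activity *is* the measurement.
* **[³H]water**, 1 µCi/mL. Labelled and unlabelled water exchange freely,
  so the luminal tracer concentration stays at the dosing concentration and
  the recovered activity divided by it is the volume of administered water
  still in the lumen: `V = X_out/C0`.

## Kinetic model

```
dV_GI/dt = −k_abs·V_GI + k_sec·V_body·(S/S_sum)
```

Assumptions: a single well-mixed luminal compartment; first-order
absorption with the same k_abs for ingested and secreted fluid (required
for the ingested/secreted decomposition to close); a zero-order secretion
input proportional to the body fluid pool and to the loop's share of
intestinal surface area. Parameters and defaults:

| parameter | meaning | default | unit |
|---|---|---|---|
| k_abs | real fluid absorption rate constant | fitted | min⁻¹ |
| k_sec | fluid secretion rate constant | fitted | min⁻¹ |
| V_body | total body fluid volume | 167 | mL |
| S | loop mucosal surface area | 11.2 | cm² |
| S/S_sum | loop share of intestinal surface area | 10/142 | – |
| V0, V_lumen | administered/distribution volume | 1 | mL |
| t_max | upper end of the first-order window | 30 | min |

S_sum is never measured directly; 10/142 is the loop-to-total length ratio,
and the same proportionality is used for the villous blood-flow scaling.
Because k_sec enters only through the product k_sec·V_body·(S/S_sum), its
numerical value is conditional on that ratio; the composite secretion input
rate (mL/min) is exposed alongside it (`secretion_input_rate`). The colon
loop is 7 cm, but the surface-area default is kept at 11.2 cm² for all
regions (the clearance/permeability table is internally consistent with
that choice); per-region overrides are accepted everywhere a surface area
is taken.

With V_body fixed ("constant_body", the default) the model is linear with
the closed form `V_GI = V_ss + (V0−V_ss)e^(−k_abs t)`,
`V_ss = k_sec·V_body·(S/S_sum)/k_abs`. A mass-conserving variant
("conserving_body") integrates the coupled lumen/body pair with LSODA at
rtol 1e-10/atol 1e-12 so that total water is conserved; at the reference
scale (167 mL pool vs 1 mL dose) the two modes differ by at most ~1.4×10⁻³
mL in V_GI over 60 min at the jejunum point estimates, which is why the
closed form is the default. The trajectory decomposition tracks ingested
water remaining (`V0·e^(−k_abs t)`, independent of k_sec), secreted fluid
in the lumen, and cumulative absorbed/secreted volumes; the identity
`V_GI = V_ingested + V_secreted` is exact in constant-body mode.

## Estimation

* **Log-linear rates** (k_abs,app from FD-4, k_abs from tracer): OLS of
  ln(remaining fraction) on time over t ≤ 30 min; k = −slope. The intercept
  is free by default (it absorbs early mixing artifacts); a pinned
  (ln 1 = 0) variant is available. Nonpositive fractions are excluded with
  a logged count; fewer than two distinct usable time points is an error.
* **k_sec**: least squares of the closed form against FD-4 volumes (mL
  scale, unweighted by default; inverse per-time-variance weighting by
  flag), with k_abs fixed at the tracer estimate. The search is a bounded
  scalar minimisation on [0, 1] min⁻¹ (xatol 1e-9); since the SSR is an
  exact quadratic in k_sec, the closed-form linear-LS minimiser is used as
  a polish step, so the result is reproducible to machine-level accuracy
  and independent of any start point. Zero secretion lands exactly on the
  k_sec = 0 boundary.
* **Per-animal rates** for region comparisons: with one observation per
  animal and the intercept at ln 1 = 0, each animal's rate constant is
  identified as −ln(f_i)/t_i. Regions are compared by one-way ANOVA with
  Tukey–Kramer tests on these values. (The original analysis obtained
  animal-level k_abs dispersion through proprietary population-PK/Bayesian
  software; that step is deliberately replaced by this assumption-light
  construction plus the bootstrap below.)
* **Uncertainty**: stratified animal-level bootstrap. Animals are resampled
  with replacement within each time stratum of each marker arm, and the
  k_sec refit in every resample uses that resample's k_abs, so the k_abs
  uncertainty propagates. Two standard small-sample calibration corrections
  are applied (Hesterberg, *Am. Stat.* 2015): resamples draw n−1 animals
  per stratum (the n-of-n bootstrap underestimates within-stratum variance
  by (n−1)/n), and 95% intervals use expanded percentiles with a
  Welch–Satterthwaite effective df computed from per-stratum variances and
  the estimator's linear coefficients. The df correction matters here
  because the log-scale residual variance grows like (σ_k·t)² while the
  slope weights the latest stratum most, so the effective df is ≈5, far
  below the nominal N−2. Monte-Carlo checks (see `validation.py`) put the
  realised coverage of the 95% CIs at ≈92–95% under the reference design.

## Group statistics

One-way ANOVA (F against the F distribution) followed by Tukey–Kramer
pairwise comparisons: `q_ij = |m_i−m_j| / sqrt(MSW/2·(1/n_i+1/n_j))`
referred to the studentized range distribution with k groups and N−k df
(numerical quadrature via `scipy.stats.studentized_range`; with equal n
this reduces to Tukey's HSD). Markers: `**` p<0.01, `*` p<0.05. Degenerate
all-identical input is reported as "no variance" with NaN statistics rather
than an arbitrary p. Animals are treated as independent, which the
destructive design guarantees. Calibration is re-derived at run time:
type-I error over 2000 null simulations and a 10⁵-draw Monte-Carlo
studentized-range null against the analytic p-values.

## Synthetic-data generator

The generator emulates the study design, not the biology: for each
region × marker × time × replicate it draws per-animal (k_abs, k_sec) from
lognormal distributions with median at the configured truth (lognormality
keeps rates positive; the real inter-animal distribution is unknown — only
group sizes and SEMs are reported — so this is an explicit stand-in,
exposed in `GeneratorConfig`), evaluates the noiseless observation from the
closed form (FD-4: total volume; tracer: `V0·e^(−k_abs t)`), and applies
independent multiplicative lognormal measurement noise (median 1) to the
recovered amount and concentration, as both are ratio-scale assay readouts.
Defaults are the reference conditions: three regions with the reference
rate constants, times {5, 10, 20, 30, 60} min, 5 animals per time point
(the reported designs used 3–10), 10% inter-animal and measurement CVs,
1 mL dose. Tracer back-secretion is neglected (the body pool is ~10⁵-fold
larger than the lumen dose, so secreted fluid is effectively tracer-free).
Output is byte-deterministic given the seed.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: osmotically driven flux (the model is
first-order regardless of osmolality), gastric emptying and transit,
anesthesia effects on blood flow, assay calibration error, and any
non-lognormal animal-to-animal structure.

## Numerical and reporting choices

* Volumes are ratios of positive quantities and cannot be negative; a
  defensive clip at 0 (with a logged warning) guards imported data.
* SEM of a single animal is reported as missing, never 0.
* Permeability unit conversion is a single named constant (60 s/min);
  report tables round to 3 significant figures, full precision is kept
  internally.
* The villous-flow comparison uses Q_portal = 32.9 mL/min/kg, villous
  fraction 0.2 and body mass 0.25 kg (0.25 kg, not the 0.23 kg nominal
  purchase weight, reproduces the 0.116 mL/min loop flow; both are
  configurable). Absorption is classified blood-flow-limited when
  CL_abs/Q_villi ≥ 0.5 (configurable threshold).
* Reports are deterministic JSON (sorted keys, no timestamps) carrying a
  config hash and seeds, so identical inputs give byte-identical reports.

## Validation scale

The self-validation experiments run at desk scale: 200 simulated studies
with 200 bootstrap resamples each for recovery/coverage, a 100-point
parameter grid for the solver oracle, 2000 null simulations for ANOVA
calibration and 10⁵ Monte-Carlo draws for the Tukey check — a few seconds
to tens of seconds each on one core.

## Known limitations

* k_sec is identified only jointly with V_body·(S/S_sum); cross-study
  comparisons should use the secretion input rate unless the same ratio is
  used throughout.
* The per-animal single-point rate constants force a zero intercept; if
  early mixing artifacts matter, region comparisons inherit them.
* The model is not spatial (no plug flow), has no osmotic flux term, and
  treats the colon identically to the small intestine apart from its
  constants; permeability-limited colonic absorption under hyperosmotic
  loads is outside its scope.
* With very small strata (2 animals per time point) the Satterthwaite df
  and the bootstrap itself become unreliable; at least 3–5 animals per time
  point are recommended, matching the reference design.
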