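# gifluid

Kinetic analysis of gastrointestinal **luminal fluid dynamics** from in situ
closed-loop experiments.

The volume of fluid in an intestinal segment sets the local concentration of
any dissolved drug, so it is a first-order determinant of oral absorption
kinetics. In the closed-loop design, a ligated loop (rat jejunum, ileum or
colon) is filled with 1 mL of test solution and its entire content is
recovered at one time point per animal. Two markers separate *apparent* from
*real* fluid movement:

* **FD-4** (fluorescein isothiocyanate–dextran 4000) is non-absorbable, so
  its dilution tracks the total luminal volume — the net result of water
  absorption *and* secretion;
* **[³H]water** exchanges freely with luminal water, so its disappearance
  measures real (unidirectional) water absorption.

`gifluid` reconstructs luminal volumes from these markers, fits the rate
constants of a one-compartment kinetic model, converts them into clearances
and effective permeabilities, and compares absorption clearance with villous
blood flow. A synthetic-study generator emulating the destructive sampling
design (one animal, one time point) makes every stage testable without
animal data.

## The model

Luminal fluid volume V_GI in a closed loop follows

```
dV_GI/dt = − k_abs · V_GI + k_sec · V_body · (S/S_sum)
```

with k_abs (min⁻¹) the real fluid absorption rate constant, k_sec (min⁻¹)
the fluid secretion rate constant, V_body the total body fluid pool
(167 mL) and S/S_sum the loop's share of total intestinal surface area
(10/142). With V_body constant the solution is

```
V_GI(t) = V_ss + (V0 − V_ss)·e^(−k_abs·t),   V_ss = k_sec·V_body·(S/S_sum)/k_abs
```

Estimation proceeds in the experiment's own order:

1. **k_abs,app** — log-linear regression of FD-4 remaining fractions over
   t ≤ 30 min (the first-order window);
2. **k_abs** — the same regression on [³H]water remaining fractions;
3. **k_sec** — bounded 1-D least squares of the closed form against FD-4
   volumes, with k_abs fixed at the tracer value;
4. **CL_abs = k_abs·V_lumen** and **P_eff = CL_abs/S** (reported in cm/s);
5. villous blood flow **Q_villi = 0.2·Q_portal**, scaled to the animal and
   loop, against CL_abs (rate-limiting-step classification);
6. uncertainties by a stratified animal-level bootstrap (n−1-of-n resamples
   within each time stratum; expanded-percentile 95% CIs with
   Welch–Satterthwaite effective df), and region comparisons by one-way
   ANOVA with Tukey–Kramer tests.

## Worked example

```python
from gifluid import ClosedLoopStudy, generate_worked_fixture

records = generate_worked_fixture()          # noiseless 30-record study
res = ClosedLoopStudy.from_records(records).fit()
print(res.summary())
```

prints (abridged):

```
region    parameter       estimate ...
colon     k_abs         1.2700e-01
colon     k_sec         7.1000e-04
ileum     k_abs         1.3100e-01
ileum     k_sec         8.7800e-03
jejunum   k_abs         1.3600e-01
jejunum   k_sec         7.0500e-03
------------------------------------------------------------------------
region     CL_abs (mL/min)  P_eff (x1e-4 cm/s)
colon                0.127                1.89
ileum                0.131                1.95
jejunum              0.136                2.02
------------------------------------------------------------------------
villous flow: Q_villi=6.58 mL/min/kg, loop Q_villi=0.116 mL/min
  colon      CL_abs/Q_villi = 1.096 -> blood-flow-limited
```

Reading it: real water absorption is fast and nearly region-independent
(k_abs ≈ 0.13 min⁻¹ everywhere), whereas secretion differs ten-fold between
small intestine and colon (k_sec 7.05 vs 0.710 × 10⁻³ min⁻¹) — so regional
differences in luminal volume are governed by secretion, not absorption.
The effective permeability of water (≈ 2 × 10⁻⁴ cm/s) and a clearance on
the order of the loop's villous blood flow (ratio ≈ 1.1) indicate that
water absorption is rate-limited by mucosal blood flow, not by the membrane.
`res.simulate(region, times)` returns the fitted trajectory decomposed into
ingested water remaining and secreted fluid.

The same pipeline is scriptable from the shell:

```sh
gifluid generate --seed 42 --out study.csv        # synthetic noisy study
gifluid fit study.csv --out-dir out/              # report.json + CSV tables
gifluid simulate --k-abs 0.136 --k-sec 7.05e-3 --out traj.csv
gifluid report out/report.json
```

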