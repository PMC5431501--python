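# Methods

`canalflow` models the build-up of periapical fluid pressure when a root
canal is irrigated through a side-venting needle, for a single root with
two canals that may or may not communicate through anastomosing lateral
channels, and reproduces the statistical pipeline used to analyse bench
recordings of that pressure. This note records the model, its
assumptions, the defaults, and the choices made where the design was
genuinely open.

## Physical model

### Geometry

The simulated root is an instrumented canal pair in a rigid block. A
canal is a linear taper: diameter `D(s) = D_apical + taper · s` at
station `s` mm coronal to the closed apical terminus. Defaults follow a
size 30, 0.04-taper preparation, 23 mm long. The irrigation needle
defaults to ISO 9626 nominal normal-wall 30-gauge dimensions (OD
0.31 mm, ID 0.159 mm); these are configurable because manufacturers vary
and only the gauge is usually reported. The needle tip sits at
`s = insertion_depth` and the shaft occupies all coronal stations.

The controlling quantity is the **net flow area**
`A(s) = π/4 (D(s)² − D_needle²)` where the shaft is present, and the
full circle elsewhere. Insertion is rejected with a *binds* error
whenever the canal fails to clear the needle anywhere occupied — with a
non-negative taper it suffices to check the tip. The default 0.31 mm
needle binds at the 0.30 mm terminus, which is why insertion depth must
be strictly positive.

Anastomoses are milled cross-channels, 0.5 mm wide and deep, spanning
the 1.0 mm inter-canal web. Their axial placement is not knowable from
the bench description beyond "mid-root", so the default three channels
are spaced evenly over the middle third of the canal length (9.58, 11.5,
13.42 mm). The milled profile is modelled as a square duct by default,
with a `rounded` (semicircular-bottom) option; the exact shape left by a
ball-nosed cutter is unknown and the two options bracket it.

### Pressure estimation routes

Three routes are implemented and deliberately kept separate, because the
bench reasoning invokes both an energy argument and a force argument
without stating how they were combined:

1. **Dynamic pressure.** The closed apical sensor predominantly reads
   the kinetic head of the incoming fluid: `q = ½ ρ v²` with
   `v = Q / A` at the narrowest occupied annulus. The bench text states
   this as kinetic energy per unit mass (`½ m v²`); we implement it per
   unit volume (density in place of mass) so that the quantity is a
   pressure. Water-like fluid defaults: ρ = 1000 kg/m³, μ = 1.0 mPa·s
   (2 % NaOCl is hydraulically indistinguishable from water at room
   temperature).

2. **Force calibration.** Because pressure is force over area, one
   measured pressure at a known net area fixes an equivalent force
   `F = p_ref A_ref`; `F / A(depth)` then predicts the pressure at any
   other depth. Frictional head loss is intentionally *excluded* from
   this route (it is a pure continuity deduction); the network route
   includes it. The CLI's default calibration point is the 8.63 kPa
   median measured at 1 mm insertion and 9.5 mL/min, and predictions at
   other flows scale as `(Q/Q_ref)²`, consistent with the `v²`
   dependence.

3. **Lumped resistive network.** Canal runs and cross-channels become
   edges of a hydraulic network. Annulus and pipe edges use the
   concentric-annulus Hagen–Poiseuille conductance
   `Q/ΔP = (π/8μL)[r_o⁴ − r_i⁴ − (r_o²−r_i²)²/ln(r_o/r_i)]`; the
   resistance of a tapered run is integrated adaptively along the taper
   (so splitting a run at a junction is exactly additive). Rectangular
   channels use the exact duct series (0.035144 a⁴/μL for a square).
   Node pressures solve Kirchhoff mass conservation (dense solve with
   two steps of iterative refinement, driving the flow residual to
   rounding). An optional turbulent correction replaces the conductance
   of any edge with Re > 2300 by the Darcy–Weisbach value with Blasius
   friction `f = 0.316 Re^(−0.25)`, iterated (damped) to a fixed point at
   relative tolerance 1e−10. At the bench's flows and geometry every
   edge stays laminar (Re ≲ 600); the correction exists for wider
   exploration.

   Closed apical dead-ends carry no net flow. Each reads its adjacent
   junction's static pressure **plus `k_imp` times the tip dynamic
   pressure**, transmitted through the primed incompressible column
   (Pascal's law) — applied to every dead-end in the connected component
   that carries the injected flow, and zero for hydraulically isolated
   components. This single rule reproduces the two qualitative bench
   observations at once: a near-null control channel in the separate
   model, and near-equal readings from the two connected canals in the
   anastomosis model. `k_imp ∈ [0, 1]` (default 1.0, full stagnation
   recovery) is exposed because the bench gives no basis for fitting it.

### What the network model does and does not predict

All *ordering* properties hold and are enforced by tests: apical
pressure rises with flow rate, falls with insertion depth, falls when
channels are added (monotone relief), and the anastomosis model is
always below the separate model. Absolute magnitudes are **not**
calibrated to the bench medians: the laminar drop through the very tight
annular gap near the tip (radial clearance 15 µm at 1 mm insertion)
dominates the model prediction and overestimates the measured pressures
at 1 mm insertion several-fold, while agreeing within tens of percent at
3 mm. Absent the bench's raw calibration data (vent geometry, form
losses), no constant was fitted; the model is used for structure, not
magnitude.

## Synthetic experiment generator

The generator stands in for the bench apparatus: 16 groups (2 models ×
2 insertion depths × 4 flow rates of 1.5/2.5/9.5/15.6 mL/min), 12
recordings per group, 5 mL delivered per recording, two 1 Hz channels
per recording.

* Each test-channel trace is a logistic rise (3 s), a plateau held for
  the delivery duration (`60·volume/Q` seconds), and an exponential
  decay, with bounded uniform noise (±0.0067 kPa, the bench's observed
  sensor bound) on every sample. A noiseless trace peaks exactly at its
  plateau.
* Plateau levels are drawn **log-normal** about the group's target
  median: pressures are positive and the bench data were non-normal and
  heteroscedastic, which the log-normal reproduces while keeping the
  median exactly at the target. The log-sigma is solved in closed form
  from the target IQR. Default targets are the published group
  medians/IQRs, so a default run *is* the study condition.
* Separate-model adjacent channels are bounded noise about null;
  anastomosis-model adjacent channels equal the test channel within the
  sensor bound.
* Seeding: one master seed; each recording's generator is
  `SeedSequence(entropy=master, spawn_key=(group_index, replicate))`, so
  any subset of the design is reproducible in isolation.

The generator does **not** emulate pump pulsation, sensor drift, tubing
compliance, vent-orientation effects, or any flow-physics coupling
between channels beyond the configured equality bound. Passing recovery
tests therefore demonstrates that the analysis pipeline is correct and
unbiased under the study's statistical structure — not that the physical
model predicts bench magnitudes.

## Statistical pipeline

* **Summaries.** Median and IQR per group; quartiles use linear
  interpolation (numpy type-7). The convention is configurable because
  reported IQRs depend on it and the bench software's convention is
  unknown.
* **Calibration curve and safe flow rate.** Least-squares quadratic
  `P = a + bQ + cQ²` through (flow, median pressure) points; the safe
  flow-rate threshold is the smallest positive root of `P(Q) = 4 kPa`
  (the intraosseous pressure, 30 mmHg) within the fitted range, and can
  be snapped *up* to the 0.5 mL/min pilot grid — reporting the first
  probed flow at which the threshold is exceeded. The package fits the
  quadratic to the three low-flow groups (1.5/2.5/9.5 mL/min): the
  15.6 mL/min point sits in a regime the quadratic cannot span (its
  inclusion makes the fitted curve non-physical at low flow).
* **Between-model tests.** Two-sided Mann–Whitney: exact null
  distribution for groups of ≤ 12 without ties, full permutation
  enumeration for tied pools of ≤ 12 observations, otherwise the normal
  approximation with tie and continuity corrections. Degenerate all-tied
  input is flagged rather than tested.
* **Within-model tests.** The repeated design (same rig, all eight
  depth×flow conditions measured per replicate run) is analysed as a
  Friedman blocked rank test with replicate as block, followed by Dunn
  pairwise z-statistics `z = |R̄ᵢ − R̄ⱼ| / √(k(k+1)/6n)` with Bonferroni
  adjustment over the 28 pairs, summarised as a compact letter display.
  Because mean ranks order the conditions totally, the not-significant
  relation is interval-shaped and letters are assigned to maximal
  homogeneous intervals. Note a structural limit of this statistic: with
  k = 8 conditions and n = 12 blocks, adjacent rank neighbours (mean
  rank difference 1) can never reach Bonferroni-adjusted significance,
  so the partition is necessarily coarser than one produced by, e.g.,
  unadjusted pairwise tests. The mean-rank ordering itself, plus the
  omnibus test, is the reproducible surface.
* **Prevalence.** Percentages to two decimals from numerator/denominator
  count tables, as anatomical surveys print them.

## Numerical choices

* Internal canonical units: SI for all hydraulics, kPa for reported
  pressures (1 psi = 51.7149 mmHg; 1 mmHg = 0.1333224 kPa, chosen so
  30 mmHg prints as 4.000 kPa), mL/min for flows at API boundaries.
* Tapered-run resistance: `scipy.integrate.quad` at 1e−12 relative
  tolerance.
* Network solve: dense `numpy.linalg.solve` plus two iterative-refinement
  steps; components without an atmospheric outlet are rejected if they
  carry injection, otherwise held at gauge zero.
* Tie-breaks: the maximum of a recording reports the earliest attaining
  sample.
* Thresholds: roots within `(0, Q_max]` of the fit are accepted; grid
  snapping uses `ceil` to the grid step with a 1e−9 guard.

## Problem sizes used in the test suite

Stochastic checks run at: 10⁴ replicates for median recovery (1 %
tolerance), 500 seeds for quadratic coefficient bias (< 0.01), 200
seeded experiments for the within-model rank-ordering reproduction
(≥ 95 % of runs), and 5 random geometries for the annulus-conductance
quadrature cross-check (≤ 1 %). These sizes give comfortable
concentration margins for the assertions they support while keeping the
default suite fast.

## Known limitations

* Network magnitudes are uncalibrated (see above); treat absolute kPa
  from `solve_network` as model output, not bench prediction.
* The side-vent is collapsed onto the needle-tip station; vent offset
  and outlet orientation (which the bench found to matter) are not
  modelled.
* The `rounded` channel profile uses an effective-depth approximation to
  the rectangular-duct series, not an exact solution for that shape.
* The Blasius friction law is used for any Re > 2300 without an upper
  cutoff; it is accurate to about Re ≈ 10⁵.
* The sample-size/power computation behind "12 recordings per group" is
  not reproduced; the originating software and formula are unknown.
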