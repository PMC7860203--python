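# Methods

## Model

The cerebral venous outflow is modelled as a fixed-topology directed network:
superior sagittal sinus (SSS) and straight sinus (StS) merge at the torcula;
the confluent flow splits into mirrored left/right chains of transverse (TS),
proximal and distal sigmoid (PSS, DSS) sinus and internal jugular vein (IJV)
segments, ending at two outlets held at gauge pressure 0 (a relative-pressure
outlet condition). Flow is steady, Newtonian (density 1055 kg/m³, viscosity
0.0035 Pa·s), and walls are rigid.

Each segment dissipates pressure through two mechanisms:

* **Distributed friction** (Darcy–Weisbach): `ΔP = f·(L/D)·ρV²/2` with
  `f = 64/Re` for Re ≤ 2300 — algebraically identical to the Poiseuille law
  `ΔP = 128μL/(πD⁴)·Q`, i.e. linear in flow — and the Blasius correlation
  `f = 0.316·Re^(−1/4)` above. The friction factor is discontinuous at the
  switch; this is accepted and documented rather than blended, and at the
  flows and diameters of this network every segment stays laminar
  (max Re ≈ 1800 at 2000 mL/min).
* **Minor (vortical) losses**: `ΔP = K·ρV²/2` per bend, quadratic in flow.
  Bend coefficients follow `K = [0.131 + 0.159·(r/D)^(−3.5)]·(θ/90°)`, a
  standard circular-arc correlation in turn angle θ and bend-radius-to-
  diameter ratio; per-segment extra K values can be added freely.

In the laminar regime a segment drop is therefore exactly
`a_seg·Q + b_seg·Q²`, and the system drop of a symmetric-branch tree is
exactly quadratic in total inflow — the mechanistic reading of the observed
quadratic pressure–flow law.

**Network solution.** Inflows obey `Q_StS = 0.30·Q_SSS` (the straight sinus
carries 30% of sagittal flow); by default the prescribed flow is the *total*
inflow, `Q_SSS = Q/(1+0.30)`, with a flag to treat it as SSS-only instead
(the boundary-condition convention is genuinely ambiguous; total is the
default). The left-branch fraction is found by bisection on (0, 1) until the
two parallel torcula→outlet drops agree to 1e-9 relative; each branch drop is
strictly increasing in its flow, so the bracket is monotone and 200
iterations bound the solver. Mass is conserved identically by construction
and verified to 1e-12 in tests.

**Calibration.** The bend correlation cannot capture patient-specific
junction and curvature losses, so the model keeps a single free parameter: a
global scalar multiplying every K, root-found so the solved drop matches the
published young-adult operating point (620 mL/min, 4.5 mmHg). Friction terms
are never scaled. Calibration is infeasible (and raises) when friction alone
exceeds the anchor. After calibration the average geometry crosses the
8.3 mmHg induction level at ≈880 mL/min; note that any convex curve through
(620, 4.5) must cross 8.3 mmHg well below 1500 mL/min, so the published
≈1500 mL/min crossing of the CFD-averaged curves (which do not pass exactly
through that operating point) is treated as qualitative, not a calibration
target.

## Geometry

Non-circular lumens are reduced to two scalars: hydraulic diameter
`D_h = 4A/P` (friction length scale, used for the SSS) and effective diameter
`D_e = 2√(A/π)` (equal-area circle, used elsewhere). For binary lumen masks,
area is pixel count × spacing² and perimeter is the marching-squares contour
length after Gaussian pre-smoothing; the smoothing width grows like
`0.4·√R_px` so both the pixel-staircase ripple and the curvature bias of the
level set vanish under grid refinement (fixed-width smoothing does not
converge; raw binary marching squares overestimates a circle's perimeter by
≈6% at any resolution). The isoperimetric guard on measured sections carries
5% slack because circular sections sit exactly on the bound. Cohort
statistics use the sample (n−1) standard deviation — the convention that
reproduces the published SD row from the per-patient values.

Default segment lengths not reported for the reference cohort (TS 50 mm,
PSS/DSS 40 mm each, IJV extension 30 mm) are anatomically plausible adult
values, exposed in the geometry JSON; the SSS (107.8 mm) and StS (42.9 mm)
lengths and all diameters come from the cohort statistics. The jugular
extension reuses the DSS diameter as its anatomical continuation.

## Quadratic fitting and thresholds

`ΔP = a·Q + b·Q²` is fitted by least squares with the intercept constrained
to zero by default (a vascular bed at zero flow drops zero pressure); a free
intercept is available since trend-line conventions vary. The goodness
statistic is the Pearson correlation `r` between fitted and observed drops —
with zero-intercept fits this differs from R², and both are emitted with `r`
primary. The estimator (`QuadraticPressureFlow`) follows the scikit-learn
fit/predict contract so it composes with sklearn model selection.

The induction threshold flow is the positive root of `b·Q² + a·Q = 8.3 mmHg`
(linear fallback when b = 0). A root beyond the sweep ceiling (2000 mL/min by
default) returns `+inf` — the "never reaches the threshold" outcome of the
constant-resistance model; the cap is a parameter and can be disabled.

## Vorticity metrics

The planar curl `∂v/∂x − ∂u/∂y` is computed on masked regular grids with
central differences where both axis neighbours are lumen and one-sided
first-order differences at the mask boundary; isolated pixels with no in-mask
neighbour along an axis (e.g. the apex pixel of a rasterised disk) are
excluded from the differentiable set, and a mask with fewer than nine
differentiable pixels raises. The section statistic is the mean of |curl|:
the magnitude convention keeps counter-rotating vortex pairs from cancelling
and matches the strictly positive, flow-increasing published values; a
signed-mean option exists. Against the analytic field sampled on the same
pixels the discretisation converges at second order; against the continuous
section mean the residual mask-sampling error at the rim adds a lower-order
term, so convergence to the continuous mean is verified as monotone rather
than exactly fourth-fold per halving. Section placement (e.g. 1.5 cm below
the sigmoid outlet centre) is metadata on the plane, not derived geometry.

## Synthetic data

The generators define the study conditions; they are not tuning knobs.

* **Cohort trees**: per-patient diameters from truncated normals (lower
  bound 1 mm) with the published per-sinus means/SDs — SSS D_h 5.49 ± 0.43,
  TS D_e 6.28 ± 1.19, PSS D_e 7.77 ± 0.82, DSS D_e 8.21 ± 2.45 mm — and
  lengths SSS 107.8 ± 11.5, StS 42.9 ± 2.3 mm. Left and right branches are
  drawn independently (only one value per sinus is tabulated), which gives
  the asymmetric drainage that exercises the split solver. Patient i draws
  from the stream seeded by (seed, i): bit-reproducible, patients
  independent.
* **Velocity planes**: a circular lumen carrying a rigid-body swirl whose
  rim tangential speed is `swirl × V_mean`; the analytic section curl is
  uniform, `2·swirl·V_mean/R`, giving a closed form the discrete operator
  must reproduce exactly (the field is linear).
* **CFD surrogate**: noiseless truths `ΔP = aQ + bQ²` and
  `curl = c·Q^γ`, with multiplicative Gaussian noise (σ_p = 2% on drops,
  σ_c = 5% on curls). Multiplicative noise preserves positivity, keeps
  ΔP(0) = 0 exactly, and mirrors the sub-3% relative-error character of a
  validated CFD campaign. Defaults a = 0.003 mmHg/(mL/min),
  b = 1.5e-6 mmHg/(mL/min)², chosen so the truth crosses 8.3 mmHg near
  1500 mL/min; γ = 1.4, the midpoint of the 1.2–1.6 range implied by the
  published 400→2000 mL/min curl growth factors (5^1.2 to 5^1.6);
  c = 0.006 s⁻¹/(mL/min)^γ, which puts the 400 mL/min curl near the
  published low-flow values (~26 s⁻¹).
* **Referral cohort flows**: the 42-child flow list behind the "13 above
  1500 mL/min" summary was never published, so a synthetic cohort with
  exactly that composition is generated (truncated normals on either side of
  the threshold); only the counting and rounding are the computed result.

What the surrogate does *not* emulate: pulsatility, non-Newtonian rheology,
wall compliance, secondary-flow structure, or any per-patient coupling
between geometry and the surrogate coefficients. Passing surrogate tests
therefore demonstrates the statistical pipeline (fitting, correlation,
thresholds) under the stated noise model, not CFD fidelity.

## ICP coupling

Davson's equation and the venous Ohm analog are composed so the network's
system drop stands in for `TCBF·R_ven`. `FR_csf` and `R_out` have no
published values here; the defaults (0.35 mL/min, 10 mmHg·min/mL) are
user-supplied round numbers whose product plus an 11.1 mmHg sinus pressure
reproduces the 14.6 mmHg paediatric baseline, and are labelled as such. The
induction criteria (baseline ICP 14.6, required rise 3.8, baseline drop 4.5,
diagnostic ICP 18.34 mmHg) are carried verbatim, including the 0.06 mmHg
inconsistency between 14.6 + 3.8 and 18.34 — both constants are kept as
distinct fields. Cohort counting uses strict inequality ("above" the
threshold) and integer-rounded percent.

## Problem sizes and numerics

The default pipeline uses 5 patients × 10 flows; the acceptance script uses
20 single-patient surrogate replicates per correlation statistic and the
five-value reference cohort — everything runs in seconds on one CPU. Split
bisection tolerance 1e-9 (relative, on the branch-drop mismatch),
calibration tolerance 1e-9 relative on the anchor drop, ICP onset flow by
Brent's method at 1e-12. Unit constants: 1 mmHg = 133.322 Pa,
1 mL/min = 1/60 × 10⁻⁶ m³/s; SI internally, mm/mmHg/mL·min⁻¹ at interfaces.

## Known limitations

* The network cannot predict velocity *fields*; curl metrics apply to planes
  supplied or synthesised, not planes derived from the 1-D solution.
* One global minor-loss scale cannot represent per-junction differences;
  per-segment extra K values exist but default to zero.
* The laminar/Blasius switch is discontinuous; results at Re near 2300
  should not be trusted to better than the jump (irrelevant at default
  geometries, which stay laminar throughout the sweep).
* Calibration anchors the *average* operating point; per-patient anchors
  would need per-patient pressure data that does not exist publicly.
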