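# sinusflow

Reduced-order hemodynamics of the cerebral venous sinuses, built to ask a
clinical question: **can cerebral hyperemia alone raise venous pressure enough
to induce idiopathic intracranial hypertension (IIH)?**

Intracranial pressure is tied to the superior sagittal sinus (SSS) pressure by
Davson's equation,

```
ICP = FR_csf · R_out + SSS_p ,        SSS_p = TCBF · R_ven + CVP ,
```

with CSF formation rate `FR_csf`, CSF outflow resistance `R_out`, total
cerebral blood flow `TCBF`, venous outflow resistance `R_ven` (SSS to jugular
bulbs) and central venous pressure `CVP`. The classical picture takes `R_ven`
constant, so a 35% hyperemic flow increase on a 4.5 mmHg baseline drop adds
only 1.6 mmHg — not the 3.8 mmHg needed to push a paediatric ICP of 14.6 mmHg
past the diagnostic level. But the sinuses are curved, and the vortical flow
their bends induce dissipates pressure like the velocity *squared*. The
SSS-to-jugular drop is then quadratic in flow,

```
ΔP(Q) = a·Q + b·Q²      ⇔      R_ven(Q) = a + b·Q ,
```

and high blood flow becomes a credible route to IIH.

`sinusflow` implements that argument end to end as a one-dimensional loss
network:

- **vessel geometry** — hydraulic (`D_h = 4A/P`) and effective
  (`D_e = 2√(A/π)`) diameters, from analytic sections or binary lumen masks;
  cohort statistics of the five-patient reference diameters;
- **hemodynamics** — Darcy–Weisbach friction (laminar `f = 64/Re`, Blasius
  above Re 2300) plus bend/minor losses `K·ρV²/2` on a two-inlet
  (SSS + straight sinus), two-outlet (left/right jugular) tree, solved by
  bisection on the left/right flow split; a single minor-loss scale is
  calibrated to the published operating point (620 mL/min, 4.5 mmHg);
- **flow sweep & fitting** — the 200–2000 mL/min sweep (10 points, straight
  sinus carrying 30% of SSS flow), a scikit-learn compatible zero-intercept
  quadratic regressor, and the flow at which ΔP crosses the 8.3 mmHg IIH
  induction threshold;
- **vorticity metrics** — planar curl `∂v/∂x − ∂u/∂y` on masked
  cross-sections by finite differences, section-averaged in magnitude, and
  its Pearson correlation with pressure drop;
- **ICP coupling** — Davson's equation, the venous Ohm analog with constant
  or flow-dependent resistance, and cohort arithmetic (e.g. 13 of 42 flows
  above 1500 mL/min → 31%);
- **synthetic data** — patient trees drawn from the published diameter
  statistics, swirl planes with closed-form curl, and noisy CFD-surrogate
  pressure/curl series, all reproducible by seed.

## Worked example

```python
from sinusflow import (default_tree, calibrate, sweep, fit_quadratic,
                       threshold_flow)
from sinusflow.units import ml_min_to_m3_s, mmhg_to_pa

tree = calibrate(default_tree(), ml_min_to_m3_s(620), mmhg_to_pa(4.5))
curve = sweep(tree)                       # 200..2000 mL/min, 10 points
fit = fit_quadratic(curve)                # ΔP = a·Q + b·Q², zero intercept
print(f"a = {fit.a:.4e}   b = {fit.b:.4e}   r = {fit.r:.6f}")
print(f"drop at 620 mL/min : {fit.predict(620):.2f} mmHg")
print(f"drop at 2000 mL/min: {fit.predict(2000):.2f} mmHg")
print(f"8.3 mmHg crossing  : {threshold_flow(fit, 8.3):.0f} mL/min")
```

prints

```
a = 2.1503e-03   b = 8.2384e-06   r = 1.000000
drop at 620 mL/min : 4.50 mmHg
drop at 2000 mL/min: 37.25 mmHg
8.3 mmHg crossing  : 882 mL/min
```

The calibrated average geometry reproduces its 4.5 mmHg anchor exactly, the
fit is exact (in the laminar regime the network drop *is* a quadratic), and
at hyperemic flows the quadratic term dominates: by 2000 mL/min the drop is
far past the 8.3 mmHg induction level, which this geometry crosses at
882 mL/min. A constant-resistance model anchored at the same operating point
would need ~1140 mL/min and rises far more slowly.

The same analysis runs from the shell:

```sh
sinusflow run --synth --n 5 --seed 7 --out out/
cat out/summary.txt
```

which writes per-patient curve CSVs, fit JSON, curl–pressure correlations and
the hyperemia/cohort scenario report.

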