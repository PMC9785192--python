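# Methods

`pbpkddi` implements whole-body physiologically based pharmacokinetic (PBPK)
models of posaconazole (POS) and ruxolitinib (RUX), couples them through
competitive CYP3A4 inhibition, and provides the evaluation statistics,
virtual-population machinery, Ki estimation and synthetic-data generation
needed to exercise the full analysis without any external data.

## Whole-body model

The body is the classic perfusion-limited topology: lung, adipose, bone,
brain, gut wall, heart, kidney, liver, muscle, skin, spleen, gonads, stomach
wall, a lumped "rest" compartment, and arterial/venous blood. Blood flows are
embedded as an ICRP-style reference adult table (73 kg, 176 cm, 30 y male);
cardiac output is defined as the sum of the systemic flows, which is what
makes the flow-conservation invariant exact. Gut, spleen and stomach wall
drain into the portal vein; the liver receives hepatic artery plus portal
flow. Organ volumes scale linearly with body weight, flows and GFR with
weight^0.75, and GFR declines 0.8%/year past age 40. Blood and plasma
concentrations are treated as equal (blood:plasma ratio 1) for all three
compounds; neither source model reports a measured ratio and the endpoints
reproduced here are ratios and plasma exposures, which this assumption
leaves essentially untouched.

Each organ is well stirred: venous plasma leaving organ *t* is `C_t/Kp_t`.
Metabolism is first order, `v = CL_spec · [E]_organ · V_organ · C_u`, with
`C_u = fu_p · C_t / Kp_t`; "kcat"-type processes carry a Michaelis constant
and are evaluated in their linear range (`kcat/Km` acts as a specific
clearance); saturable metabolism is deliberately out of scope. Renal
filtration is `gfr_fraction · GFR · fu_p · C_kidney/Kp`; biliary excretion
uses a specific clearance (1/min) referenced to liver volume. Amounts are
integrated in µmol with LSODA, restarted at every dose, infusion-boundary
and meal event; defaults are rtol 1e-8 / atol 1e-10 with a 0.1 h output
grid (population studies use rtol 1e-6 / atol 1e-9, which changes the
reported medians by far less than any tolerance applied to them). Every
simulation carries a mass-balance ledger (administered = in body + in lumen
+ cumulatively eliminated); a relative residual above 1e-6 is an error, not
a warning.

## Distribution

Tissue:plasma partition coefficients come from either the Rodgers & Rowland
scheme (RUX, midazolam) or Poulin & Theil (POS), computed from an embedded
tissue-composition table (water/lipid/phospholipid fractions, acidic
phospholipids, albumin ratios). Adipose neutral-lipid partitioning uses the
standard vegetable-oil correlation `log D_vo = 1.115·logP − 1.35` in both
schemes — octanol alone overpredicts storage-lipid partitioning by an order
of magnitude for moderately lipophilic bases. With this choice the RUX
steady-state volume of distribution is ≈43 L and the POS volume ≈270 L,
both physiologically sensible.

## Oral absorption

Five lumped lumen segments (stomach, duodenum, jejunum, ileum, colon) with a
fixed pH profile (1.3 / 6.0 / 6.5 / 7.0 / 6.5), first-order transit
(gastric half-emptying 15 min fasted; ≈4.3 h mean small-intestinal
residence — the upper half of the physiological 2–6 h range, which matters
for release-limited tablets; ≈20 h colon) and per-segment effective
absorptive areas. Dissolved drug permeates at
`permeability × area × concentration` into the gut wall, where mucosal
CYP3A4 acts before the portal vein — this is what makes oral victims more
sensitive to the interaction than i.v. victims.

Release models:

* **Weibull** (RUX extended-release tablet: t50 15 min, shape 1.10; POS
  DR-tablet: t50 145 min, shape 1.67, 30 min lag): the engine releases the
  *remaining* solid at the Weibull hazard `F'(t)/(1−F(t))`, which keeps the
  lumen ledger exact while the solid transits. The DR-tablet is enteric:
  gastric release is blocked, and a per-segment "adapted intestinal
  solubility" table caps the dissolved concentration (release pauses at
  saturation). With multiple doses the hazard clock restarts at the most
  recent administration — exact whenever a dose releases completely within
  its dosing interval, which holds for both tablets here.
* **Particle dissolution** (POS suspension: radius 1.9 µm, unstirred layer
  140 µm, density 0.37 g/cm³): Nernst–Brunner rate for monodisperse
  shrinking spheres, `3m·D/(ρ·r·h)·(Cs−C)`, with the aqueous diffusivity
  from molar mass. Supersaturation is allowed; the excess above local
  saturation precipitates first order (default half-life 10 min, not
  reported by the source and therefore exposed in the formulation file) and
  the precipitate is returned to the *soluble* solid pool, growing the
  effective particle radius with the cube root of the mass gain. In the ODE
  engine the radius is carried algebraically as `r0·(m/m_dose)^(1/3)` — the
  same cube-root law — because a per-segment radius state is numerically
  stiff to no benefit.
* **Meals** slow gastric emptying linearly in caloric content (multiplier
  `max(1 − kcal/1200, 0.1)` for 4 h); only the caloric supply enters the
  rule. This reproduces the direction of the suspension food effect (fed
  exposure above fasted) but deliberately not its full 2.6–4× magnitude,
  which in vivo is driven by bile/fat-mediated solubilization that this
  model does not contain.

Solubility follows a Henderson–Hasselbalch profile with a per-charge gain
factor. For POS (diprotic weak base, pKa 4.6/3.6) the gain (0.021091) is
solved exactly so the curve passes through both reported anchors,
0.79 mg/mL at pH 1 and 0.001 mg/mL at pH 7.

## Drug–drug interaction

POS inhibits CYP3A4 competitively with Ki = 5.22·10⁻³ µM. The victim's
CYP3A4 specific clearance is multiplied by `1/(1 + I_u/Ki)` in every organ
expressing the enzyme, with `I_u` the perpetrator's local unbound tissue
concentration (a plasma-unbound alternative is available in
`SolverSettings.inhibitor_driver`). Exposure ratios are computed per
subject from paired runs — victim alone vs. victim + perpetrator on the
same individual with the same seeds — so ratio variability reflects the
interaction only. Population summaries report the median and the 5–95%
interval. Steady-state metrics are read on dosing day 10 by default.

Ki estimation minimizes the sum of squared log10 concentration residuals of
the with-perpetrator victim profiles, consistent with the log-scale MRD
metric. Because the perpetrator's kinetics do not depend on Ki, its
trajectory is simulated once per dataset; each candidate Ki then integrates
only the victim system driven by the stored unbound inhibitor
concentrations. The optimizer is a seeded multi-start (default 20 starts,
log-uniform in the bounds, literature start always included) bounded
quasi-Newton search on log10 Ki with memoized objective evaluations.

## Parameter provenance and identification

Every value printed in the source publication's main text is carried
verbatim in the YAML fixtures (Weibull parameters, particle geometry,
specific clearances 0.46/0.65 L/µmol/min, Ki, the two permeabilities with
their original — and different — unit tags, the solubility anchors, meal
calories). The remaining compound parameters lived in supplementary tables
that are not redistributed here, so they were identified by fitting this
package's own engine to the publication's reported exposure endpoints
(steady-state RUX Cmax/AUC, day-10 POS trough/Cmax), exactly the kind of
parameter identification the original workflow used against its clinical
datasets. Each fixture field is tagged `main_text`, `literature` or
`identified`.

Two identified values deserve explicit mention:

* **Liver enzyme concentrations.** The sum of the CYP3A4/CYP2C9 intrinsic
  clearances (through the fixed in-vitro specific clearances) sets RUX
  clearance; their balance sets fm,CYP3A4 — the single number the
  interaction magnitude hinges on. Both were identified (8.079 and
  10.164 µmol/L, hepatic fm,CYP3A4 ≈ 0.36, gut CYP3A4 1.5 µmol/L); both
  lie inside reported hepatic P450 abundance ranges. Generic abundance
  tables gave fm ≈ 0.44 and overpredicted the AUC ratio by ~20% in this
  engine.
* **Midazolam** is a constructed stand-in (`midazolam_synthetic.yaml`):
  literature physicochemistry plus a CYP3A4 specific clearance calibrated
  to a typical i.v. clearance of ≈25 L/h. It exists to exercise the Ki
  estimation and the oral-vs-i.v. interaction pattern, not to reproduce
  any published midazolam exposure.

## Virtual populations and synthetic data

Populations sample demographics independently (uniform or truncated normal
per field; the packaged study population uses GvHD-cohort-style ranges) and
apply median-preserving log-normal deviates to clearance (CV 30%), unbound
fraction (15%), dissolution time (30%) and intestinal permeability (40%) —
within the variability ranges reported for POS absorption. Median
preservation is deliberate: the reported population endpoints are medians,
and this keeps the population median anchored to the calibrated typical
individual. Correlated covariate sampling (as in full population
databases) is not modeled.

The synthetic-data module generates (a) dense study profiles — fixed
nominal sampling times, per-subject parameter deviates, multiplicative
log-normal residual error — and (b) sparse clinical-routine TDM samples at
steady state, where the *recorded* time-since-dose differs from the true
one by a seeded jitter draw, emulating patient-reported intake times, and a
perpetrator can be co-timed with the victim dose. Ground truth (parameter
deviates, true times, noise-free predictions) travels with every dataset.
Passing tests on these data demonstrate internal consistency of the whole
pipeline — they cannot demonstrate correctness for real patients, whose
disease physiology, co-medication and assay behavior the generator does not
emulate.

## Evaluation statistics

PE/MPE/MAPE are the signed and absolute mean percentage errors; MAPE takes
the absolute value per point (so MAPE ≥ |MPE| always) and MRD is
`10^sqrt(mean(Δlog10²))` (so MRD ≥ 1, and a single 2-fold pair gives
exactly 2). The 2-fold acceptance boundary is inclusive. Below-LLOQ
observations are excluded from all statistics and from both sides of the
coverage computation. Prediction intervals are pointwise empirical 5–95%
quantiles over ≥20 subjects; coverage interpolates the band linearly in
time. Pooled and per-dataset 2-fold statistics are both reported, since
conventions differ.

Local sensitivity follows the one-at-a-time design: log-spaced multipliers
spanning [1/10, 10] in at most 9 steps, relative sensitivity
`S = (ΔM/M)/(Δp/p)` by central difference at the base point, per-point
failures recorded rather than dropped. In this engine lipophilicity is the
dominant negative driver of POS AUC among the distribution/elimination
parameters (S ≈ −0.5 at the 9-step spacing), but its magnitude is smaller
than the value the reference software reports (−6.81) because solubility
and permeability are independent inputs here rather than functions of
logP; the anchor is therefore qualitative (large, negative, rank-1).

## Numerical choices and degenerate inputs

Zero doses are allowed and produce identically zero concentrations (used by
the interaction limit tests). Dose events restart the integrator; the
output grid always contains the event times. NCA uses the linear trapezoid
on the output grid, Cmax/tmax from the grid maximum, and the
end-of-interval concentration as trough. The piecewise integrator core is
exposed (`integrate_piecewise`) so reduced systems — e.g. the
one-compartment closed-form check — exercise exactly the code path the
whole-body model runs through.

## Problem sizes

Population studies in the test suite and the acceptance script use the
n = 100 seeded population for exposure endpoints, 150 + 40 subjects for the
band-coverage calibration, and 10 seeded replicates for the Ki recovery
experiment; these sizes give Monte-Carlo errors comfortably below the
tolerances applied to the corresponding quantities.

## Known limitations

* Perfusion-limited distribution only; no permeability-limited organs, no
  transporters, no enterohepatic recirculation, no saturable metabolism,
  no metabolite kinetics, no autoinduction.
* The GI model is a 5-segment lumping with fixed pH and water volumes; bile
  micelle solubilization is absent, so food effects are directional only.
* No disease (GvHD) physiology — the population is healthy adults with
  study-like demographics, mirroring the source analysis, which made the
  same choice for lack of a quantitative disease model.
* The midazolam fixture is synthetic (see above); Table-style midazolam
  DDI ratios are reproduced as a qualitative pattern (oral > i.v.), not as
  quantitative targets.
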