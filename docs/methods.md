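# Methods

## Scope and intent

The package simulates nadolol pharmacokinetics with a whole-body,
perfusion-limited PBPK model and qualifies the simulations against the
published clinical record (healthy adults IV/oral, chronic renal failure,
pediatrics).  It is a from-scratch, scriptable re-implementation of a
workflow originally performed in a GUI simulator; the compartmental
equations, partition method and population machinery are therefore this
package's own documented choices, and qualification relies on
model-agnostic criteria (predicted/observed ratios, average fold error,
the twofold interval) rather than curve-for-curve identity.

## Physiology

The reference adult (70 kg, 170 cm, 30 y) ships as a CSV of ~15 organs
with volumes (L), regional blood flows (L/h) and water/lipid/protein
volume fractions, ICRP-style.  Cardiac output is carried by the lung
compartment and must equal the sum of systemic flows to 1e-6 relative —
this invariant is enforced at construction and preserved by every scaling
operation (the lung flow is recomputed as the systemic sum).  Reference
GFR is 120 mL/min, hematocrit 0.45, gastric emptying 15 min; none of these
are tied to code — users can construct any `PhysiologyState`.

**Renal failure** changes exactly three quantities, following the renal
impairment literature the source model used: GFR 45/18 mL/min, hematocrit
0.42/0.39 and gastric emptying 20.4/24.6 min for moderate/severe disease.
Protein-binding and CYP-abundance changes in CKD are deliberately out of
scope.

**Pediatric scaling.**  Organ volumes scale with the weight fraction of
the adult, multiplied by age-dependent relative fractions for brain,
muscle and adipose (infant brains are relatively ~5× larger); flows,
clearances and GFR scale allometrically with exponent 0.75.  GFR
additionally follows a Hill maturation sigmoid of postmenstrual age
(TM50 47.7 weeks, Hill 3.4, PMA = postnatal age + 40 weeks), a standard
published maturation function; at age 18 it is within 2 % of the adult
value and it is non-decreasing in age along the packaged weight-for-age
curve.  Pediatric hematocrit comes from a small age table.  Gastric
emptying is kept at the adult value for children — a simplification, since
the engine only uses it for the oral lag.

**Populations** sample age and weight uniformly (weight defaults to the
packaged weight-for-age ± 20 % when no range is given), sex as
Bernoulli(female fraction), and apply median-preserving log-normal
variability, CV 16 % truncated at ±3 SD, to every organ volume, flow and
GFR.  CV 16 % is a typical inter-individual spread for PBPK population
simulations; the source states only population sizes and demographic
ranges.  Everything is reproducible from a single integer seed.

## Drug model

The nadolol parameter set (MW 309.4 g/mol, solubility 8.33 mg/mL, pKa
9.17, logP 0.81, fu 0.7, specific intestinal permeability 1.03e-6 cm/min,
CL_R 131 and CL_T 219 mL/min) is packaged as the default.  The
blood:plasma ratio is not reported for nadolol and defaults to 1.0.

Partition coefficients use a homogenised tissue-composition form,
Kp = f_w + 10^logP·f_lip + (1/fu − 1)·f_prot, chosen for transparency: it
is exactly 1 in the aqueous limit, monotone in lipid content, and
per-organ overridable so users can pin literature values.  For nadolol it
yields Vss ≈ 160 L (≈2.3 L/kg) and a terminal half-life of ~11 h, inside
the reported 14–24 h range's neighbourhood but on the short side.  The IV
AUC is provably independent of the Kp set (see Engine), which confines the
consequences of this choice to curve shape.

Renal clearance scales proportionally with GFR against the 120 mL/min
reference; biliary clearance (CL_T − CL_R = 88 mL/min) scales
allometrically with body weight^0.75.

**Oral absorption.**  The smooth-cylinder conversion ka = 2·Peff/r
(r = 1.17 cm) gives ~1.06e-4 /h for nadolol's specific permeability — a
number that ignores the mucosal surface amplification a full GI model
applies, and would predict essentially zero absorption.  The package
therefore ships `calibrate_oral_absorption`, a bisection on the simulated
oral bioavailability of the full engine, and packages its result for a
target F = 1/3 (the standard literature figure for nadolol: about one
third of an oral dose is absorbed) as the default effective
ka = 0.1283 /h.  With the 3 h transit half-life this reproduces F ≈ 0.33
and an oral Tmax of ~3 h.

## Engine

States are drug amounts (mg) in: gastric and intestinal lumen; arterial
and venous blood; lung; ~12 systemic organs; and three accounting sinks
(unabsorbed transit loss, renal, biliary).  Perfusion-limited organ
balances use the venous-equilibrium form dA_t/dt = Q_t(C_art −
C_t/(Kp_t/BP)).  The liver receives the hepatic artery plus portal
outflows of gut, spleen and pancreas.

Clearance placement is chosen so the fundamental identity
AUC_0-inf = Dose/CL_T holds *exactly* on the measured venous plasma
concentration, independent of every Kp: renal elimination is proportional
to the kidney inflow (arterial) plasma concentration and is drawn from the
kidney compartment; biliary elimination is proportional to the mixed liver
inflow concentration and drawn from the liver.  Drawing from the tissue
rather than the blood keeps all blood flows at cardiac output, which makes
∫C_ven = ∫C_art and hence Dose = CL_T·AUC exactly (verified to 1e-9 in
tests, including under 4× Kp perturbations).

IV doses are delivered as 2-minute zero-order infusions (clinical bolus
practice, configurable down to a true instantaneous bolus).  An
instantaneous bolus into the venous pool creates a delta-like first-pass
transient carrying ≈ Dose/CO of AUC that no finite output grid can
integrate; the infusion makes the curve smooth, so NCA clearance recovers
CL_T within 2 % on a 0.02 h grid.

Between dose events the system is linear and time-invariant, so the
default propagator advances with cached matrix exponentials (one augmented
exponential also yields the forced-response integral for infusion
segments) — exact to machine precision, unconditionally stable, and fast
enough for thousands of virtual subjects per minute on one CPU.  An LSODA
path with analytic Jacobian is retained and cross-checked against the
exponential propagator in the tests.  Mass balance (body + lumen + sinks =
administered) holds to ~1e-13 at every output time.

Output is the venous plasma concentration in ng/mL on a uniform grid
(default 0.1 h); per-kg doses resolve against each subject's body weight
at simulation time; sample concentrations at oral dose times are pre-dose
(troughs).

## NCA and summaries

Linear trapezoid AUC (matching the linear default of the spreadsheet NCA
tool the original workflow used); λz by log-linear regression over the
last 5 points or the last 20 % of the time span, whichever is more;
AUC_0-inf = AUC_0-t + C_last/λz; CL = Dose/AUC_0-inf (apparent CL/F for
oral); a non-positive terminal slope leaves the extrapolated quantities
unavailable rather than guessed.  VPC envelopes report per-time arithmetic
mean, min/max and 5th/95th percentiles (linear interpolation between order
statistics); box summaries use median, quartiles and min/max whiskers, as
in the source figures.

## Qualification and its limits

Two layers:

1. **Printed-table arithmetic.**  The packaged tables carry the published
   predicted and observed Cmax/AUC/CL cells of 22 study arms.  The package
   recomputes every ratio; 60 of 66 reproduce the printed value within
   ±0.0105 (covering truncation-vs-rounding of two decimals).  The six
   exceptions are frozen and flagged, not matched — the largest is a
   printed 0.25 for 0.07/2.7 = 0.026, an apparent order-of-magnitude typo.
   The published AFE for IV-healthy clearance (0.98) reproduces exactly as
   the geometric mean of its ratios; the published Cmax/AUC AFE cells do
   not follow from the printed ratios by any geometric mean we could
   construct and are therefore packaged for reference but not asserted.
   Observed CL columns have inconsistent units between blocks and are
   carried opaquely (never unit-converted).

2. **Re-simulation.**  Each adult study arm is re-simulated with 100
   virtual subjects drawn from its published demographics, single doses
   analysed over 48 h and the steady-state arm as the last interval of 7
   once-daily doses, and the arithmetic-mean Cmax and AUC_0-t compared to
   the observed values under the twofold criterion.  All IV and oral AUC
   ratios fall within [0.5, 2] except one 30 mg arm whose observed (and
   source-predicted) AUC is ~2.2× every other single-dose 30 mg arm — the
   printed numbers imply an unreported repeated-dose schedule, so that arm
   is reported and flagged rather than scored.  Oral Cmax ratios pass
   likewise.  IV Cmax ratios sit at 0.45–0.50: a perfusion-limited model
   lets tissues take up drug at full regional blood flow, so six minutes
   after dosing the apparent distribution volume is already ~45 L, whereas
   the observed first-sample concentrations of this low-permeability
   (BCS III) drug imply ~23 L.  This is a structural limitation of the
   perfusion-limited assumption for nadolol, documented rather than
   patched; fixing it would require permeability-limited tissue models.
   Pediatric arms are not re-simulated: their printed rows mix single- and
   repeated-dose sampling that cannot be reconstructed (one arm received
   doses at 0 and 45 h; another's printed values are only consistent with
   multi-day accumulation windows).

Population-level directions are asserted as properties: oral 80 mg median
AUC increases healthy → moderate → severe renal failure, and fixed-dose
(0.32 mg IV / 5 mg oral) median AUC decreases monotonically from infants
to teenagers across the CDC age bands.

## Synthetic observed data

The original observed curves exist only as digitized figures, so
end-to-end tests use synthetic studies: closed-form one/two-compartment
profiles (the analytic oracle, independent of the engine), log-normal
inter-individual variability on CL and V (default CV 20 %), and a
proportional (CV 10 %) plus additive (0.1 ng/mL floor) error model with
zero-clipping.  These emulate the sampling structure and noise level of
digitized clinical data but not its real-world features — actual sampling
schedules, assay LLOQ censoring, model misspecification between subjects —
so passing recovery tests demonstrates the pipeline's statistical
correctness, not clinical data quality.  Over 200 synthetic subjects the
geometric mean of NCA clearance estimates recovers the generating
clearance within 5 %.

## Numerical choices and problem sizes

Solver: exact piecewise-LTI propagation (no tolerance); the LSODA
cross-check uses rtol 1e-6 / atol 1e-8.  Output grid 0.1 h (0.02 h where a
2-minute infusion must be resolved).  Quartiles and percentiles use linear
interpolation; Tmax ties resolve to the earliest time; degenerate
closed-form eigenvalues fall back to limiting (t·e^{−λt}) forms.
Simulation sizes follow the study design: 100 virtual subjects per study
arm, renal-failure group and pediatric age band; 200 subjects for the
recovery property.  Every scenario runs in seconds on one CPU.

## Known limitations

- Terminal half-life (~11 h) is shorter than the reported 14–24 h; the
  tissue-composition Kp stand-in under-partitions for nadolol.  AUC and CL
  comparisons are insensitive to this by construction; Cmax and curve
  shape are not.
- Early IV distribution is too fast (see above) — IV Cmax is
  underpredicted roughly twofold.
- Single mixed intestinal compartment: no segmental transit, no
  dissolution limitation (nadolol is high-solubility), no enterohepatic
  recirculation.
- Renal and biliary clearances scale with GFR and weight only; no
  transporter ontogeny or CKD protein-binding changes.
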