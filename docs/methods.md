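# Methods

## Model structure and assumptions

The model is a deliberately small physiologically-based pharmacokinetic
(PBPK) system. Arterial and venous circulation are lumped into one
well-mixed blood compartment whose volume equals total volemia; marker
concentration in blood is homogeneous. Source organs are infinite
reservoirs: their tissue concentrations are boundary conditions, never
depleted. This matches how such markers behave on the hours-to-days scale
of interest — the brain's extracellular S100B pool is replenished by
astrocytes far faster than the barrier drains it — and it means disease
states that raise the source (gliosis) are modeled simply by raising the
tissue concentration.

Exchange between an organ and blood is gradient-driven and bidirectional,
`CL_i(t) · (B_i − C)`. A unidirectional influx variant (`CL_i · B_i`) is
available as a toggle on `CompartmentModel`; with the default parameter
sets `B_i ≫ C`, so the two differ by well under 1%, but the bidirectional
form is the default because it behaves correctly in degenerate regimes
(with no renal elimination the blood equilibrates with the source instead
of growing without bound).

Elimination is purely glomerular: renal clearance is GFR times a sieving
coefficient `C_F(MW)`, urine is a pure sink, and there is no tubular
handling, protein binding, degradation, or hepatic route. Consequently a
marker whose `C_F` clamps to zero (raw sieving value negative above
~130 kDa, e.g. IgG at 140 kDa) is never eliminated at all — the model's
half-life for such markers is reported as `inf`, a deliberate sentinel
rather than an overflow.

## Parameters

| Parameter | Default | Units | Role |
| --- | --- | --- | --- |
| Brain tissue conc (S100B monomer/dimer, GFAP, UCHL-1) | 10.0 / 10.0 / 1.0 / 7.6 | ng/ml | source strength |
| Brain volume (neonate / adult m / adult f) | 0.42 / 1.42 / 1.05 | l | scales CLmax |
| Blood volume (neonate / adult) | 0.28 / 6.0 | l | dilution + elimination pool |
| Baseline barrier leak (adult / newborn) | 2.5 / 10 | % of maximal | steady-state permeability |
| Skin volume, tissue S100B (light / dark) | 7.8, 0.288 / 2.0 | l, ng/ml | dermal source |
| Skin leak | 2 | % of maximal | steady dermal transfer |
| Adult GFR coefficients A (Cauc m/f, A-A m/f), B (m/f) | 141/144, 163/166; 0.9/0.7 | — | creatinine formula |
| Neonatal GFR preset | 47 ml/min/1.73 m², BSA 0.25 m² | — | immature kidney |
| Sieving curve | −0.04094 + 1.19614 / (1 + 10^((27096−MW)·−3.1e−5)), clamped [0,1] | — | MW-dependent filtration |
| Index→serum slope | 0.0022 | ng/ml per index unit | disruption anchor |
| Reference transient | 0.29 − 0.20·0.79^t | ng/ml, t in min | kinetic anchor |

The adult leak default (2.5%) is the midpoint of the physiological 1–5%
range. Serum creatinine defaults to the sex norm B, making the creatinine
term inert; the exponent −1.209 engages only when creatinine exceeds the
norm, because a positive exponent would make GFR rise with creatinine,
contradicting renal physiology. Age is standardized to 45 years. The
canonical internal units are ng, ml, min; GFR is kept in ml/min throughout
(per-hour conversion is an export concern only), because the disruption
kinetics are parameterized in minutes and mixing time bases would corrupt
the transients.

Nadler's total-blood-volume formula is provided in two dialects: the
canonical form with the cubed height term (default) and an `as_printed`
linear-height variant kept for fidelity to common transcriptions. The
linear form gives ~3.8 l for a 1.8 m/80 kg male — physiologically
implausible — which is why the cubic form is the default. Preset blood
volumes use the fixed 6.0 l adult value rather than the formula.

## Barrier calibration

The maximal brain-to-blood transfer clearance CLmax and the recovery time
constant τ of a disruption are not published quantities; they are
reconstructed from the two clinical anchors. For a candidate τ, CLmax is
pinned by a 1-D root solve so that a simulated maximal disruption (index
100, starting from the baseline-leak steady state) peaks exactly 0.22 ng/ml
above baseline; τ is then chosen by bounded scalar minimization of the RMS
deviation between the simulated increment and the reference transient's
rising limb over its first 20 minutes. The reference is compared as an
*increment* curve, `0.20·(1−0.79^t)` — its printed form minus the 0.09
ng/ml intercept — because the clinical cohort's baseline differs from the
model's healthy-adult steady state. The optimum is interior
(CLmax ≈ 21.3 ml/min, τ ≈ 8.8 min, RMS ≈ 0.015 ng/ml) and is recovered
unchanged from perturbed search brackets, which is the identifiability
check: the peak constraint pins the product CLmax·τ, the rising-limb shape
breaks the degeneracy.

Organ maxima scale with tissue volume relative to the 1.42 l adult
reference brain (neonate brain ×0.42/1.42, skin ×7.8/1.42). This single
rule, together with the one calibrated constant, reproduces the neonatal
steady state and the dermal contributions without any per-organ fitting.
The same calibrated machinery is applied to all markers — the anchors are
S100B measurements, and no marker-resolved disruption data exist, so
marker identity enters only through tissue concentration and molecular
weight.

Disruption recovery is a single exponential relaxation of the index back to
baseline. The clinical description constrains only that the opening
"gradually" recloses; the exponential is the parsimonious choice and
matches the exponential form of the reference transient. Overlapping events
combine by pointwise maximum — an artifact convention, since the source
observations involve single events. Whether the 0.22 ng/ml anchor is a
transient peak or a quasi-plateau is ambiguous in the source data; the
calibration treats it as the transient peak, consistent with the saturating
shape of the reference time course.

## Numerics

The ODE (state: serum concentration plus cumulative influx and excreted
mass) is integrated with LSODA at rtol 1e-8 / atol 1e-12 ng/ml on a fixed
output grid (default dt 0.5 min), segmented at event onsets so index
discontinuities never straddle a solver step. Solver undershoot below zero
is clipped only within 1e-9 ng/ml; anything larger raises. Mass balance —
influx minus excretion minus blood-content change — holds to ~1e-15
relative in practice and is asserted below 1e-6. Steady state is declared
at the earliest grid point whose trailing 60 min window varies by less than
1e-4 relative. Event-free plateaus are cross-checked against the closed
form `ΣCL_i·B_i / (ΣCL_i + CL_R)` to 0.1% over randomized models. The
scenario horizon is 1440 min (≈ 22 elimination time constants for the
slowest default arm), long enough that truncation error is orders of
magnitude below the detection tolerance. There is no randomness anywhere in
the core; property tests use seeded/derandomized generators.

## Scenarios

Scenario arms differ only in the parameters the scenario names (asserted by
diffing their resolved-parameter echoes). The disruption event in figures
is placed 60 min after detected steady state, with the calibrated τ.
Neonatal brain marker concentrations are set equal to adult values, so
age differences are purely anatomic/physiological. The dark-skin tissue
concentration is taken as exactly 2.0 ng/ml (the tabulated value; the
accompanying figure text says "above 2.0"). The neonatal scenario omits
skin — the pigmentation analysis is defined for adult males only, and the
model refuses a neonate+skin combination. Fat, though it contains S100B,
is reported not to influence blood levels and is excluded from the organ
defaults; the presumed mechanism (poor vascularization) is not modeled.

One claim needed restating at the level where it holds: because clearance
is linear in the kidney-health fraction, the *relative* half-life increase
under renal failure is identical for every marker with `C_F > 0` (function
0.1 gives exactly 10× everywhere). The size-dependence of renal failure is
real but lives in the *absolute* increase, which grows monotonically with
MW and diverges for markers above the sieving cutoff.

## What the synthetic conditions do and do not show

All inputs are the tabulated physiological presets; there is no patient
data in the package. Passing tests therefore demonstrate internal
consistency (solver vs algebra, conservation, monotonicities) and
faithfulness to the published anchor values — not clinical accuracy. In
particular: the homogeneous blood pool ignores arterio-venous gradients
that matter in the first minutes after disruption; the radiologic index is
a coarse scalar for a spatially heterogeneous barrier; skin enters with a
single uniform tissue concentration; and the elimination model omits every
non-glomerular route, so predictions for very large markers (half-life
`inf`) are a statement about the model's scope, not about biology.

## Known limitations

- No CSF/interstitial sub-compartments; the brain source lumps them.
- No pediatric maturation between the neonate and adult endpoints.
- No tubular secretion/reabsorption; `C_F = 0` markers are never cleared.
- Single shared CLmax across markers; no marker-specific permeability.
- The calibration inherits the ambiguity of its clinical anchors; its
  constants are reconstructions, not measurements.
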