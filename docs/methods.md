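# Methods

## Scope

`hemocoherence` implements a complete, testable analogue of a clinical
investigation of physiological hemodynamic coherence in anesthetized adults:
how the effective circulating volume, summarized by the mean circulatory
filling pressure analogue (Pmca), relates to sublingual microcirculatory red
blood cell (RBC) velocity and to the pressure difference Δp that drives flow
through individual microvessels. Because the clinical records are not
deposited, the package ships a synthetic-cohort generator calibrated to the
published cohort summary statistics; every downstream stage (hemodynamics,
CFD, statistics) operates identically on synthetic or ingested data.

## The Pmca model

Based on a Guytonian two-compartment model of the systemic circulation with a
24:1 veno-arterial compliance ratio,

    Pmca = a·CVP + b·MAP + c·CO,  a = 0.96, b = 0.04 (a + b = 1),

with the anthropometric arteriovenous-resistance coefficient

    c = 0.038(94.17 + 0.193·age) /
        [4.5 · 0.99^(age−15) · 0.007184·height^0.725·weight^0.425].

The denominator contains the DuBois body-surface-area formula, which fixes
the units (age in years, height in cm, weight in kg). The published form of
this expression omits the division; the ratio reading implemented here is the
one that reproduces the published cohort-mean Pmca of 13.1 mmHg from the
cohort-mean CVP (7.1), MAP (88.1) and CO (4.8). Derived variables:
PG_VR = Pmca − CVP, R_VR = PG_VR/CO, O2ER = (SaO2 − ScvO2)/SaO2 (stored as a
fraction, rendered as % only when reporting), and Fick-convention
DO2/VO2 with Hüfner constant 1.34 mL O2/g Hb (1.39 selectable) and a
0.003 mL O2/dL/mmHg dissolved-oxygen term; central venous saturation stands
in for mixed venous saturation. Note that DO2/VO2 evaluated *at cohort-mean
inputs* (≈920/234 mL/min) differs from the *cohort mean of per-patient*
DO2/VO2 — means of nonlinear combinations are not combinations of means.

Records failing validation raise a structured error listing all violations;
derived records with PG_VR ≤ 0 are flagged, never silently dropped.

## Synthetic cohort: what it emulates

The generator reproduces, per draw:

* systemic variables with the published cohort means/SDs (HR 67.5±7, MAP
  88.1±7, CVP 7.1±0.7, SaO2 100±0, ScvO2 74.2±2.3, Hb 14.1±0.94, ...),
  sampled as truncated normals (rejection sampling) with physiologic floors;
  SAP/DAP are tied to MAP through a sampled pulse pressure;
* per-patient log-normal RBC velocity distributions with patient-specific
  means. The pooled target is 15±9 μm/s, moment matched on the log scale
  (σ²_tot = ln(1+9²/15²) ≈ 0.3075, μ = ln 15 − σ²_tot/2 ≈ 2.554). The
  within-patient log-sd defaults to 0.25 — per-patient distributions are
  visibly narrower than the spread of their means — and the between-patient
  spread is the remainder, so the mixture pools back to exactly the target
  moments;
* the piecewise Pmca–velocity coherence coupling: patients with mean
  velocity in the closed 6–24 μm/s band receive Pmca = 14 mmHg plus
  a jitter of sd 0.25 mmHg truncated at ±3σ (so plateau Pmca prints as
  14.0 and the plateau is a bounded band); faster patients draw Pmca
  uniformly from [11, 14) mmHg. Patients below 6 μm/s are not generated
  (no reported behaviour in that regime); the left truncation this induces
  on the patient-mean distribution is compensated analytically (the
  between-patient log-mean is shifted by a one-dimensional root solve of the
  truncated log-normal mean) so the accepted cohort still pools to 15 μm/s;
* vessel geometry: diameter ~ N(17.2, 4) μm truncated ≥ 5 μm; length
  ~ N(137.3, 96.8) μm truncated to ≥ max(30 μm, 2 × diameter) so every
  segment is meshable. Because the length sd exceeds half its mean, the
  truncated length mean (~160 μm) necessarily exceeds the 137.3 μm target —
  a documented property, not a defect;
* sublingual density/flow scores (De Backer, consensus PPV) as sampled
  pass-through columns, never computed from images.

Generation order is velocity regime → Pmca target → cardiac output
back-solved from the Pmca model (records violating CO > 0 are resampled, with
a hard limit of 1000 consecutive rejections). This keeps the coherence
coupling and the Pmca algebra simultaneously exact on every record, at the
price that generated CO (mean ≈ 6 L/min) runs somewhat above the published
4.8±1 — the plateau value of 14 mmHg back-solves to CO ≈ 6.3 L/min at
cohort-mean CVP/MAP. Ground-truth labels (patient log-parameters, pre-noise
Pmca, regime) are retained for recovery tests.

What the generator does **not** emulate: the positive diameter–velocity
correlation present in the clinical data, intra-patient vessel clustering,
measurement noise of the optical-flow velocimetry, or any video-level
artifact. Passing tests therefore demonstrate that the pipeline recovers the
structure the generator encodes — not that it would recover it from real
video-derived data.

## Vessel geometry and meshing

A vessel is a single unbranched 2D segment: centerline polyline plus
per-point lumen width (μm). Walls are normal offsets at ±width/2 (rejected if
the half-width exceeds the local curvature radius), the inlet/outlet are the
end cross-sections, and the mesh is a structured body-fitted quadrilateral
grid by transfinite interpolation (default 250 × 20 = 5000 cells, ≥ 20
across the width). Segments can be recovered from 8-bit masks by
morphological skeletonization with widths from the Euclidean distance
transform; ends are trimmed by one local width because distance-transform
widths are biased at vessel caps (this deliberately shortens the recovered
segment). Branching or multi-component masks are rejected. All mesh
coordinates are SI metres; μm appear only at the I/O boundary. Meshes and
fields export as legacy ASCII VTK (quad cells, boundary tags as cell data).

## The flow solver

Steady incompressible Newtonian laminar flow (ρ = 1050 kg/m³,
ν = 3.2 × 10⁻⁶ m²/s — the published viscosity is printed with the units
m³ s⁻¹, which is dimensionally untenable for a kinematic viscosity and is
read as m²/s). Finite volumes on the collocated, cell-centered structured
grid; SIMPLE pressure–velocity coupling with Rhie–Chow face-flux
interpolation; under-relaxation 0.7 (momentum) / 0.3 (pressure). Boundary
conditions: uniform plug inlet velocity (each vessel's mean RBC velocity),
fixed gauge pressure at the outlet, no-slip rigid walls.

Numerical choices that matter:

* **Convection by deferred correction.** At microcirculatory Reynolds
  numbers (Re = Uh/ν ≈ 10⁻⁴) convective coefficients are ~8 orders below
  diffusive ones, so convection lives entirely in the explicit
  deferred-correction source (central/upwind blend, central by default) over
  a constant implicit operator (diffusion + relaxation). The momentum and
  pressure-correction matrices are therefore LU-factorized once per case,
  which is what makes 1000+ cohort solves cheap. The converged solution
  still satisfies the full discretized equations including convection. The
  solver warns above Re = 100 (laminar assumption stressed).
* **Second-order wall shear.** The two-point wall-normal gradient is
  upgraded by a deferred one-sided three-point (quadratic) gradient; this
  makes the discrete fully developed profile—and hence the Poiseuille
  pressure drop—second-order accurate (0.13% error at 20 cells across the
  width, 0.03–0.04% after one uniform refinement).
* **Residual normalization.** Momentum residuals are scaled by
  ṁ_in·U_in and continuity by ṁ_in, so the 10⁻⁶ convergence criterion is
  mesh- and unit-independent. Convergence implies a global mass imbalance
  |Q_in − Q_out|/Q_in at the same order (≤ 10⁻³ is asserted).
* **Δp measurement.** Area(length)-weighted mean pressure over transverse
  sections; the default is inlet→outlet. Because the plug inlet carries a
  development excess (~9% of the Poiseuille drop at L/h ≈ 8), solver
  validation measures Δp over the downstream 80% of the channel, where the
  flow is fully developed (the creeping-flow development length is below one
  channel height). Any two sections can be requested; measurements on
  unconverged solutions are refused.

Validation: across straight channels with h ∈ {10, 17.2, 25} μm,
L ∈ {100, 137.3, 300} μm and U ∈ {6, 15, 24, 40} μm/s, the solved Δp agrees
with 12μLU/h² to better than 0.2% at the default mesh; Δp is linear in the
inlet velocity to < 1% for a 0.5–4× range; residual histories are
bit-identical across reruns of the same mesh and configuration.

## Statistics

Per-patient velocities are fitted as log-normals by maximum likelihood
(mean/sd of logs) with a Kolmogorov–Smirnov check of the logs against the
fitted normal. Group comparison uses Kruskal–Wallis (the standard rank-based
non-parametric one-way ANOVA). Correlations are Kendall's τ-b (tie-corrected;
the data contain ties) and Spearman's ρ, two-sided p-values, α = 0.05.
Reflecting the 20-subject clinical sample, correlations are accompanied by a
pairs bootstrap with n = 30 resamples by default (configurable): percentile
intervals (BCa is not meaningful at 30 replicates), point estimate the
replicate mean, degenerate replicates redrawn, fully seeded. The Pmca–Δp
correlation is reported at both the per-patient unit (Δp averaged over a
patient's vessels) and the per-vessel unit (where Δp is actually computed);
the analysis does not model vessel-within-patient nesting, and no
multiple-testing correction is applied — both stated limitations.

The plateau estimator reports mean/sd/count of Pmca over patients whose mean
velocity lies in the closed 6–24 μm/s band, with an explicit empty result
when no patient qualifies.

## Problem sizes

Defaults chosen for the shipped analyses: 20-patient cohorts (3 vessels ×
40 velocity samples each) for pipeline runs, 200-patient cohorts for
calibration and plateau recovery; solver validation at 250 × 20 cells with
one 500 × 40 refinement study; cohort CFD batches at 48 × 12 cells per
vessel, where the straight-channel discretization error (< 0.4%) is far
below the between-vessel geometric variability that the rank statistics
operate on.

## Known limitations

* 2D, steady, rigid-walled, Newtonian, single-phase flow only; no
  Fåhræus–Lindqvist rheology, pulsatility, or network topology.
* The generator samples vessel geometry independently of velocity; the
  clinical data show a strong positive diameter–velocity correlation, so the
  synthetic joint tails (fast flow in long narrow vessels) produce a wider
  Δp spread than clinically observed — Δp for a few percent of sampled
  vessels exceeds 1 Pa even though the clinical band is 0.02–0.1 Pa.
* With pooled velocity moments pinned at 15±9 μm/s, at most ~13% of patients
  can lie in the fast (> 24 μm/s) regime; with 20-patient cohorts the
  Pmca–Δp rank correlation is negative in roughly 8 of 10 cohorts, not
  always — the coherence signal rides on the few fast-vs-plateau patient
  pairs, exactly as in the small clinical sample.
* Mask-derived geometry is a documented stand-in for an unspecified
  image-processing pipeline; quantitative claims rest on analytic
  geometries.
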