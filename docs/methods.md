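# Methods

This note documents the models, numerical choices and limitations of
`cowflow`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the worked example, not
asserted from memory.

## From duplex envelopes to boundary flows

Duplex ultrasound reports, per cardiac cycle, the Doppler *envelope*
velocity (the spectral maximum) at each of the four cerebral inflow
arteries (LICA, RICA, LVA, RVA) together with a B-mode lumen diameter.
Processing follows the standard chain:

- **Ensemble averaging.** Each cycle is fitted with a periodic cubic
  smoothing spline whose smoothing budget caps the RMS deviation from
  the samples at 1% of the signal RMS (the fit must denoise, not
  reshape), resampled to a uniform phase grid, circularly shifted so its
  global maximum lands at the alignment phase (default 0.25), and
  averaged pointwise. Peak alignment prevents systolic smearing when
  cycle lengths vary; the output period is the mean of the input
  periods. Any consistent alignment phase is valid because every
  downstream comparison is phase-consistent.
- **Poiseuille conversion.** The envelope tracks the centreline
  (maximal) velocity. Under a parabolic profile the cross-sectional mean
  is half the centreline value, so `Q(t) = ½ V_env(t) · π(D/2)²`. The ½
  factor is exposed as a configuration constant because envelope-vs-mean
  conventions differ between laboratories; if a recording already stores
  intensity-weighted mean velocity the factor is 1.
- **Diameter** is a single time-averaged value per recording. A rigid
  lumen is assumed throughout, consistent with the rigid-wall simulation
  downstream.
- **tCBF** is the sum of the time-averaged flows of the four inflow
  waveforms. Negative envelope samples are rejected rather than clipped:
  the inflow arteries are antegrade in this protocol, so a negative
  sample indicates a tracing error, not reverse flow.

## Outlet boundary conditions

Outflow is prescribed in two stages. First, total inflow is split across
seven cerebral territories (left/right middle, left/right posterior,
anterior, cerebellum, ophthalmic) by a regional fraction table. The
regional fractions used by the original outflow code are not published
with the method, so the table is a required input; the package ships a
clearly-labelled provisional default (anterior 0.18, each middle 0.25,
each posterior 0.10, cerebellum 0.09, ophthalmic 0.03) that is used by
the synthetic cohort and the tests. The middle-cerebral dominance and
small ophthalmic share follow textbook perfusion proportions; the exact
values are a stand-in, and study-specific tables (possibly per
participant and condition) should be supplied for real analyses.

Second, within a territory, flow is divided among outlets by the
diameter-power rule `Q_i ∝ d_i^n` with exponent n = 2.33, computed in
log space so extreme exponents stay finite. The split fractions are
scale-invariant in the diameters, monotone in each diameter, and
interpolate between an even split (n → 0) and winner-take-all (n → ∞).
Conservation then holds at every phase point by construction, at
region and global level.

Extrusion lengths (11 × boundary diameter) are computed for the export
manifest only: they matter for developing flow in a 3D solver, while the
network surrogate needs no development length.

## The quasi-steady network surrogate

The reference method solves 3D finite-volume Navier–Stokes on
subject-specific geometry. `cowflow` replaces that with a deliberately
reduced model so the flow-conserving structure can be studied at desk
scale:

- Each phase point of the cardiac cycle is an independent steady solve
  (quasi-steady approximation). Fluid inertia between instants —
  Womersley effects — is neglected; at CoW scales the inertial phase
  lag mainly reshapes waveforms, while the flow *routing* that the
  comparison depends on is set by conductances and conservation. No
  multi-cycle warm-up is needed.
- Segments are uniform rigid cylinders with laminar Poiseuille
  conductance `G = πD⁴/(128 μ_eff L)`; tapering vessels are represented
  by subdividing segments in the network file. The nodal-pressure system
  `Lp = b` (graph Laplacian of conductances, prescribed boundary
  injections, one node pinned to zero) is solved batched across phase
  points.
- Blood shear-thinning enters through an effective viscosity per
  segment, evaluated at the Poiseuille wall shear rate `γ̇ = 8v̄/D`
  (other characteristic-shear conventions exist; this one matches the
  wall value of the parabolic profile). The Carreau–Yasuda parameters
  (η_∞ = 0.0022 Pa s, η₀ = 0.022 Pa s, λ = 0.11 s, a = 0.644,
  n = 0.392) are a published set for blood in and around the CoW.
- The viscosity nonlinearity is resolved by fixed-point iteration from
  μ = η₀, with per-element progressive damping: each time an element's
  update changes sign its damping factor halves (floor 1/64). Shear
  rates below 10⁻⁶ s⁻¹ are treated as exactly zero: in dead branches the
  linear solve leaves round-off flow (~10⁻²² m³/s), and the fractional
  power (λγ̇)^a amplifies that jitter above the 10⁻¹⁰ relative
  convergence tolerance unless it is floored. Physiological wall shear
  rates are O(10²–10³) s⁻¹, so the floor is inert for any real flow.
- Outputs: signed segment flow, mean and maximal velocity
  (v_max = 2v̄, the parabolic-profile relation), wall shear stress
  τ_w = 32 μ_eff Q/(πD³), effective viscosity, and nodal pressures
  relative to the pinned reference (absolute pressure is undetermined
  when all boundaries prescribe flow).

What the surrogate preserves from the 3D method: exact mass
conservation, the two-stage outlet distribution, shear-thinning
rheology, rigidity, laminarity, and proportional routing through
collateral loops (communicating arteries). What it cannot show:
secondary/recirculating flow, skewed velocity profiles at bends and
junctions, Womersley phase lag, or spatial WSS patterns. Velocity
magnitudes therefore differ from a 3D solution in detail; comparisons
that depend on flow conservation and scaling (the package's purpose)
are preserved.

The grid-convergence-index routine implements the Richardson-style
estimate `GCI = F_s |(f_coarse − f_fine)/f_fine| / (r^p − 1)` with
safety factor 1.25 and the 3% mesh-independence criterion. It exists to
verify reference 3D solutions; the network surrogate itself has no mesh.

## Velocity metrics

The simulated TCD envelope is the station-averaged maximal velocity at
three planes at 25/50/75% of the M1 path. In the quasi-1D model a
uniform M1 makes the stations coincide; the three-plane interface is
retained for fidelity with how 3D solutions are sampled against TCD.
Metrics: systolic = cycle maximum, time-averaged = cycle mean,
end-diastolic = the final sample of the peak-aligned cycle (the instant
before the next upstroke). An alternative end-diastole definition
(minimum over the last 20% of the cycle) is selectable; the two agree
for clean envelopes and differ only under late-cycle noise. Relative
change is `Δ% = 100·(stimulus − rest)/rest` per metric, defined only
for positive resting values.

## Statistics

Differences are oriented TCD − CFD throughout (TCD envelope methods read
systematically higher). Paired t-tests and Pearson correlations are
two-sided at α = 0.05; Shapiro–Wilk flags non-normality but does not
switch the tests to a non-parametric fallback (flags are reported
alongside). Bland–Altman agreement uses bias ± 1.96·SD limits and an
ordinary-least-squares slope of difference on pairwise mean as the
proportional-bias estimate with its two-sided p-value. No
multiple-testing correction is applied by default, matching the
single-comparison reporting convention of method-agreement studies; a
Holm adjustment is available (`run_study(..., holm=True)`). Degenerate
cells (zero-variance differences, constant vectors) are flagged rather
than silently dropped.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes,
calibrated to published group statistics in healthy adults:

- **Flows.** Per-artery resting time-averaged flows are truncated
  normals with means/SDs 268.9 ± 63.3 (LICA), 218.8 ± 74.2 (RICA),
  74.2 ± 26.4 (LVA) and 56.2 ± 18.3 (RVA) mL/min, so resting tCBF is
  centred on 618.1 mL/min. Condition flows are the participant's resting
  flows scaled by log-normal response factors centred on the group
  condition-to-rest ratios (hypercapnia ≈ +40%; exercise ≈ +5–20%),
  with log-scale spread 0.20 — sized to the reported between-participant
  dispersion of relative velocity changes (≈25–30 percentage points) —
  and correlation 0.5 between arteries within a participant (the true
  correlation of responses is unreported; it is exposed as
  configuration).
- **Waveforms.** A mean-one triphasic envelope shape (systolic peak at
  phase 0.25 with a dicrotic shoulder, truncated to 4 Fourier
  harmonics) with pulsatility (peak−min)/mean = 1.2; three cycles per
  recording with 3% log-normal cycle-to-cycle amplitude and period
  jitter; periods from per-condition heart rates (rest 68.7 ± 9.5,
  hypercapnia 74.1 ± 8.1, exercise 120.4 ± 21.3 bpm). The diameter is
  chosen so Poiseuille conversion of the envelope recovers the drawn
  flow, with ICA/VA envelope time averages of 50/35 cm/s.
- **Networks.** A complete-CoW template (ICAs, vertebrals joining the
  basilar, M1/M2, A1/ACoA/A2, P1/PCoA/P2, cerebellar and ophthalmic
  branches; every territory holds at least one outlet) with diameters
  log-normally jittered at 5% CV per participant.
- **TCD bias.** Each participant receives multiplicative bias factors
  (defaults: systolic 1.5, time-averaged 1.7, end-diastolic 1.9,
  between-participant SD 0.15) held constant across conditions. The
  envelope-level bias interpolates smoothly between the end-diastolic
  factor (at the envelope minimum) and the systolic factor (at the
  peak), so the systolic metric scales by exactly the systolic factor
  while the realised time-averaged bias emerges from the interpolation.
  The defaults sit inside the reported ranges by which envelope TCD
  exceeds simulated velocity (roughly 33–73% systolic, 62–85% average,
  85–106% end-diastolic); they are calibration defaults, not ground
  truth. Measurement noise is a smooth multiplicative log-normal
  modulation (constant plus first harmonic, per-phase CV 0.05,
  mean-corrected) — smooth so that the cycle maximum is not inflated
  the way white noise would inflate it.
- **Determinism.** Everything derives from a master seed through
  spawned substreams per participant (and per condition/artery within a
  participant), so cohorts are bit-reproducible and regenerating one
  participant never perturbs another.

Because the bias is constant within a participant, the generator
reproduces by construction the qualitative signature the statistics are
meant to expose: absolute TCD–CFD disagreement with relative-change
agreement. Passing tests on this cohort therefore validate the
*machinery* (conservation, extraction, statistics, bias cancellation) —
they cannot validate whether real TCD bias is in fact multiplicative and
participant-constant, nor reproduce participant-level physiology
(autoregulation, posture, spectral broadening mechanisms, waveform-shape
changes under stimuli are all absent).

## Problem sizes and numerical defaults

Phase resolution defaults to 200 samples/cycle for standalone solves and
96 for the cohort pipeline; raw synthetic recordings carry 64
samples/cycle. These resolutions put discretisation error of the cycle
mean and maximum well below the 5% noise floor of the synthetic data.
The Monte-Carlo parameter-recovery study uses 200 cohorts of 12
participants — small enough to run on one CPU in minutes, large enough
that the Monte-Carlo error of the recovered mean bias (<1%) is far
inside the 5% acceptance band. Fixed-point tolerance is 10⁻¹⁰ (relative
viscosity change), conservation checks at 10⁻⁹ relative, and region
tables must sum to 1 within 10⁻¹².

## Known limitations

- The regional fraction table is provisional (see above).
- Quasi-steady flow: no inertial phase lag; pulse-wave propagation and
  compliance are absent by design (rigid walls).
- The M1 three-plane sampling degenerates to a single value in a
  uniform quasi-1D segment.
- End-diastolic extraction assumes peak-aligned cycles.
- The synthetic TCD bias model is multiplicative and smooth; real
  envelope artefacts (spectral broadening, angle error, probe drift)
  have richer structure.
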