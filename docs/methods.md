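# Methods

This note documents the models, numerical choices and known limitations of
the `enafl` package: an axisymmetric Pennes bioheat simulation of a single
endoscopic non-ablative fractional laser (eNAFL) spot, thermal-field
summaries, ordinal tumour-grading statistics, and the synthetic-data
generators that stand in for the animal experiments.

## Bioheat model

Tissue is an axisymmetric cylinder of radius R = 5 mm and thickness
h = 500 µm (thin slab) or h = 5 mm (thick variant).  Temperature T(r, z, t)
obeys the heat diffusion equation with the Pennes perfusion term:

    ρ C_p ∂T/∂t = ∇·(k ∇T) + ρ_b C_b ω_b (T_b − T) + Q_m + Q_laser .

The perfusion term is written with the physically correct sign — perfusion
is a distributed heat *sink* pulling tissue toward the arterial temperature
T_b whenever T > T_b; the opposite sign would make blood flow self-heating.

The laser enters as a **top-surface Neumann flux**

    q(r) = A exp(−r² / 2σ²),   A = P / (2π σ²),

so that 2π∫ q r dr = P exactly.  The width convention is pinned to
**σ = d/6** (the stated 200 µm beam diameter spans ±3σ of the 1-D marginal,
which carries 99.7 % of the power along a line cut through the centre);
σ = d/3 is available for sensitivity runs.  Heating lasts t_on = 2 s at
P = 35 mW (70 mJ per spot), followed by free cooling.  The entire outer
boundary is insulated; the axis uses the symmetry condition ∂T/∂r = 0.
The initial condition is uniform T = T_b.

Volumetric absorption of the 1927 nm beam (penetration depth ~100–200 µm in
water) is deliberately out of scope: the source is a pure surface flux.

### Tissue and blood constants

The simulation needs eight material constants that are not fixed by the
problem statement; the package pins a literature-typical soft-tissue set and
treats it as a documented reference configuration, **not** as measured colon
values:

| symbol | meaning | default | unit |
|---|---|---|---|
| k | tissue conductivity | 0.5 | W m⁻¹ K⁻¹ |
| ρ | tissue density | 1090 | kg m⁻³ |
| C_p | tissue specific heat | 3400 | J kg⁻¹ K⁻¹ |
| ρ_b | blood density | 1050 | kg m⁻³ |
| C_b | blood specific heat | 3617 | J kg⁻¹ K⁻¹ |
| ω_b | perfusion rate | 1×10⁻³ | s⁻¹ |
| T_b | blood / baseline temperature | 37 | °C |
| Q_m | metabolic heat | 420 | W m⁻³ |

Over the 10 s simulated window perfusion and metabolism are nearly
negligible (the perfusion decay rate ρ_b C_b ω_b / ρC_p ≈ 1.0×10⁻³ s⁻¹);
they are retained because the solver must support them and because the
closed-form perfusion limit is one of the validation oracles.

## Discretisation

A vertex-centred finite-volume scheme on a graded tensor-product (r, z)
mesh, advanced by an implicit θ-scheme (backward Euler θ = 1 by default;
Crank–Nicolson θ = 0.5 available).  Key properties:

* **Exact discrete energy balance.**  Conductances have zero row sums and
  the per-node source powers are the *analytic* integrals of the Gaussian
  flux over each annular face, so with perfusion off the enthalpy gain at
  the end of heating equals P·t_on to machine precision (the 1 % acceptance
  check passes at ~10⁻¹²).
* **Discrete maximum principle.**  Backward Euler with an M-matrix: with the
  source off the spatial maximum cannot grow.
* **Unconditional stability**; the linear system is factorised once per
  phase (`scipy.sparse.linalg.splu`) and re-used for every step.

Default mesh: uniform Δr = 1.5 µm out to r = 300 µm, then geometric
stretching (ratio 1.06) to the 5 mm edge; Δz grows geometrically from
0.5 µm at the irradiated surface (ratio 1.08).  Δt = 5 ms.  This resolves
both the σ = 33 µm source and the surface flux boundary layer
(∂T/∂z|₀ = q₀/k ≈ 10⁷ K m⁻¹): a uniform 5 µm surface cell would alias
~25 °C of that gradient, which is why the near-surface grading is not
optional.  Refining every spacing and the time step 2× moves the reported
peak by < 0.2 °C (the acceptance property requires < 0.5 °C).  The thin-slab
run uses ≈ 17 000 nodes and completes in seconds on one CPU; the thick
variant ≈ 26 000 nodes.

The solver is validated against two closed forms (unit tests):

* semi-infinite Gaussian-flux heating,
  T(0,0,t) = T_b + (q₀σ/k)√(2/π)·arctan(√(2αt)/σ), matched to < 0.7 %
  by the thick slab before its boundaries are felt;
* the k = 0 perfusion decay exp(−ρ_b C_b ω_b t / ρC_p), matched to < 0.1 %
  over 10 s.

## Known discrepancy: absolute peak temperatures

Reference values quoted for this experimental configuration — a 65.5 °C
peak for the thin slab and 50 °C for the thick block at t = 2 s, computed
with a commercial finite-element model meshed with a single element through
the slab thickness — are **not reproduced** by this solver, and cannot be
reproduced by any convergent solver of the stated surface-flux model.  With
the full 35 mW absorbed in a σ = 33 µm Gaussian surface spot and
k = 0.5 W m⁻¹ K⁻¹, the semi-infinite closed form above already gives a
407 °C rise at t = 2 s (the package computes 447.5 °C thin / 443.5 °C thick,
consistent with that closed form plus boundary effects).  No re-reading of
the width convention rescues the reference pair: the thin-minus-thick
difference scales with the absorbed power at fixed σ while the absolute
rise scales with power/σ, and no (power, σ) combination fits both quoted
numbers at once.  The likely origin of the lower reference values is the
single-element vertical resolution against a boundary-layer gradient of
10⁷ K m⁻¹.  The acceptance checks for these two quantities (and for the
over-40 °C width, which at the computed temperatures is millimetres rather
than sub-300 µm) are therefore kept at the quoted values and fail honestly;
all structural claims — peak at the axis surface exactly at the end of
heating, thin hotter than thick, monotone radial fall-off a > b > c > d —
are reproduced.

Physically, real spots stay far cooler than the pure surface-flux model
predicts because the 1927 nm beam deposits its energy over a ~150 µm
absorption depth, contact with the fibre tip conducts heat away, and any
measurement averages over instrument resolution; thermography of real spots
shows rises of ~20 °C.  Those mechanisms are intentionally outside this
model.

## Thermal analysis

* **Probe traces** interpolate snapshots bilinearly; defaults are the four
  standard surface points a–d at 0, 100, 150, 200 µm.
* **Peak summary** is the global space-time argmax; ties break toward the
  earliest time, then the smallest radius/depth (row-major pixel order for
  camera stacks).
* **Super-threshold extent** is reported as a *full lateral width*
  2·max{r : T > threshold} over all snapshots and depths (diameter-like, to
  compare with the 200 µm fibre core), with the outermost crossing refined
  by linear interpolation between nodes.  Thresholds at or below baseline
  are rejected.
* **Trace metrics**: peak rise above baseline, first time the maximum is
  attained, and the first post-peak time back within a configurable band
  (default 1 °C) of baseline.  For camera stacks the baseline is the mean of
  pre-heating frames when a laser-on time is known, else the first frame.
* **Site ranking** sorts labelled traces by peak rise, stably.

## Grading scale and statistics

Grades follow the endoscopic 0–5 scale on the covered fraction f of the
colonic circumference, with inclusive "up to" boundaries: grade 0 =
invisible under white light but fluorescent; grade 1: f ≤ f₁; grade 2:
f ≤ 1/8; grade 3: f ≤ 1/4; grade 4: f ≤ 1/2; grade 5: f > 1/2.  The
grade-1 bound f₁ ("very small but detectable") is not standardised and is
exposed as configuration with default 0.02.

The Mann-Whitney U test is **exact**: the null distribution is built by
complete enumeration over all C(n₁+n₂, n₁) group labelings of the observed
pooled values, with ties contributing mid-ranks (½ per tied pair).  The
implementation uses a generating-function dynamic programme over doubled
mid-ranks, which is integer-exact and equivalent to enumeration; the test
suite cross-checks it exhaustively against a literal labeling-enumeration
oracle for all small tied configurations.  For pooled n > 25 a seeded
Monte-Carlo permutation fallback is used and flagged.  With 5 vs 4
completely separated samples the one-sided p equals the attainable minimum
1/126 = 0.0079.  Group comparisons default to the one-sided alternative
"irradiated < control" (the direction the therapy acts in); this choice is
prominent in the API and the two-sided test is always available.  No
multiple-testing correction is applied across days — deliberately, to match
the analysis being reproduced; this is a reporting choice, not a
recommendation.

Success percentages are rounded half-up to one decimal (3/15 → 20.0,
6/8 → 75.0, 12/13 → 92.3).  Pearson correlation uses the t transform with
n − 2 degrees of freedom.  The growth delay is the difference of group
medians of the per-mouse first day at or above grade 3; mice that never
reach it are censored at last day + 1 and counted, and a fully censored
group is flagged rather than silently numeric.

## Synthetic data generators

All generators take an explicit seed, are bit-reproducible, and return
their ground truth alongside the data.

* **Grade trajectories.**  The latent log-odds of the covered fraction is
  linear in time (logistic growth, bounded at 1 as a circumferential
  fraction must be): λ(t) = logit(s₀) + g·(t − delay), with defaults
  s₀ = 0.004, g = 0.9 day⁻¹, delay = 2 days for treated mice.  Noise is a
  per-mouse random intercept (sd = noise_sd = 0.35) plus per-day jitter
  (sd/2) on the latent scale, so ties arise naturally after grade
  discretisation.  The day-1 inclusion criterion (every mouse grade 0/1) is
  emulated by per-mouse rejection sampling; parameter sets whose noise-free
  day-1 grade already exceeds 1 are rejected outright.  The noise sd was
  calibrated once so cohorts reproduce the qualitative pattern of late
  separation; with these defaults the median delay estimate over 200 seeds
  is 2.0 days and essentially every cohort has at least one day with
  p < 0.05.
* **Fluorescence pairs.**  Sizes are drawn stratified across the six grade
  bands (a cohort spanning the scale); the signal is
  base·size·exp(−a·size)·lognormal-noise.  The default a = 8.79 is the root
  of the population moment condition cov(grade, signal) = 0 under this size
  draw, so the population correlation is ≈ 0 by construction; at a = 0 and
  zero noise the signal is strictly increasing in size (sample r ≈ 0.9).
* **Thermography frames.**  ΔT(x, y, t) = A·exp(−ρ²/2σ²)·min(t/t_on, 1)·
  exp(−max(0, t−t_on)/τ) + N(0, noise_sd²), defaults: 64×64 pixels at 25 µm
  pitch, A = 20 °C, σ = 88 µm (FWHM ≈ 207 µm, the mucosal lesion scale),
  t_on = 2 s, τ = 1 s, 10 Hz for 6 s, noise 0.2 °C.  Site centres sit on
  integer pixels so the noiseless construction is recovered exactly.
* **Implantation outcomes.**  Per-method Bernoulli draws at rates
  0.20 / 0.75 / 0.923 with n = 15 / 8 / 13; a fixed reference table (3/15,
  6/8, 12/13) bypasses randomness for the validation examples.

What the generators do *not* emulate: real endoscopic images, inter-rater
grading variability, camera emissivity/calibration artefacts, or any
correlation between a mouse's thermal exposure and its later grades.
Passing tests therefore demonstrate that the estimators recover the
generating process, not that the biological effect sizes are correct.

## Shipped fixtures

`enafl/data/grades_synthetic.csv` is a **synthetic** 9-mouse, 7-day grade
table (the per-mouse grades behind the original comparison are
unpublished): trajectories are monotone, day-1 grades are 0/1, day 6 is
completely separated (one-sided exact p = 1/126 = 0.0079), day 7 gives
p = 4/126 = 0.0317, and the estimated growth delay is exactly 2 days.
`enafl/data/implantation_outcomes.csv` holds the fixed reference counts.

## Degenerate inputs and tie-breaks

Zero conductivity is allowed (perfusion-only decay oracle); zero power runs
stay at T_b exactly; a source narrower than twice the core spacing is
refused as under-resolved; thresholds at or below baseline are refused;
probe points outside the mesh are rejected by label; empty samples, zero
variance and n < 3 are rejected in the statistics layer.  All argmax
tie-breaks are documented above and fixed, so runs are deterministic.
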