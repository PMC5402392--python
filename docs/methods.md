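# Methods

## Signal model

Tissue is modelled as two longitudinal magnetization pools: free water (F)
and semi-solid macromolecular protons (B), with equilibrium sizes
M0F = PD·(1−f) and M0B = PD·f, where f is the macromolecular proton
fraction (MPF). The pools exchange with forward rate k_FB = R·f and reverse
rate k_BF = R·(1−f) (detailed balance holds by construction), and each pool
has its own R1 and T2. During an off-resonance pulse the pools are
saturated at rates

    W_F = π·ω1rms²·g_L(Δ, T2F),    W_B = π·ω1rms²·g_SL(Δ, T2B),

with g_L the Lorentzian lineshape of the liquid pool and g_SL the
super-Lorentzian powder average of the semi-solid pool,

    g_SL(Δ) = √(2/π) ∫₀¹ T2B/|3u²−1| · exp(−2(2πΔ·T2B/(3u²−1))²) du,

evaluated by fixed 256-node Gauss–Legendre quadrature (doubling the node
count changes the value by <1e-6 relative at the protocol offset; the
integrand's on-resonance divergence is excluded by a 1 kHz validity floor,
far below the 4.5 kHz operating offset even after B0 shifts). The pulse
power metric ω1rms is computed from the sampled envelope: for the protocol's
Gaussian pulse, σ = t_m/6 (±3σ truncation), 512 samples, peak scaled so
∫ω1 dt equals the 900° effective flip.

The MT-weighted SPGR steady state treats each TR as: saturation pulse of
duration t_m (generator = relaxation–exchange matrix minus diag(W_F, W_B)),
instantaneous excitation by α·B1 acting on the free pool only (the standard
far-resonance small-tip treatment), then free relaxation–exchange for
TR − t_m. Each segment's affine propagator is built from the closed-form
2×2 matrix exponential (spectral decomposition with an expm1-stabilized
near-degenerate branch), and the steady state is the fixed point of the
composed affine map. Everything broadcasts over numpy arrays, so whole
volumes are solved in a handful of vectorized operations; a brute-force
oracle (scipy expm + 2000-TR iteration) agrees with the fixed point to
better than 1e-6 relative across the tested f × R1 grid. Ideal spoiling is
assumed; readout TE decay is ignored because TE is common to the
quantitative sequences.

## Single-point inversion

Only f is fitted per voxel. The remaining two-pool parameters come from the
standard single-point constraint set — R = 19 s⁻¹, T2B = 10 µs,
T2F·R1F = 0.022, R1B = 1 s⁻¹, all configurable — and from the observed
relaxation rate R1 = 1/T1 measured by the two-point VFA fit. The VFA R1 is
interpreted as the slow eigenvalue of the coupled relaxation–exchange
system, and the free-pool rate is recovered from it at each candidate f by

    R1F = R1_obs − k_F + k_F·k_B/(R1B + k_B − R1_obs),

which makes the 2×2 generator's slow eigenvalue equal R1_obs exactly. The
measured ratio of the MT-weighted image to the synthetic reference (the
Ernst signal at the MT sequence's TR and B1-corrected flip) is inverted by
bisection on f ∈ [0, 0.45] — the model ratio is strictly decreasing in f at
pulsed-MT settings — refined by secant steps to |Δf| < 1e-6. Ratios outside
the model's attainable range are flagged invalid (NaN); on noisy voxels the
constraint assembly is clamped to stay in the physical domain so the
vectorized scan can proceed (such voxels fail the bracket test anyway).
B0 shifts the effective saturation offset; B1 scales both ω1rms (hence W
quadratically) and every flip angle. Voxels below five times the background
noise floor in the PD-weighted image are excluded, and the invalid-voxel
fraction is logged. MPF is reported in percent.

## Field maps

- **B1 (AFI):** the dual-TR signal ratio r = S2/S1 gives
  cos α ≈ (rn−1)/(n−r), n = TR2/TR1. This closed form is a short-TR
  approximation with ~1e-3 error at T1 ≥ 1 s; because the phantom
  validation targets biases far below that, the pipeline optionally (and by
  default) re-inverts the ratio exactly once the VFA R1 is available — the
  exact two-TR steady state is solvable for cos α given E1, E2
  (`afi_b1_exact`), which removes the approximation bias.
- **B0 (dual-TE GRE):** the phase difference is wrapped to (−π, π], giving
  offsets within ±1/(2ΔTE) = ±294 Hz at the 1.7 ms echo spacing. No spatial
  unwrapping is performed; at the simulated shim quality the brain stays
  inside the principal range (a documented limitation for worse shims).
- **Consumption:** both maps are acquired at half in-plane resolution.
  Invalid/low-signal voxels are filled from the nearest trusted voxel (so
  background values cannot bleed into the object during interpolation), the
  box-average-to-center curvature offset of the coarse voxels is removed by
  a discrete-Laplacian correction (weight (k²−1)/(24k²) for a k× block),
  and the maps are upsampled with cell-centered cubic splines — exact for
  the smooth low-order fields B0/B1 exhibit; trilinear interpolation
  remains available. These steps matter because MPF responds with ~15 pp
  per unit B1 error: together they keep the systematic reconstruction bias
  near 1e-3 percentage points.

## The digital phantom

The phantom stands in for the study animals: six structures (corpus
callosum, anterior commissure, internal capsule, thalamus, caudoputamen,
cortex) drawn as schematic ellipses/shells in a coronal plane and extruded
over the central slices of a 96×96×24 grid at 0.1×0.1×0.5 mm — validation
needs labels, not anatomy. Unlabeled brain tissue is a GM-like filler;
background has PD = 0. Each structure carries a group-level MPF from the
published control/cuprizone summary table (e.g. corpus callosum
13.15 ± 0.73% control, 9.65 ± 0.95% cuprizone, n = 7 per group); synthetic
animals draw structure means from those normal distributions, and optional
seeded within-structure jitter is available. T1 (WM 1.6 s, GM 1.9 s at
11.7 T) and relative PD (0.85/1.0) are assumptions — the study did not
report them — and are flagged as such in the ground-truth CSV.

Per-voxel two-pool parameters are assembled through the same constraint set
the solver uses (R1B = 1 s⁻¹, R1F from the eigenvalue relation at the
target observed R1 = 1/T1, T2F from the product constraint), so the ground
truth is model-consistent and reconstruction errors measure the pipeline
rather than constraint mismatch; an `independent` mode (R1F = R1B = 1/T1)
is provided for deliberate model-mismatch studies, where constraint bias of
order 1 pp appears.

The acquisition simulator produces the five-sequence session: the
MT-weighted volume from the full two-pool matrix model with the local
B0/B1; the no-saturation readouts (T1w/PDw, AFI, dual-TE GRE) as ideally
spoiled steady states at the observed R1 — these sequences probe the
mono-exponential recovery of the coupled system, the same slow-eigenvalue
reading the solver assumes, and modelling them with an unexcited bound-pool
reservoir would instead measure a different (bi-exponentially biased)
quantity than VFA is defined to estimate. Field-mapping scans are
simulated at half in-plane resolution by block-averaging (a coarse voxel
integrates over its footprint). Magnitude images receive Rician noise (two
independent Gaussian channels); the phase pair is formed from noisy
quadratures, so phase noise is SNR-consistent. The default noise sets the
Gaussian channel SD to 1% of the mean white-matter MT-weighted signal.

Synthetic LFB sections render the myelin truth through the inverse of the
pooled MPF–OD calibration (slope 0.135 MPF%/OD%, intercept 5.941 MPF%),
clip OD to [0, 100]%, and encode it in the red channel as
I_R = I_B·(1 − OD/100) with seeded pixel noise, three adjacent sections per
anatomical location; green/blue channels only style the appearance.
Because histology is generated from the same truth via that linear map, the
cohort-level MPF–OD correlation is near-perfect by construction (r ≈ 1,
versus ≈0.95 in real data) — passing cohort tests therefore demonstrates
internal consistency of the two quantification chains, not biological
scatter.

## Statistics

Group comparison uses one-way MANOVA across the six structures (Wilks'
Λ = det(W)/det(W+B) with Rao's F approximation, implemented directly and
cross-checked against statsmodels), followed by per-structure equal-variance
t-tests and Cohen's d with the df-weighted pooled SD (equal n makes this the
average-variance form); d's CI uses the normal approximation to its
sampling variance. MPF–OD association uses Pearson/OLS with t-based
coefficient CIs; correlations are compared between groups by Fisher's
r-to-z, regression lines by ANCOVA (interaction test for slopes, additive
model for intercepts). Regional effects use a fixed-effects factorial
ANOVA with sum-to-zero coding and Type-III sums of squares (main effects
plus pairwise interactions; balanced designs make the SS type moot).
Repeatability uses Bland–Altman (bias ± 1.96 SD limits, one-sample t on the
differences, Levene's test on the two measurement sets) and the
within-subject CoV, aggregated across subjects as the arithmetic mean (RMS
offered as an option). Tests are two-tailed at α = 0.05 with no
multiple-testing correction. Shapiro–Wilk and Levene delegate to scipy.

Simulation sizes used by the test and acceptance suites: 1000 replicates
for the factorial-ANOVA null calibration (per-term type-I rate within
[0.035, 0.065]); 20 seeded replicates for noisy phantom recovery and for
the rescan calibration; a 7+7-animal cohort for the end-to-end study.

## Known limitations

- The phantom's geometry is schematic; there is no partial-volume mixing
  beyond nearest-label assignment, no motion, no spoiling imperfection
  (RF-spoiling phase schedules are treated as achieving ideal spoiling),
  and no ROI-placement variability — which is why simulated scan–rescan
  CoV (≪1%) sits far below values observed with manual ROI analysis.
- Published per-structure effect sizes imply limited power at n = 7/group
  for the weakest structures (thalamus d ≈ 1.3 → ~60% power), so a
  synthetic cohort does not always reach significance in all six
  structures; the corpus callosum and the overall MANOVA do.
- The two-pool constraints are literature defaults; true mouse-brain
  values at 11.7 T may differ, and all four are exposed in the
  configuration.
- On-resonance (transverse) MT effects, dipolar order/inhomogeneous MT,
  and multi-parameter Z-spectrum fitting are out of scope.
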