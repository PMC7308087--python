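# Methods

This note documents the models, estimators, and design choices in
`rtopmap`, what the synthetic generators do and do not emulate, and the
numerical conventions a maintainer needs.

## Signal model and RTOP estimation

**Acquisition.** A pulsed-gradient experiment is described by per-measurement
b-values and unit directions plus pulse timings δ (duration) and Δ
(separation). The effective diffusion time is τ = Δ − δ/3 and q-magnitudes
satisfy b = 4π²q²τ. The default scheme mirrors a public 3-shell human
connectome protocol: b = 1000/2000/3000 s/mm², 90 directions per shell
(spherical Fibonacci spiral, Haar-randomly rotated per shell under the
seed), 6 b0 volumes, δ = 10 ms, Δ = 43 ms (τ = 39.67 ms). All of this is
configurable.

**Basis.** E(q) is expanded in the separable anisotropic Hermite (MAP)
basis φ_{n}(u, q) = i^{−n}/√(2ⁿn!) · e^{−2π²q²u²} H_n(2πuq) per axis,
restricted to even total order N = n₁+n₂+n₃ ≤ radial_order, which makes
every basis function real and matches E(−q) = E(q). At the default
radial_order 6 there are 50 coefficients. A log-linear tensor fit supplies
the eigenframe rotation and the scales u_i = √(2λ_iτ); the pre-fit uses
**only the lowest shell**, because the single-tensor model is a low-b
approximation and low-b scales track the slow tail of multi-compartment
signals much better than an all-shell fit (worst-case oracle error on
mixture phantoms drops about threefold). Degenerate tensor fits fall back
to isotropic scales from the mean diffusivity, clipped to
[1e−5, 4e−3] mm²/s.

**Regularization.** The least-squares fit is penalized by the q-space
Laplacian energy ∫‖Δ_q E‖² d³q, assembled analytically from 1-D
Gauss–Hermite integrals of the basis functions and their second
derivatives (exact: the integrands are polynomial × Gaussian). The penalty
weight is dimensionless (scaled by trace(MᵀM)/trace(P)) and chosen per
voxel by generalized cross-validation over a log-spaced grid 1e−8…1, or
fixed by the caller. Positivity of the propagator is not enforced;
non-positive RTOP voxels are flagged and excluded from region means.

**RTOP.** In this basis only all-even (n₁,n₂,n₃) triples contribute:
RTOP = (2π)^{−3/2}(u_xu_yu_z)^{−1} Σ c·(−1)^{N/2} Π √((n_i−1)!!/n_i!!).
The tests verify this closed form against direct 3-D quadrature of the
fitted signal (0.1% level) and against the Gaussian-mixture oracle
Σ f_i (4πτ)^{−3/2}det(D_i)^{−1/2}. Normalized RTOP divides by the
free-water value: nRTOP = RTOP·(4πτ·D_free)^{3/2}, D_free = 3.0e−3 mm²/s
(body-temperature water), so free diffusion gives exactly 1. Normalization
is applied per voxel before any surface averaging.

**Noise.** The generators use Rician magnitude noise with SNR defined on
the b0 signal. Fitting accepts an optional known noise level `noise_sigma`
and then removes the magnitude noise floor with the moment correction
ŝ = √(max(s² − 2σ², 0)) (the second moment of a Rician is ν² + 2σ²).
Without the correction, RTOP at SNR 30 is biased upward by roughly a third;
with it the median shift is a few percent.

**Generator realism and a physics limit.** Mixture-phantom eigenvalues are
drawn uniformly in [0.5e−3, 2.5e−3] mm²/s, spanning cellular tissue water
to partial-volume free water in cortex. The floor is a deliberate physical
choice: at b_max = 3000 s/mm², a compartment with diffusivity 0.3e−3 mm²/s
still retains ~40% of its signal at the highest shell, and direct
quadrature shows that up to ~40% of its RTOP integral lies beyond the
measured q-range — no estimator can recover that mass without stronger
model assumptions, and order-6 fits err by 10–20% there. Voxels dominated
by very slow (strongly restricted, white-matter-like radial) diffusion are
therefore *underestimated* at this acquisition; this is a limitation of
the acquisition, not of the fit, and passing tests on these phantoms say
nothing about such voxels.

## Surface statistics

Volumes are sampled at vertex coordinates by trilinear (default) or
nearest-neighbor interpolation; out-of-volume vertices are missing and
excluded. Subdivision means are unweighted over finite vertices (an
area-weighted option exists). The multimodal-atlas merge maps
AVI+MI+FOP3 → dAI, AAIC → vAI, PoI1+PoI2+Ig+FOP2 → PI; all other labels
become background, and absent required labels are an error.

The two-way repeated-measures ANOVA treats subject as a random factor and
tests each within-subject effect against its own effect-by-subject
interaction, giving df = (k−1, (k−1)(n−1)); with 413 subjects this yields
(2, 824) for subdivision and interaction and (1, 412) for hemisphere. No
sphericity correction is applied by default (dfs are reported uncorrected);
the implementation matches an independent repeated-measures ANOVA oracle to
10 significant figures in the tests. Post-hoc paired t-tests cover all
within-hemisphere subdivision pairs and between-hemisphere same-subdivision
pairs with Bonferroni adjustment p_adj = min(1, m·p).

**Stability analysis.** For each contrast and each candidate N, 100
subject subsets are drawn without replacement and the fraction with paired
p < α (default 0.01) is recorded; the minimum N with fraction ≥ 95% is the
contrast's stable sample size. The resample count and criterion are
conventions (configurable); the planted-table generator produces a unit
standardized paired difference with gap = √2·noise_sd, and such an effect
is declared stable by N ≤ 25.

## Gradient fields and directional statistics

Per-triangle gradients of the piecewise-linear interpolant are exact for
linear fields; vertex gradients are area-weighted averages of incident
triangle gradients re-projected to the vertex tangent plane, with boundary
vertices flagged invalid. A region's main direction is the normalized
resultant of vertex gradient unit vectors (magnitude weighting optional,
off by default; resultants below 1e−8 are a degeneracy error).

Subject main directions are treated as points on S²: mean direction = the
normalized resultant; dispersion = circular standard deviation
√(−2 ln R̄); SEM = dispersion/√N. The 95% CI on the mean direction is a
recentered tangent-plane bootstrap cone (2000 seeded resamples by default):
the 95th percentile of bootstrap-mean displacements about their own mean
plus the bootstrap bias — the recentering keeps empirical coverage at the
nominal level (~95% in von Mises–Fisher simulations; the plain percentile
cone sits nearer 94%). The Rayleigh statistic is S = 3N‖R̄‖² against
χ²(df = 3); its type-I rate at N = 413 calibrates to 0.03–0.07 at α = 0.05.
Angles are reported in radians; in-plane angles use atan2 in the sheet
plane. One caveat worth recording: per-vertex white noise does **not**
average out of a region's mean gradient (gradient sums telescope to
boundary terms), so single-subject direction recovery degrades with raw
vertex noise much faster than √n intuition suggests; group-level statistics
over subjects restore the expected behavior.

Isocontours use marching triangles on the piecewise-linear field: one
straight segment per crossed triangle, empty (with a warning) for levels
outside the field range.

## Connectivity

Motion screening: total displacement = max translation magnitude from the
first frame (< 2 mm), and mean framewise displacement = sum of absolute
backward parameter differences with rotations converted to arc length on a
50 mm sphere (< 0.2 mm). Preprocessing: Gaussian smoothing at 6 mm FWHM
(σ = FWHM/2√(2 ln 2)), then a zero-phase 4th-order Butterworth band-pass
0.008–0.1 Hz. Seed connectivity is the OLS beta of the seed's mean series
in a design with the global mean, six motion parameters, and an intercept;
betas are invariant to nuisance rescaling, and rank-deficient designs fail
with the collinear columns named. Group inference is a one-sample t-test
with Benjamini–Hochberg FDR. Differential subdivisions: a voxel belongs to
seed s's mask iff both one-sided paired comparisons s > s′ survive FDR at
α = 0.01; the AND of opposite strict inequalities makes the three masks
disjoint by construction, and they are intersected with a user-supplied
target mask. The rest phantom places its six target zones with one-voxel
gaps along the anterior axis so that 6 mm smoothing cannot bleed one zone's
signal into the next; with adjacent zones the differential masks blur at
the shared border, which is a property of smoothing, not of the test.

## Brain–behavior CCA

Subjects with any missing behavioral cell are removed listwise (with a log;
fewer than 30 survivors is an error). Both blocks are z-scored (training
statistics only, inside cross-validation) and the CCA is solved by SVD
whitening; numerically-zero directions are truncated, and a block whose
rank cannot support k = min(p, q) pairs is an error. Sign indeterminacy is
resolved by forcing the largest-magnitude brain weight positive per
component. Pillai's trace V = Σρ² is tested with the standard approximate-F
transform; under independent blocks its p-values are uniform. The
correlation "between the first latent variables" is computed between the
first canonical variate scores (weight vectors are fixed and cannot
correlate across subjects); in-sample it equals ρ₁ by construction and is
asserted as such. Effect sizes convert as d = 2r/√(1−r²), which maps
r = 0.19/0.31/0.17 to d = 0.39/0.65/0.35 at two decimals (r = 0.32 gives
0.676 → 0.68). Leave-one-out prediction refits the CCA per fold and scores
the held-out subject on the first training weight pair; prediction r is
attenuated relative to the in-sample fit, positive under planted structure,
and null-consistent (|r| < 0.1 at n = 400) without it. Behavioral columns
are used untransformed (a transform hook exists); reaction-time inversion
or logging is left to the caller.

The brain–behavior phantom embeds one latent pair with exact population
canonical correlation ρ via invertible mixing of [u, noise] and
[v = ρu + √(1−ρ²)w, noise] blocks, so all remaining canonical correlations
are 0; column scalings are cosmetic and cannot affect CCA.

## Orchestration and problem sizes

`run_all` executes simulate → rtop → parcel-stats → gradients →
connectivity → cca with per-stage seeds derived from one master seed, and
writes a manifest of output checksums (identical configs and inputs give
identical checksums for deterministic stages). Default problem sizes — 20
mixture voxels, 60 statistical subjects (413 for the brain–behavior table),
50 gradient subjects, 12 resting-state runs on a 20×12×8 grid with 240
frames — were chosen so the full pipeline and its calibration loops
complete in seconds on one CPU while keeping every statistical check well
powered; all are configurable upward.

## What the phantoms do not emulate

Real cortical geometry and curvature (sheets are planar rectangles), partial
volume between gray matter and CSF at the pial surface, susceptibility and
eddy-current artifacts, physiological noise and autocorrelated fMRI noise
(phantom frames are temporally white before filtering), inter-subject
registration error, and restricted (non-Gaussian) diffusion compartments.
Passing tests demonstrate correctness of the estimators under their stated
models and calibration of the statistics — not robustness to these
real-data effects.
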