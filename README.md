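# rtopmap

Quantitative mapping of cortical gray-matter microstructure from multi-shell
diffusion MRI, and its relation to functional circuitry and behavior.

The package implements, end to end and on synthetic data with analytic
ground truth, a pipeline for studying how the microstructure of the human
insular cortex varies across its functional subdivisions (ventral anterior
vAI, dorsal anterior dAI, posterior PI), how that organization is mirrored
in anterior-cingulate (ACC) territories that are functionally coupled to
each subdivision, and how it relates to cognitive-control behavior. It is
aimed at researchers who want a tested, inspectable reference implementation
of each stage — q-space reconstruction, surface statistics, directional
statistics, seed-based connectivity parcellation, and brain–behavior
canonical correlation — without needing access to a large consortium
dataset.

## The quantity at the core: normalized RTOP

The return-to-origin probability is the value of the ensemble-average
diffusion propagator at zero displacement, obtained by integrating the
q-space signal attenuation:

```
RTOP = ∫ E(q) d³q            [mm⁻³],   b = 4π²q²τ,   τ = Δ − δ/3
```

Higher RTOP means more restricted diffusion (smaller pores). We report the
dimensionless **normalized RTOP**, the ratio of tissue RTOP to that of free
water at the same diffusion time:

```
nRTOP = RTOP · (4πτ D_free)^{3/2},      D_free = 3.0×10⁻³ mm²/s
```

which equals 1 for free diffusion. `E(q)` is reconstructed with an
anisotropic Hermite-function (MAP) basis: a diffusion-tensor pre-fit on the
lowest shell supplies per-axis scales `u_i = √(2λ_iτ)` and the eigenframe
rotation, and a Laplacian smoothness penalty (weight chosen per voxel by
generalized cross-validation) regularizes the least-squares fit. RTOP then
has a closed form in the basis coefficients. For Gaussian-mixture signals
`RTOP = Σ_i f_i (4πτ)^{-3/2} det(D_i)^{-1/2}` exactly, which the synthetic
phantoms use as an oracle.

Downstream stages follow the field's standard methods: unweighted vertex
averaging within subdivisions; two-way repeated-measures ANOVA
(subdivision × hemisphere) with Bonferroni-corrected paired post-hocs and a
subsampling stability analysis; finite-element surface gradients with
spherical directional statistics and the Rayleigh test `S = 3N‖R̄‖²`
(χ², df = 3); seed-based regression connectivity with global-signal and
motion covariates, Benjamini–Hochberg FDR, and logical-AND differential
masks; and full canonical correlation analysis with Pillai's trace,
`d = 2r/√(1−r²)` effect sizes, and leave-one-out prediction.

## Worked example

Each analysis stage is a numbered driver under `analysis/`; all of them are
thin wrappers over `rtopmap.workflow.run_stage`, so the same computations
are importable from the library. Running the sequence

```
for f in analysis/0*.py; do python $f --out results/pipeline --seed 3; done
```

prints, stage by stage (same numbers via `rtopmap all --seed 3`):

```
wrote 13 phantom files under results/pipeline: 276 dMRI measurements, tau = 39.7 ms, 20 mixture voxels with closed-form RTOP.
normalized RTOP vs oracle: median relative error 0.12%, worst voxel 1.50%; 0 voxels flagged non-positive.
subdivision effect F(2,118) = 546.2, p = 2.23e-60; planted vAI < dAI < PI ordering detected: True.
group mean gradient direction recovered within 2.8 degrees of the planted axis across all subdivisions (N = 50); largest Rayleigh p = 6.4e-32.
differential masks disjoint: True; worst Dice vs planted zones 0.98; 0 of 12 runs excluded by motion screening.
6 subjects excluded for missing behavior, 407 retained; first canonical r = 0.38 (planted 0.32), Pillai's trace = 0.31 (p = 0.000); leave-one-out prediction r = 0.26 (Cohen's d = 0.54).
```

Reading these numbers: the q-space estimator recovers the known
Gaussian-mixture RTOP to well under 5% per voxel; the subdivision ANOVA on
the planted table shows the expected microstructural ordering
vAI < dAI < PI; the surface-gradient stage recovers the planted
anterior–posterior/ventral–dorsal axis within a few degrees and rejects
directional uniformity decisively; the connectivity stage reassembles the
three target zones per hemisphere almost exactly and never assigns a voxel
to two zones; and the brain–behavior stage recovers a planted canonical
correlation of 0.32 within sampling error, with the expected attenuation
from in-sample fit (0.38) to out-of-sample prediction (0.26).

Intermediate artifacts are written in standard formats (NIfTI, GIFTI, CSV,
JSON) under the output directory, one subdirectory per stage, along with a
`manifest.json` of output checksums; deterministic stages reproduce
identical checksums on re-run.

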