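"""Seed-based resting-state connectivity and differential target parcellation.

Runs pass a motion screen (total displacement and mean framewise
displacement), are spatially smoothed and band-pass filtered, and each seed's
mean time series is regressed voxelwise against every voxel with the global
signal and six motion parameters as nuisance covariates.  Target-region
subdivisions are voxels whose connectivity to one seed exceeds both other
seeds (paired t-tests, Benjamini-Hochberg FDR, logical AND), intersected
with a target mask; the three resulting masks are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MotionScreen",
    "motion_screen",
    "preprocess_rest",
    "seed_connectivity",
    "group_onesample",
    "differential_subdivisions",
    "dice",
]

ROTATION_SPHERE_RADIUS_MM = 50.0  # Power framewise-displacement convention


@dataclass(frozen=True)
class MotionScreen:
    include: bool
    total_displacement: float  # mm, max translation from the reference frame
    mean_fd: float  # mm
    max_fd: float  # mm


def motion_screen(
    motion_params: np.ndarray,
    total_displacement_max: float = 2.0,
    fd_max: float = 0.2,
) -> MotionScreen:
    """Head-motion screening on a frames x 6 parameter table.

    Columns are 3 translations (mm) then 3 rotations (rad).  Total
    displacement is the maximum translation magnitude relative to the first
    frame; framewise displacement (FD) sums absolute backward differences of
    all six parameters with rotations converted to arc length on a 50 mm
    sphere.  A run is included iff total displacement and mean FD are below
    their thresholds.
    """
    m = np.asarray(motion_params, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6 or not np.all(np.isfinite(m)):
        raise ValueError("motion_params must be a finite frames x 6 table")
    trans = m[:, :3] - m[0, :3]
    td = float(np.linalg.norm(trans, axis=1).max())
    diffs = np.abs(np.diff(m, axis=0))
    diffs[:, 3:] *= ROTATION_SPHERE_RADIUS_MM
    fd = diffs.sum(axis=1)
    mean_fd = float(fd.mean()) if fd.size else 0.0
    max_fd = float(fd.max()) if fd.size else 0.0
    include = td < total_displacement_max and mean_fd < fd_max
    return MotionScreen(include, td, mean_fd, max_fd)


def preprocess_rest(
    data: np.ndarray,
    tr: float,
    fwhm_mm: float = 6.0,
    band_hz: tuple[float, float] = (0.008, 0.1),
    voxel_size_mm: float = 2.0,
) -> np.ndarray:
    """Spatial Gaussian smoothing then zero-phase temporal band-pass.

    FWHM converts to the Gaussian sigma via fwhm / (2 sqrt(2 ln 2)); the
    band-pass is a 4th-order Butterworth applied forward-backward
    (zero phase).  The temporal mean is removed, so output voxel means
    are ~0.
    """
    if data.ndim != 4:
        raise ValueError("data must be 4-D (x, y, z, t)")
    nyquist = 0.5 / tr
    lo, hi = band_hz
    if not 0 < lo < hi < nyquist:
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyquist:.3f})")
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    smoothed = ndimage.gaussian_filter(data, sigma=(sigma_vox,) * 3 + (0,))
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=1.0 / tr, output="sos")
    filtered = signal.sosfiltfilt(sos, smoothed, axis=-1)
    return filtered - filtered.mean(axis=-1, keepdims=True)


def seed_connectivity(
    data: np.ndarray,
    seed_mask: np.ndarray,
    motion_params: np.ndarray,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelwise OLS beta of the mean seed time series.

    Design: [seed mean, global mean, 6 motion parameters, intercept], all
    regressors demeaned except the intercept.  Returns the seed beta as a
    volume (NaN outside the brain mask).
    """
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    if brain_mask is None:
        brain_mask = np.ones(data.shape[:3], dtype=bool)
    t = data.shape[-1]
    seed_ts = data[seed_mask].mean(axis=0)
    global_ts = data[brain_mask].mean(axis=0)
    X = np.column_stack([seed_ts, global_ts, motion_params, np.ones(t)])
    X[:, :-1] -= X[:, :-1].mean(axis=0)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (near-)collinear columns for the error message
        names = ["seed", "global"] + [f"motion{i}" for i in range(6)] + ["intercept"]
        corr = np.corrcoef(X[:, :-1].T)
        bad = [
            f"{names[i]}~{names[j]}"
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient design (rank {rank}): {bad or names}")
    Y = data[brain_mask].T  # t x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out = np.full(data.shape[:3], np.nan)
    out[brain_mask] = beta[0]
    return out


def group_onesample(
    beta_maps: np.ndarray,
    alpha: float = 0.01,
    correction: str = "fdr",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t-test against zero per voxel with BH-FDR correction.

    beta_maps: (n_subjects, n_voxels).  Zero-variance voxels get p = 1.
    Returns (t values, significance mask at the corrected threshold).
    """
    if beta_maps.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    tvals, pvals = stats.ttest_1samp(beta_maps, 0.0, axis=0)
    zero_var = beta_maps.std(axis=0) == 0
    pvals = np.where(zero_var | ~np.isfinite(pvals), 1.0, pvals)
    tvals = np.where(np.isfinite(tvals), tvals, 0.0)
    if correction == "fdr":
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    elif correction == "none":
        reject = pvals < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return tvals, reject


def _paired_greater_fdr(a: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    """Voxels where a > b by one-sided paired t-test, BH-FDR at alpha."""
    d = a - b
    tvals, p_two = stats.ttest_rel(a, b, axis=0)
    with np.errstate(invalid="ignore"):
        p_one = np.where(tvals > 0, p_two / 2.0, 1.0 - p_two / 2.0)
    p_one = np.where(np.isfinite(p_one) & (d.std(axis=0) > 0), p_one, 1.0)
    reject, _, _, _ = multipletests(p_one, alpha=alpha, method="fdr_bh")
    return reject


def differential_subdivisions(
    beta_maps: dict[str, np.ndarray],
    target_mask: np.ndarray,
    alpha: float = 0.01,
) -> dict[str, np.ndarray]:
    """Per-seed masks of voxels differentially connected to that seed.

    For each seed s the voxel must survive s > s' (one-sided paired t-test,
    FDR-corrected at alpha) against both other seeds; the two binarized maps
    are intersected (logical AND) and then intersected with the target mask.
    The AND of opposite strict inequalities cannot hold simultaneously, so
    the three output masks are pairwise disjoint.
    """
    names = list(beta_maps)
    if len(names) != 3:
        raise ValueError("expected exactly 3 seeds")
    shapes = {beta_maps[n].shape for n in names}
    if len(shapes) != 1:
        raise ValueError(f"misaligned beta map grids: {shapes}")
    flat = {n: beta_maps[n].reshape(beta_maps[n].shape[0], -1) for n in names}
    tflat = np.asarray(target_mask, dtype=bool).ravel()
    if tflat.size != next(iter(flat.values())).shape[1]:
        raise ValueError("target mask grid does not match beta maps")
    out: dict[str, np.ndarray] = {}
    for s in names:
        mask = np.ones(tflat.size, dtype=bool)
        for other in names:
            if other == s:
                continue
            mask &= _paired_greater_fdr(flat[s], flat[other], alpha)
        out[s] = (mask & tflat).reshape(target_mask.shape)
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * float(np.logical_and(a, b).sum()) / denom if denom else 0.0
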