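"""Canonical correlation between subdivision microstructure and behavior.

Brain measures are the six per-hemisphere subdivision means of normalized
RTOP; behavioral measures are eleven cognitive-control scores.  Subjects
with any missing behavioral cell are excluded listwise.  The CCA is the
full singular-value decomposition solution on z-scored blocks; overall
significance uses Pillai's trace V = sum rho_i^2 with the standard
approximate-F transform.  Out-of-sample prediction is leave-one-out: each
fold refits the CCA on the training subjects (standardization statistics
from training only) and scores the held-out subject on the first canonical
pair; Pearson correlation between predicted and actual scores across folds,
with Cohen's d = 2r / sqrt(1 - r^2), quantifies prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CCAResult",
    "PredictionResult",
    "exclude_missing",
    "fit_cca",
    "variate_correlation",
    "cohens_d_from_r",
    "loo_predict",
    "pillai_trace_test",
]


@dataclass
class CCAResult:
    brain_weights: np.ndarray  # (p, k)
    behavior_weights: np.ndarray  # (q, k)
    canonical_correlations: np.ndarray  # (k,) non-increasing, in [0, 1]
    brain_variates: np.ndarray  # (n, k), unit variance
    behavior_variates: np.ndarray  # (n, k), unit variance
    pillai_trace: float
    pillai_p: float


@dataclass
class PredictionResult:
    predicted: np.ndarray  # held-out brain-side first-variate scores
    actual: np.ndarray  # held-out behavior-side first-variate scores
    pearson_r: float
    p: float
    cohens_d: float
    n_skipped: int


def exclude_missing(
    behavior: pd.DataFrame,
    brain: pd.DataFrame,
    subject_col: str = "subject",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Listwise deletion of subjects with missing behavioral cells.

    Returns aligned complete-case (behavior, brain) tables plus an exclusion
    log with one row per dropped subject and the reason.
    """
    log_rows = []
    beh = behavior.set_index(subject_col)
    br = brain.set_index(subject_col)
    shared = beh.index.intersection(br.index)
    for sid in beh.index.difference(br.index):
        log_rows.append({"subject": sid, "reason": "unmatched id (behavior only)"})
    for sid in br.index.difference(beh.index):
        log_rows.append({"subject": sid, "reason": "unmatched id (brain only)"})
    beh = beh.loc[shared]
    br = br.loc[shared]
    missing = beh.isna().any(axis=1) | br.isna().any(axis=1)
    for sid in beh.index[missing]:
        log_rows.append({"subject": sid, "reason": "missing behavioral value"})
    keep = ~missing
    if int(keep.sum()) < 30:
        raise ValueError(f"only {int(keep.sum())} complete subjects; need >= 30")
    return (
        beh.loc[keep].reset_index(),
        br.loc[keep].reset_index(),
        pd.DataFrame(log_rows, columns=["subject", "reason"]),
    )


def _zscore(X: np.ndarray, mean=None, std=None):
    mean = X.mean(axis=0) if mean is None else mean
    std = X.std(axis=0, ddof=1) if std is None else std
    if np.any(std <= 0):
        bad = np.where(std <= 0)[0].tolist()
        raise ValueError(f"degenerate (constant) columns at indices {bad}")
    return (X - mean) / std, mean, std


def pillai_trace_test(rhos: np.ndarray, n: int, p: int, q: int) -> tuple[float, float]:
    """Pillai's trace V = sum rho_i^2 with the approximate-F test."""
    V = float(np.sum(rhos**2))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (n - p - q - 2) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (2 * nn + s + 1) / (2 * m + s + 1) * V / (s - V) if s > V else np.inf
    return V, float(stats.f.sf(F, df1, df2))


def _cca_core(Zx: np.ndarray, Zy: np.ndarray):
    """SVD-based CCA on standardized blocks; returns (wx, wy, rhos).

    Numerically-zero directions within a block are truncated; a block whose
    rank cannot support the k = min(p, q) canonical pairs is an error
    (degenerate columns).
    """
    n = Zx.shape[0]
    k = min(Zx.shape[1], Zy.shape[1])
    Ux, Sx, Vxt = np.linalg.svd(Zx, full_matrices=False)
    Uy, Sy, Vyt = np.linalg.svd(Zy, full_matrices=False)
    tol = n * np.finfo(float).eps
    rx = int(np.sum(Sx > tol * Sx[0]))
    ry = int(np.sum(Sy > tol * Sy[0]))
    bad = []
    if rx < k:
        bad.append(f"brain block (rank {rx} < {k})")
    if ry < k:
        bad.append(f"behavior block (rank {ry} < {k})")
    if bad:
        raise ValueError(f"rank-deficient {' and '.join(bad)}")
    Ux, Sx, Vxt = Ux[:, :rx], Sx[:rx], Vxt[:rx]
    Uy, Sy, Vyt = Uy[:, :ry], Sy[:ry], Vyt[:ry]
    W, rhos, Zt = np.linalg.svd(Ux.T @ Uy)
    W, rhos, Z = W[:, :k], np.clip(rhos[:k], 0.0, 1.0), Zt.T[:, :k]
    # weights mapping standardized data to unit-variance variates
    wx = Vxt.T @ np.diag(1.0 / Sx) @ W * np.sqrt(n - 1)
    wy = Vyt.T @ np.diag(1.0 / Sy) @ Z * np.sqrt(n - 1)
    # sign convention: largest-|.| brain weight positive per component
    for j in range(k):
        i = np.argmax(np.abs(wx[:, j]))
        if wx[i, j] < 0:
            wx[:, j] = -wx[:, j]
            wy[:, j] = -wy[:, j]
    return wx, wy, rhos


def fit_cca(brain: np.ndarray, behavior: np.ndarray) -> CCAResult:
    """Full CCA between an n x p brain block and an n x q behavior block.

    Columns are z-scored internally; k = min(p, q) canonical pairs are
    returned with non-increasing correlations.  Canonical correlations are
    invariant to invertible linear transforms of either block.
    """
    X = np.asarray(brain, dtype=float)
    Y = np.asarray(behavior, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    if n <= p + q:
        raise ValueError(f"need n > p + q = {p + q}, got n = {n}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("inputs must be complete (run exclude_missing first)")
    Zx, *_ = _zscore(X)
    Zy, *_ = _zscore(Y)
    wx, wy, rhos = _cca_core(Zx, Zy)
    V, pillai_p = pillai_trace_test(rhos, n, p, q)
    return CCAResult(
        brain_weights=wx,
        behavior_weights=wy,
        canonical_correlations=rhos,
        brain_variates=Zx @ wx,
        behavior_variates=Zy @ wy,
        pillai_trace=V,
        pillai_p=pillai_p,
    )


def variate_correlation(result: CCAResult, axis: int = 1) -> tuple[float, float]:
    """Pearson correlation between paired canonical variate scores.

    For the fitted sample this equals the corresponding canonical
    correlation by construction (asserted to 1e-10).
    """
    j = axis - 1
    r, p = stats.pearsonr(result.brain_variates[:, j], result.behavior_variates[:, j])
    assert abs(r - result.canonical_correlations[j]) < 1e-10
    return float(r), float(p)


def cohens_d_from_r(r: float) -> float:
    """Effect-size conversion d = 2r / sqrt(1 - r^2)."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return 2.0 * r / np.sqrt(1.0 - r * r)


def loo_predict(brain: np.ndarray, behavior: np.ndarray) -> PredictionResult:
    """Leave-one-out prediction on the first canonical pair.

    Each fold standardizes with training statistics only, fits the CCA on
    the n-1 training subjects, and projects the held-out subject onto the
    first brain and behavior weight vectors.  Folds whose CCA fails are
    skipped (error if more than 5% skip).
    """
    X = np.asarray(brain, dtype=float)
    Y = np.asarray(behavior, dtype=float)
    n = X.shape[0]
    predicted, actual = [], []
    skipped = 0
    for i in range(n):
        tr = np.arange(n) != i
        try:
            Zx, mx, sx = _zscore(X[tr])
            Zy, my, sy = _zscore(Y[tr])
            wx, wy, _ = _cca_core(Zx, Zy)
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
            continue
        predicted.append(float((X[i] - mx) / sx @ wx[:, 0]))
        actual.append(float((Y[i] - my) / sy @ wy[:, 0]))
    if skipped > 0.05 * n:
        raise ValueError(f"{skipped}/{n} leave-one-out folds failed")
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    r, p = stats.pearsonr(predicted, actual)
    return PredictionResult(predicted, actual, float(r), float(p),
                            cohens_d_from_r(float(r)), skipped)
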