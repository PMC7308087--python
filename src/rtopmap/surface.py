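"""Surface sampling, subdivision summaries, and subdivision statistics.

Per-voxel normalized RTOP volumes are sampled at mesh vertex coordinates,
averaged within functional subdivisions (vAI, dAI, PI per hemisphere), and
the resulting subject x subdivision x hemisphere table is analyzed with a
two-way repeated-measures ANOVA, Bonferroni-corrected paired post-hoc
t-tests, and a subsampling stability analysis that finds the minimum sample
size at which each contrast is reliably significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthetic import SUBDIVISIONS, SurfaceMesh

__all__ = [
    "sample_volume_to_surface",
    "subdivision_means",
    "merge_multimodal_labels",
    "two_way_rm_anova",
    "posthoc_paired_ttests",
    "stability_analysis",
    "AnovaTable",
]

# Glasser multimodal-atlas insular regions -> tripartite subdivisions
MULTIMODAL_MERGE = {
    "dAI": ("AVI", "MI", "FOP3"),
    "vAI": ("AAIC",),
    "PI": ("PoI1", "PoI2", "Ig", "FOP2"),
}


def sample_volume_to_surface(
    volume: np.ndarray,
    affine: np.ndarray,
    mesh: SurfaceMesh,
    method: str = "trilinear",
) -> np.ndarray:
    """Interpolate a scalar volume at mesh vertex coordinates (world mm).

    Vertices outside the field of view are returned as NaN and excluded
    from downstream means.
    """
    if method not in ("trilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    inv = np.linalg.inv(affine)
    v = mesh.vertices
    ijk = (v @ inv[:3, :3].T) + inv[:3, 3]
    order = 1 if method == "trilinear" else 0
    vals = ndimage.map_coordinates(
        np.asarray(volume, dtype=float), ijk.T, order=order,
        mode="constant", cval=np.nan,
    )
    inside = np.all((ijk >= -0.5) & (ijk <= np.array(volume.shape) - 0.5), axis=1)
    vals[~inside] = np.nan
    return vals


def subdivision_means(
    vertex_values: np.ndarray,
    labels: np.ndarray,
    subdivisions: tuple[str, ...] = SUBDIVISIONS,
) -> pd.DataFrame:
    """Unweighted mean over labeled, finite vertices per subdivision."""
    rows = []
    for name in subdivisions:
        sel = labels == name
        if not sel.any():
            raise ValueError(f"subdivision {name!r} has no vertices")
        vals = vertex_values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"subdivision {name!r} has no finite values")
        rows.append({"subdivision": name, "mean_rtop": float(vals.mean()),
                     "n_vertices": int(vals.size)})
    return pd.DataFrame(rows)


def merge_multimodal_labels(
    fine_labels: np.ndarray,
    merge: dict[str, tuple[str, ...]] | None = None,
) -> np.ndarray:
    """Collapse fine multimodal-atlas insular labels to vAI / dAI / PI.

    dAI = AVI + MI + FOP3; vAI = AAIC; PI = PoI1 + PoI2 + Ig + FOP2.
    Any other label maps to "background".  Raises if a required fine label
    is entirely absent.
    """
    merge = merge or MULTIMODAL_MERGE
    fine = np.asarray(fine_labels)
    present = set(np.unique(fine).tolist())
    required = [name for parts in merge.values() for name in parts]
    missing = [name for name in required if name not in present]
    if missing:
        raise ValueError(f"missing required fine labels: {missing}")
    out = np.full(fine.shape, "background", dtype=object)
    for coarse, parts in merge.items():
        out[np.isin(fine, parts)] = coarse
    return out.astype(str)


# ---------------------------------------------------------------------------
# statistics on the subject x subdivision x hemisphere table


@dataclass(frozen=True)
class AnovaTable:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


def _pivot(summary: pd.DataFrame) -> np.ndarray:
    """(n_subjects, n_subdivisions, n_hemis) array from the long table."""
    required = {"subject", "hemisphere", "subdivision", "mean_rtop"}
    if not required.issubset(summary.columns):
        raise ValueError(f"summary must have columns {sorted(required)}")
    wide = summary.pivot_table(
        index="subject", columns=["subdivision", "hemisphere"],
        values="mean_rtop", aggfunc="first",
    )
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete cells for subjects {bad[:5]}")
    subs = sorted({c[0] for c in wide.columns})
    hemis = sorted({c[1] for c in wide.columns})
    Y = np.empty((wide.shape[0], len(subs), len(hemis)))
    for i, s in enumerate(subs):
        for j, h in enumerate(hemis):
            Y[:, i, j] = wide[(s, h)].to_numpy()
    return Y


def two_way_rm_anova(summary: pd.DataFrame) -> list[AnovaTable]:
    """Two-way within-subject ANOVA (subdivision x hemisphere).

    Balanced design with subject as a random factor: each effect is tested
    against its own effect-by-subject interaction, so a main effect with
    k levels has df = (k - 1, (k - 1)(n - 1)).  No sphericity correction is
    applied.
    """
    Y = _pivot(summary)
    n, a, b = Y.shape
    gm = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mAB = Y.mean(axis=0)
    mAS = Y.mean(axis=2)
    mBS = Y.mean(axis=1)

    ss_a = n * b * np.sum((mA - gm) ** 2)
    ss_b = n * a * np.sum((mB - gm) ** 2)
    ss_ab = n * np.sum((mAB - mA[:, None] - mB[None, :] + gm) ** 2)
    ss_as = b * np.sum((mAS - mA[None, :] - mS[:, None] + gm) ** 2)
    ss_bs = a * np.sum((mBS - mB[None, :] - mS[:, None] + gm) ** 2)
    resid = (
        Y - mAB[None] - mAS[:, :, None] - mBS[:, None, :]
        + mA[None, :, None] + mB[None, None, :] + mS[:, None, None] - gm
    )
    ss_abs = np.sum(resid**2)

    def table(name: str, ss: float, dfn: int, ss_err: float, dfe: int) -> AnovaTable:
        F = (ss / dfn) / (ss_err / dfe)
        return AnovaTable(name, float(F), dfn, dfe,
                          float(stats.f.sf(F, dfn, dfe)))

    return [
        table("subdivision", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        table("hemisphere", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        table("subdivision:hemisphere", ss_ab, (a - 1) * (b - 1),
              ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]


def _contrasts(summary: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Paired samples for every within-hemisphere subdivision pair and every
    between-hemisphere same-subdivision pair."""
    Y = _pivot(summary)
    subs = sorted(summary["subdivision"].unique())
    hemis = sorted(summary["hemisphere"].unique())
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, h in enumerate(hemis):
        for i1 in range(len(subs)):
            for i2 in range(i1 + 1, len(subs)):
                out[f"{h}: {subs[i1]} vs {subs[i2]}"] = (Y[:, i1, j], Y[:, i2, j])
    if len(hemis) == 2:
        for i, s in enumerate(subs):
            out[f"{s}: {hemis[0]} vs {hemis[1]}"] = (Y[:, i, 0], Y[:, i, 1])
    return out


def posthoc_paired_ttests(summary: pd.DataFrame,
                          correction: str = "bonferroni") -> pd.DataFrame:
    """All pairwise paired t-tests with Bonferroni adjustment.

    Contrast sign is the sign of mean(first - second); identical columns
    give t = 0 and adjusted p = 1.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    pairs = _contrasts(summary)
    if next(iter(pairs.values()))[0].size < 3:
        raise ValueError("need at least 3 subjects for paired t-tests")
    m = len(pairs)
    rows = []
    for name, (x, y) in pairs.items():
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x, y)
        rows.append({
            "contrast": name, "t": float(t), "p_raw": float(p),
            "p_adjusted": float(min(1.0, m * p)),
            "sign": int(np.sign(np.mean(x - y))),
            "mean_difference": float(np.mean(x - y)),
        })
    return pd.DataFrame(rows)


def stability_analysis(
    summary: pd.DataFrame,
    sample_sizes: list[int],
    n_resamples: int = 100,
    alpha: float = 0.01,
    criterion: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Minimum sample size reliably reproducing each paired contrast.

    For each contrast and each N, draws ``n_resamples`` subject subsets
    without replacement and records the fraction whose paired t-test reaches
    p < alpha; the minimum N with fraction >= criterion is reported (NaN when
    no N qualifies).
    """
    if n_resamples < 10:
        raise ValueError("n_resamples must be >= 10")
    pairs = _contrasts(summary)
    n_subjects = next(iter(pairs.values()))[0].size
    if max(sample_sizes) > n_subjects:
        raise ValueError("sample size exceeds number of subjects")
    rng = np.random.default_rng(seed)
    rows = []
    for name, (x, y) in pairs.items():
        d = x - y
        fractions = {}
        for N in sorted(sample_sizes):
            hits = 0
            for _ in range(n_resamples):
                idx = rng.choice(n_subjects, size=N, replace=False)
                sub = d[idx]
                if np.allclose(sub.std(), 0):
                    continue
                _, p = stats.ttest_1samp(sub, 0.0)
                hits += p < alpha
            fractions[N] = hits / n_resamples
        stable = [N for N, f in fractions.items() if f >= criterion]
        rows.append({
            "contrast": name,
            "min_stable_n": float(min(stable)) if stable else float("nan"),
            **{f"frac_n{N}": f for N, f in fractions.items()},
        })
    return pd.DataFrame(rows)
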