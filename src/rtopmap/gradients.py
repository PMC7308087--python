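"""Surface gradient fields, directional statistics, and isocontours.

The per-vertex scalar field (normalized RTOP sampled on the cortical sheet)
is differentiated with a piecewise-linear finite-element gradient; each
subject contributes one main gradient direction per subdivision (the
normalized resultant of vertex gradient directions), and the population of
subject directions is summarized with spherical directional statistics and
a Rayleigh test of uniformity (statistic 3 N |mean resultant|^2, chi-squared
with 3 degrees of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import SurfaceMesh

__all__ = [
    "GradientField",
    "DirectionalStats",
    "mesh_gradient",
    "main_direction",
    "directional_stats",
    "rayleigh_test",
    "isocontours",
]


@dataclass
class GradientField:
    """Per-vertex tangential gradient vectors (field units per mm)."""

    vectors: np.ndarray  # (V, 3)
    valid: np.ndarray  # (V,) boolean, interior vertices with defined gradient


@dataclass(frozen=True)
class DirectionalStats:
    mean_direction: np.ndarray  # unit 3-vector
    mean_angle: float  # radians, in-plane angle atan2(y, x)
    dispersion: float  # radians, circular SD sqrt(-2 ln Rbar)
    sem: float  # radians, dispersion / sqrt(N)
    ci_halfwidth: float  # radians, 95% bootstrap CI on the mean direction
    rayleigh_statistic: float
    rayleigh_df: int
    rayleigh_p: float
    n: int


def _face_geometry(mesh: SurfaceMesh):
    v = mesh.vertices
    t = mesh.triangles
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    cross = np.cross(p1 - p0, p2 - p0)
    double_area = np.linalg.norm(cross, axis=1)
    ok = double_area > 1e-12
    normals = np.zeros_like(cross)
    normals[ok] = cross[ok] / double_area[ok, None]
    return double_area, normals, ok


def _boundary_vertices(mesh: SurfaceMesh) -> np.ndarray:
    """Vertices on edges shared by only one triangle."""
    t = mesh.triangles
    edges = np.sort(np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = np.zeros(mesh.vertices.shape[0], dtype=bool)
    boundary[uniq[counts == 1].ravel()] = True
    return boundary


def mesh_gradient(mesh: SurfaceMesh, vertex_values: np.ndarray) -> GradientField:
    """Finite-element surface gradient of a piecewise-linear vertex field.

    Each triangle carries the exact gradient of the linear interpolant;
    vertex gradients are the area-weighted average of incident triangle
    gradients, re-projected onto the vertex tangent plane.  Boundary
    vertices are flagged invalid (one-sided stencils bias the direction).
    """
    f = np.asarray(vertex_values, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("vertex values must be finite")
    t = mesh.triangles
    v = mesh.vertices
    double_area, normals, ok = _face_geometry(mesh)
    if not ok.any():
        raise ValueError("all triangles are degenerate")
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} zero-area triangles")

    # grad on a face: (1 / 2A) n x (f0 (p2-p1) + f1 (p0-p2) + f2 (p1-p0))
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    e = (f[t[:, 0], None] * (p2 - p1)
         + f[t[:, 1], None] * (p0 - p2)
         + f[t[:, 2], None] * (p1 - p0))
    face_grad = np.zeros_like(e)
    face_grad[ok] = np.cross(normals[ok], e[ok]) / double_area[ok, None]

    nv = v.shape[0]
    acc = np.zeros((nv, 3))
    wacc = np.zeros(nv)
    nacc = np.zeros((nv, 3))
    w = 0.5 * double_area * ok
    for k in range(3):
        np.add.at(acc, t[:, k], w[:, None] * face_grad)
        np.add.at(nacc, t[:, k], w[:, None] * normals)
        np.add.at(wacc, t[:, k], w)

    valid = wacc > 0
    grad = np.zeros((nv, 3))
    grad[valid] = acc[valid] / wacc[valid, None]
    nrm = np.zeros((nv, 3))
    nn = np.linalg.norm(nacc, axis=1)
    pos = nn > 1e-12
    nrm[pos] = nacc[pos] / nn[pos, None]
    grad -= np.einsum("vi,vi->v", grad, nrm)[:, None] * nrm

    valid &= ~_boundary_vertices(mesh)
    return GradientField(grad, valid)


def main_direction(field: GradientField, region: np.ndarray,
                   magnitude_weighted: bool = False) -> np.ndarray:
    """Main gradient direction in a region: normalized resultant of the
    per-vertex gradient unit vectors (optionally magnitude-weighted)."""
    sel = np.asarray(region, dtype=bool) & field.valid
    g = field.vectors[sel]
    mag = np.linalg.norm(g, axis=1)
    g = g[mag > 1e-12]
    mag = mag[mag > 1e-12]
    if g.shape[0] < 10:
        raise ValueError("region has fewer than 10 valid gradient vertices")
    units = g / mag[:, None]
    resultant = (g if magnitude_weighted else units).sum(axis=0)
    norm = np.linalg.norm(resultant)
    if norm < 1e-8:
        raise ValueError("degenerate direction: resultant norm ~ 0")
    return resultant / norm


def _mean_resultant(directions: np.ndarray) -> tuple[np.ndarray, float]:
    mean = directions.mean(axis=0)
    rbar = float(np.linalg.norm(mean))
    return mean / max(rbar, 1e-300), rbar


def rayleigh_test(directions: np.ndarray) -> tuple[float, int, float]:
    """Rayleigh uniformity test for unit vectors on the sphere.

    S = 3 N |mean resultant|^2, compared to chi-squared with df = 3; under
    uniformity S is asymptotically chi2(3), so S is bounded by 3N and large
    values reject uniformity.
    """
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 10:
        raise ValueError("need >= 10 unit 3-vectors")
    _, rbar = _mean_resultant(d)
    S = 3.0 * d.shape[0] * rbar**2
    return float(S), 3, float(stats.chi2.sf(S, 3))


def directional_stats(
    directions: np.ndarray,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> DirectionalStats:
    """Spherical summary of one unit direction per subject.

    Dispersion is the circular standard deviation sqrt(-2 ln Rbar) of the
    directions about their mean; SEM = dispersion / sqrt(N); the 95% CI
    half-width on the mean direction is the 95th percentile of angles
    between bootstrap resample means and the full-sample mean.
    """
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 3:
        raise ValueError("need >= 3 unit 3-vectors")
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length direction")
    d = d / norms[:, None]
    n = d.shape[0]
    mean_dir, rbar = _mean_resultant(d)
    dispersion = float(np.sqrt(max(0.0, -2.0 * np.log(min(rbar, 1.0)))))
    sem = dispersion / np.sqrt(n)

    rng = np.random.default_rng(seed)
    if rbar >= 1.0 - 1e-12:
        ci = 0.0
    else:
        # recentered tangent-plane bootstrap cone: radius is the 95th
        # percentile of bootstrap-mean displacements about their own mean,
        # plus the bootstrap bias, which keeps coverage at the nominal level
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        bms = d[idx].mean(axis=1)
        bms /= np.linalg.norm(bms, axis=1, keepdims=True)
        helper = np.array([1.0, 0.0, 0.0]) if abs(mean_dir[0]) < 0.9 \
            else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(mean_dir, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(mean_dir, e1)
        T = np.column_stack([bms @ e1, bms @ e2])
        tbar = T.mean(axis=0)
        radius = (np.quantile(np.linalg.norm(T - tbar, axis=1), 0.95)
                  + np.linalg.norm(tbar))
        ci = float(np.arcsin(np.clip(radius, 0.0, 1.0)))

    S, df, p = rayleigh_test(d) if n >= 10 else (float("nan"), 3, float("nan"))
    return DirectionalStats(
        mean_direction=mean_dir,
        mean_angle=float(np.arctan2(mean_dir[1], mean_dir[0])),
        dispersion=dispersion,
        sem=float(sem),
        ci_halfwidth=ci,
        rayleigh_statistic=S,
        rayleigh_df=df,
        rayleigh_p=p,
        n=n,
    )


def isocontours(
    mesh: SurfaceMesh,
    vertex_values: np.ndarray,
    levels: list[float],
) -> dict[float, list[np.ndarray]]:
    """Marching-triangles isocontours of a piecewise-linear vertex field.

    Returns, per level, a list of line segments (2 x 3 arrays); a level
    outside the field's range yields an empty list with a warning.  Within
    each crossed triangle the contour is the single straight segment joining
    the two edge crossings.
    """
    f = np.asarray(vertex_values, dtype=float)
    v = mesh.vertices
    t = mesh.triangles
    out: dict[float, list[np.ndarray]] = {}
    fmin, fmax = f.min(), f.max()
    for level in levels:
        segments: list[np.ndarray] = []
        if not fmin <= level <= fmax:
            warnings.warn(f"level {level} outside field range [{fmin}, {fmax}]")
            out[level] = segments
            continue
        for tri in t:
            pts = []
            for a, b in ((0, 1), (1, 2), (2, 0)):
                fa, fb = f[tri[a]], f[tri[b]]
                if (fa - level) * (fb - level) < 0:
                    w = (level - fa) / (fb - fa)
                    pts.append(v[tri[a]] + w * (v[tri[b]] - v[tri[a]]))
                elif fa == level and fb != level:
                    pts.append(v[tri[a]].astype(float))
            if len(pts) == 2:
                segments.append(np.vstack(pts))
        out[level] = segments
    return out


def contour_length(segments: list[np.ndarray]) -> float:
    return float(sum(np.linalg.norm(s[1] - s[0]) for s in segments))
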