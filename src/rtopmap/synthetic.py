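"""Synthetic ground-truth generators for every pipeline stage.

Each generator plants a known effect so downstream estimators can be checked
against analytic truth:

* Gaussian-mixture diffusion voxels — the return-to-origin probability
  (RTOP) of a mixture of Gaussian compartments has a closed form, giving an
  exact oracle for the q-space reconstruction.
* A rectangular cortical sheet with a planted linear scalar field — its
  surface gradient is known exactly, giving an oracle for the mesh gradient
  and directional statistics.
* A resting-state phantom with three seeds, each coupled to one disjoint
  target zone — the differential-connectivity parcellation must recover the
  zones.
* A brain-behavior matrix pair with one planted canonical pair at a chosen
  population canonical correlation.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import AcquisitionScheme

__all__ = [
    "GaussianCompartment",
    "SurfacePhantom",
    "RestPhantom",
    "BrainBehaviorPhantom",
    "simulate_voxel_signal",
    "rtop_oracle",
    "make_surface_phantom",
    "make_parcel_table",
    "make_rest_phantom",
    "make_brain_behavior",
    "random_mixture",
]

SUBDIVISIONS = ("vAI", "dAI", "PI")


# ---------------------------------------------------------------------------
# diffusion voxels


@dataclass(frozen=True)
class GaussianCompartment:
    """One Gaussian diffusion compartment.

    volume_fraction is unitless in (0, 1]; diffusion_tensor is 3x3 symmetric
    positive definite in mm^2/s.
    """

    volume_fraction: float
    diffusion_tensor: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.diffusion_tensor, dtype=float)
        if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("diffusion_tensor must be 3x3 symmetric")
        if np.linalg.eigvalsh(D).min() <= 0:
            raise ValueError("diffusion_tensor must be positive definite")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError("volume_fraction must be in (0, 1]")
        object.__setattr__(self, "diffusion_tensor", D)

    @staticmethod
    def isotropic(fraction: float, diffusivity: float) -> "GaussianCompartment":
        return GaussianCompartment(fraction, diffusivity * np.eye(3))


def _check_fractions(compartments: list[GaussianCompartment]) -> None:
    total = sum(c.volume_fraction for c in compartments)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {total}, expected 1")


def simulate_voxel_signal(
    scheme: AcquisitionScheme,
    compartments: list[GaussianCompartment],
    snr: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Signal attenuation E(q) per measurement for a Gaussian mixture.

    Noiseless: E = sum_i f_i exp(-b g' D_i g), so E(0) = 1.  With ``snr``,
    Rician magnitude noise is added with sigma = 1/snr referenced to the
    b0 signal (E(0) = 1).
    """
    _check_fractions(compartments)
    b = scheme.b_values
    g = scheme.directions
    E = np.zeros(scheme.n_measurements)
    for c in compartments:
        bDg = np.einsum("mi,ij,mj->m", g, c.diffusion_tensor, g)
        E += c.volume_fraction * np.exp(-b * bDg)
    if snr is None:
        return E
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    sigma = 1.0 / snr
    return np.hypot(E + sigma * rng.standard_normal(E.shape),
                    sigma * rng.standard_normal(E.shape))


def rtop_oracle(compartments: list[GaussianCompartment], tau: float) -> float:
    """Closed-form RTOP (mm^-3) of a Gaussian mixture at diffusion time tau.

    RTOP = integral of E(q) over q-space
         = sum_i f_i (4 pi tau)^(-3/2) det(D_i)^(-1/2).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    _check_fractions(compartments)
    return float(sum(
        c.volume_fraction
        * (4.0 * np.pi * tau) ** -1.5
        * np.linalg.det(c.diffusion_tensor) ** -0.5
        for c in compartments
    ))


def random_mixture(rng: np.random.Generator,
                   max_compartments: int = 3) -> list[GaussianCompartment]:
    """Random Gaussian mixture emulating cortical gray-matter voxels.

    Compartment eigenvalues are drawn in [0.5e-3, 2.5e-3] mm^2/s: the range
    spanned by cellular tissue water and partial-volume free water in cortex
    at in-vivo diffusion times.  The floor matters physically: below
    ~0.5e-3 mm^2/s most of the return-to-origin integral lies beyond the
    q-range of a b_max = 3000 s/mm^2 acquisition and is not measurable by
    any estimator (see the methods note on generator realism).
    """
    k = int(rng.integers(1, max_compartments + 1))
    f = rng.dirichlet(np.ones(k))
    comps = []
    for i in range(k):
        lam = rng.uniform(0.5e-3, 2.5e-3, size=3)  # mm^2/s
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        D = q @ np.diag(lam) @ q.T
        D = 0.5 * (D + D.T)
        comps.append(GaussianCompartment(float(f[i]), D))
    return comps


# ---------------------------------------------------------------------------
# surface phantom


@dataclass
class SurfaceMesh:
    """Triangle mesh with vertices in mm."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (T, 3) int


@dataclass
class SurfacePhantom:
    """Two rectangular cortical sheets (hemispheres) with a planted linear
    scalar field and a tripartite subdivision labeling."""

    meshes: dict[str, SurfaceMesh]  # hemisphere -> mesh
    labels: dict[str, np.ndarray]  # hemisphere -> per-vertex label strings
    planted_field: dict[str, np.ndarray]  # hemisphere -> per-vertex scalar
    planted_gradient_direction: np.ndarray  # unit 3-vector (tangential)
    slope: float
    noise_sd: float


def _sheet(nx: int, ny: int, extent: float = 40.0,
           z_offset: float = 0.0) -> SurfaceMesh:
    """Planar rectangular sheet in a z = const plane, regular triangulation."""
    xs = np.linspace(0.0, extent, nx)
    ys = np.linspace(0.0, extent / 2.0, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z_offset)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + ny
            tris.append([a, b, a + 1])
            tris.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.asarray(tris, dtype=np.int64))


def make_surface_phantom(
    n_vertices: int = 900,
    gradient_direction: np.ndarray = (1.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    offset: float = 1.5,
    slope: float = 0.02,
) -> SurfacePhantom:
    """Sheet phantom with planted field offset + slope * (v . direction).

    The sheet lies in the z = 0 plane; the x axis plays the role of the
    posterior->anterior axis and y the ventral->dorsal axis.  Labels split
    each hemisphere's sheet into three contiguous bands along x (anterior
    third vAI, middle dAI, posterior PI).  The analytic surface gradient of
    the planted field is ``slope * P(direction)`` with P the tangential
    (in-plane) projector.
    """
    g = np.asarray(gradient_direction, dtype=float)
    if np.linalg.norm(g) < 1e-12:
        raise ValueError("gradient_direction must be nonzero")
    g = g / np.linalg.norm(g)
    if n_vertices < 100:
        raise ValueError("n_vertices must be >= 100")

    per_hemi = n_vertices // 2
    nx = max(10, int(np.sqrt(2 * per_hemi)))
    ny = max(5, per_hemi // nx)
    rng = np.random.default_rng(seed)

    meshes, labels, fields = {}, {}, {}
    for h, zoff in (("L", 0.0), ("R", 30.0)):
        mesh = _sheet(nx, ny, z_offset=zoff)
        field = offset + slope * (mesh.vertices @ g)
        if noise_sd > 0:
            field = field + noise_sd * rng.standard_normal(field.shape)
        x = mesh.vertices[:, 0]
        lo, hi = np.quantile(x, [1 / 3, 2 / 3])
        lab = np.where(x <= lo, "vAI", np.where(x <= hi, "dAI", "PI"))
        meshes[h] = mesh
        labels[h] = lab
        fields[h] = field

    tangential = g - np.array([0.0, 0.0, g[2]])
    return SurfacePhantom(meshes, labels, fields, tangential, slope, noise_sd)


def make_parcel_table(
    n_subjects: int = 413,
    cell_means: np.ndarray | None = None,
    subject_sd: float = 0.05,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Planted subject x subdivision x hemisphere table of mean RTOP values.

    ``cell_means`` is (3 subdivisions x 2 hemispheres), rows ordered
    vAI/dAI/PI, columns L/R; the default plants the vAI < dAI < PI ordering
    with a small hemisphere asymmetry.  Each subject gets a random offset
    (``subject_sd``) plus independent cell noise (``noise_sd``); the planted
    standardized paired difference between two cells with mean gap g is
    g / (sqrt(2) * noise_sd).  Returns a long-format pandas DataFrame with
    columns subject, hemisphere, subdivision, mean_rtop, n_vertices.
    """
    import pandas as pd

    if cell_means is None:
        cell_means = np.array([[1.30, 1.27], [1.40, 1.38], [1.50, 1.47]])
    cell_means = np.asarray(cell_means, dtype=float)
    if cell_means.shape != (3, 2):
        raise ValueError("cell_means must be 3 subdivisions x 2 hemispheres")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        off = subject_sd * rng.standard_normal()
        for i, name in enumerate(SUBDIVISIONS):
            for j, h in enumerate(("L", "R")):
                rows.append({
                    "subject": s,
                    "hemisphere": h,
                    "subdivision": name,
                    "mean_rtop": cell_means[i, j] + off
                    + noise_sd * rng.standard_normal(),
                    "n_vertices": 100,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# resting-state phantom


@dataclass
class RestPhantom:
    """4D resting-state phantom with three seeds per hemisphere, each
    coupled to one of three disjoint target ("ACC") zones."""

    data: np.ndarray  # (x, y, z, t)
    tr: float  # s
    motion_params: np.ndarray  # (t, 6)
    seed_masks: dict[str, np.ndarray]  # "L_vAI" ... -> boolean volume
    planted_targets: dict[str, np.ndarray]  # same keys -> boolean volume
    coupling: float


def make_rest_phantom(
    grid_shape: tuple[int, int, int] = (20, 12, 8),
    n_timepoints: int = 240,
    tr: float = 0.72,
    coupling: float = 0.6,
    seed: int = 0,
) -> RestPhantom:
    """Plant seed-specific connectivity.

    Each of the six seeds (three insula subdivisions x two hemispheres)
    carries an independent latent time series s_k.  Voxels in that seed's
    target zone are ``coupling * s_k + sqrt(1 - coupling^2) * noise`` so the
    planted seed->target correlation is ``coupling`` in population; all
    other voxels are independent noise.  The three target zones per
    hemisphere are disjoint by construction.
    """
    if n_timepoints < 100:
        raise ValueError("n_timepoints must be >= 100")
    if not 0 <= coupling < 1:
        raise ValueError("coupling must be in [0, 1)")
    nx, ny, nz = grid_shape
    if nx < 20 or ny < 8 or nz < 4:
        raise ValueError("grid too small for six seeds and six targets")

    rng = np.random.default_rng(seed)
    t = n_timepoints
    data = rng.standard_normal((*grid_shape, t))

    half = nx // 2
    seed_masks: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    # seeds in the bottom z slab, targets in the top slab ("ACC")
    for hi, h in enumerate(("L", "R")):
        x0 = 0 if h == "L" else half
        for ki, name in enumerate(SUBDIVISIONS):
            key = f"{h}_{name}"
            sm = np.zeros(grid_shape, dtype=bool)
            tm = np.zeros(grid_shape, dtype=bool)
            # zones 2 voxels wide along x with 1-voxel gaps between them,
            # so spatial smoothing does not bleed one zone into the next
            xs = x0 + 1 + 3 * ki
            xe = xs + 2
            sm[xs:xe, 1 : ny // 2 - 1, 1 : nz // 2] = True
            tm[xs:xe, ny // 2 + 1 : ny - 1, nz // 2 : nz - 1] = True
            latent = rng.standard_normal(t)
            mix = np.sqrt(1.0 - coupling**2)
            data[sm] = 0.7 * latent + 0.3 * rng.standard_normal((sm.sum(), t))
            data[tm] = coupling * latent + mix * rng.standard_normal((tm.sum(), t))
            seed_masks[key] = sm
            targets[key] = tm

    # smooth drift + jitter motion parameters, well under screening limits
    # (translations in mm; rotations in rad, which screening scales by 50 mm)
    frames = np.arange(t)
    drift = np.sin(2 * np.pi * frames / t)[:, None] * rng.uniform(0.5, 1.0, size=6)
    scale = np.array([0.05, 0.05, 0.05, 2e-4, 2e-4, 2e-4])
    motion = scale * (drift + 0.05 * rng.standard_normal((t, 6)))
    motion[0] = 0.0
    return RestPhantom(data, tr, motion, seed_masks, targets, coupling)


# ---------------------------------------------------------------------------
# brain-behavior phantom


@dataclass
class BrainBehaviorPhantom:
    """Paired brain (n x 6) and behavior (n x 11) matrices with one planted
    canonical pair at population canonical correlation planted_canonical_r."""

    brain: np.ndarray
    behavior: np.ndarray
    subject_ids: np.ndarray
    planted_canonical_r: float
    planted_weights: tuple[np.ndarray, np.ndarray]
    brain_columns: tuple[str, ...]
    behavior_columns: tuple[str, ...]


BRAIN_COLUMNS = tuple(f"{h}_{s}" for h in ("L", "R") for s in SUBDIVISIONS)
BEHAVIOR_COLUMNS = (
    "nback_acc", "nback_rt", "relational_acc", "relational_rt",
    "gambling_acc", "gambling_rt", "list_sorting", "flanker",
    "card_sorting", "picture_sequence", "processing_speed",
)


def make_brain_behavior(
    n_subjects: int = 413,
    planted_canonical_r: float = 0.32,
    missing_fraction: float = 0.015,
    seed: int = 0,
) -> BrainBehaviorPhantom:
    """Plant exactly one canonical pair.

    Latents u ~ N(0,1) and v = r*u + sqrt(1-r^2)*w give corr(u, v) = r.
    u is embedded as a linear combination of the 6 brain columns and v of
    the 11 behavior columns via invertible mixing, so the population first
    canonical correlation equals ``planted_canonical_r`` exactly and all
    remaining canonical correlations are 0.  Brain columns are then scaled
    to a normalized-RTOP-like range; a ``missing_fraction`` of subjects get
    one missing behavioral cell (NaN).
    """
    if not 0 <= planted_canonical_r < 1:
        raise ValueError("planted_canonical_r must be in [0, 1)")
    if not 0 <= missing_fraction < 0.5:
        raise ValueError("missing_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n = n_subjects
    u = rng.standard_normal(n)
    v = planted_canonical_r * u + np.sqrt(1 - planted_canonical_r**2) * rng.standard_normal(n)

    X0 = np.column_stack([u, rng.standard_normal((n, 5))])
    Y0 = np.column_stack([v, rng.standard_normal((n, 10))])
    A = rng.standard_normal((6, 6)) + 2 * np.eye(6)
    B = rng.standard_normal((11, 11)) + 2 * np.eye(11)
    brain = X0 @ A.T
    behavior = Y0 @ B.T

    # weight vectors recovering the latents: brain @ wx = u
    wx = np.linalg.solve(A, np.eye(6)[:, 0])
    wy = np.linalg.solve(B, np.eye(11)[:, 0])

    # cosmetic scaling to plausible units (leaves CCA invariant)
    brain = 1.4 + 0.08 * brain / brain.std(axis=0)
    behavior = behavior / behavior.std(axis=0) * np.linspace(5, 400, 11) + 100
    wx = wx * A[0, 0]  # rescale consistently only up to sign/scale; CCA invariant

    n_missing = int(round(missing_fraction * n))
    miss_rows = rng.choice(n, size=n_missing, replace=False)
    for r in miss_rows:
        behavior[r, rng.integers(0, 11)] = np.nan

    return BrainBehaviorPhantom(
        brain, behavior, np.arange(100000, 100000 + n),
        planted_canonical_r, (wx, wy), BRAIN_COLUMNS, BEHAVIOR_COLUMNS,
    )
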