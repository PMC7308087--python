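"""Anisotropic Hermite (MAP) basis reconstruction of the q-space signal and
analytic return-to-origin probability (RTOP).

The diffusion signal attenuation E(q) is expanded in the separable basis

    Phi_{n1 n2 n3}(q) = phi_{n1}(u_x, q_x') phi_{n2}(u_y, q_y') phi_{n3}(u_z, q_z')

where q' is q rotated into the frame of a diffusion-tensor pre-fit,
u_i = sqrt(2 lambda_i tau) are per-axis scales (mm), and

    phi_n(u, q) = i^{-n} / sqrt(2^n n!) * exp(-2 pi^2 q^2 u^2) * H_n(2 pi u q)

with H_n the physicists' Hermite polynomial.  Only triples with even total
order N = n1+n2+n3 are used, which makes every basis function real (the
i^{-N} prefactor is +-1) and matches the symmetry E(-q) = E(q).  The number
of basis functions at maximum order N is (N/2+1)(N/2+2)(2N+3)/6.

RTOP is the integral of E over q-space and has a closed form in this basis:
only triples with all n_i even contribute,

    RTOP = (2 pi)^{-3/2} / (u_x u_y u_z)
           * sum_c c * (-1)^{N/2} * prod_i sqrt((n_i - 1)!! / n_i!!).

The least-squares fit carries a Laplacian smoothness penalty
lambda * integral |Delta_q E(q)|^2 d^3q, assembled analytically from 1-D
Gauss-Hermite integrals; the weight can be fixed or chosen per voxel by
generalized cross-validation (GCV).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.hermite import hermval
from scipy.special import factorial, factorial2

from .scheme import AcquisitionScheme

__all__ = [
    "MAPBasisFit",
    "fit_map_basis",
    "rtop_from_fit",
    "normalize_rtop",
    "basis_indices",
    "n_coefficients",
    "FREE_WATER_DIFFUSIVITY",
]

FREE_WATER_DIFFUSIVITY = 3.0e-3  # mm^2/s, water at body temperature


# ---------------------------------------------------------------------------
# basis bookkeeping


def n_coefficients(radial_order: int) -> int:
    h = radial_order // 2
    return (h + 1) * (h + 2) * (2 * radial_order + 3) // 6


@lru_cache(maxsize=None)
def basis_indices(radial_order: int) -> tuple[tuple[int, int, int], ...]:
    """All (n1, n2, n3) with even total order <= radial_order."""
    if radial_order < 0 or radial_order % 2:
        raise ValueError("radial_order must be a non-negative even integer")
    idx = [
        (n1, n2, n3)
        for total in range(0, radial_order + 1, 2)
        for n1 in range(total + 1)
        for n2 in range(total - n1 + 1)
        for n3 in [total - n1 - n2]
    ]
    assert len(idx) == n_coefficients(radial_order)
    return tuple(idx)


def _hermite_at(n_max: int, t: np.ndarray) -> np.ndarray:
    """H_n(t) for n = 0..n_max, shape (n_max+1, len(t))."""
    out = np.empty((n_max + 1, t.size))
    for n in range(n_max + 1):
        c = np.zeros(n + 1)
        c[n] = 1.0
        out[n] = hermval(t, c)
    return out


def _phi_1d(n_max: int, t: np.ndarray) -> np.ndarray:
    """Normalized magnitude part m_n(t) = exp(-t^2/2) H_n(t) / sqrt(2^n n!)."""
    H = _hermite_at(n_max, t)
    norm = np.sqrt(2.0 ** np.arange(n_max + 1) * factorial(np.arange(n_max + 1)))
    return np.exp(-0.5 * t**2)[None, :] * H / norm[:, None]


def _design_matrix(indices, q_local: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Basis matrix, rows = measurements, cols = basis functions.

    q_local: (M, 3) q vectors already rotated into the tensor eigenframe.
    """
    n_max = max(max(i) for i in indices)
    m = [
        _phi_1d(n_max, 2.0 * np.pi * scales[a] * q_local[:, a]) for a in range(3)
    ]
    M = np.empty((q_local.shape[0], len(indices)))
    for j, (n1, n2, n3) in enumerate(indices):
        sign = (-1.0) ** ((n1 + n2 + n3) // 2)
        M[:, j] = sign * m[0][n1] * m[1][n2] * m[2][n3]
    return M


# ---------------------------------------------------------------------------
# Laplacian smoothness penalty


@lru_cache(maxsize=None)
def _laplacian_1d_tables(n_max: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dimensionless 1-D integrals over t of products of m_n and m_n''.

    Returns (S, U, T):
      S[n, m] = int m_n m_m dt
      U[n, m] = int m_n'' m_m dt   (symmetric by parts)
      T[n, m] = int m_n'' m_m'' dt
    computed exactly by Gauss-Hermite quadrature (integrands are
    polynomial * exp(-t^2)).
    """
    nodes, weights = np.polynomial.hermite.hermgauss(2 * n_max + 24)
    H = _hermite_at(n_max + 2, nodes)
    norm = np.sqrt(2.0 ** np.arange(n_max + 1) * factorial(np.arange(n_max + 1)))
    # h_n = H_n / norm; a_n = e^{t^2/2} m_n'' = [4n(n-1)H_{n-2} - 4nt H_{n-1}
    #                                            + (t^2-1) H_n] / norm
    h = H[: n_max + 1] / norm[:, None]
    a = np.empty_like(h)
    for n in range(n_max + 1):
        poly = (nodes**2 - 1.0) * H[n]
        if n >= 1:
            poly = poly - 4.0 * n * nodes * H[n - 1]
        if n >= 2:
            poly = poly + 4.0 * n * (n - 1) * H[n - 2]
        a[n] = poly / norm[n]
    S = (h * weights) @ h.T
    U = (a * weights) @ h.T
    U = 0.5 * (U + U.T)
    T = (a * weights) @ a.T
    return S, U, T


def _laplacian_matrix(indices, scales: np.ndarray) -> np.ndarray:
    """Penalty matrix P with P[j,k] = int Delta Phi_j Delta Phi_k d^3q."""
    n_max = max(max(i) for i in indices)
    S, U, T = _laplacian_1d_tables(n_max)
    idx = np.asarray(indices)
    signs = (-1.0) ** (idx.sum(axis=1) // 2)
    two_pi_u = 2.0 * np.pi * scales
    vol = two_pi_u.prod()
    nF = len(indices)
    P = np.zeros((nF, nF))
    # per-axis index tables
    Saxis = [S[np.ix_(idx[:, a], idx[:, a])] for a in range(3)]
    Uaxis = [U[np.ix_(idx[:, a], idx[:, a])] for a in range(3)]
    Taxis = [T[np.ix_(idx[:, a], idx[:, a])] for a in range(3)]
    for a in range(3):
        for b in range(3):
            factor = (two_pi_u[a] ** 2) * (two_pi_u[b] ** 2) / vol
            term = np.ones((nF, nF))
            for axis in range(3):
                if a == b and axis == a:
                    term = term * Taxis[axis]
                elif axis == a:
                    term = term * Uaxis[axis]
                elif axis == b:
                    term = term * Uaxis[axis].T
                else:
                    term = term * Saxis[axis]
            P += factor * term
    P *= signs[:, None] * signs[None, :]
    return 0.5 * (P + P.T)


# ---------------------------------------------------------------------------
# tensor pre-fit


def _tensor_prefit(signal: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Log-linear least-squares diffusion tensor; returns 3x3 SPD-ish D.

    Only the lowest shell is used: the single-tensor model is a low-b
    approximation, and scales from a low-b fit track the slow tail of
    multi-compartment signals better than an all-shell fit.
    """
    b = scheme.b_values
    g = scheme.directions
    dwi = (b > 0) & (b <= 1.2 * scheme.shells.min())
    s = np.clip(signal[dwi], 1e-6, None)
    gx, gy, gz = g[dwi].T
    X = -b[dwi, None] * np.column_stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )
    coef, *_ = np.linalg.lstsq(X, np.log(s), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def _scales_rotation(D: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis scales u_i = sqrt(2 lambda_i tau) and eigenframe rotation.

    Falls back to isotropic scales from the mean diffusivity when the
    tensor fit is degenerate (non-positive or wildly anisotropic noise fit).
    """
    lam, R = np.linalg.eigh(D)
    md = float(np.clip(np.trace(D) / 3.0, 1e-5, 4e-3))
    if lam.min() <= 1e-6 * max(lam.max(), 1e-12) or lam.min() <= 0:
        lam = np.full(3, md)
        R = np.eye(3)
    lam = np.clip(lam, 1e-5, 4e-3)
    return np.sqrt(2.0 * lam * tau), R


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MAPBasisFit:
    """MAP basis fit for a set of voxels."""

    coefficients: np.ndarray  # (n_voxels, n_basis)
    radial_order: int
    scale_matrix: np.ndarray  # (n_voxels, 3) per-axis scales u, mm
    rotation: np.ndarray  # (n_voxels, 3, 3) eigenframe rotations
    regularization_weight: np.ndarray  # (n_voxels,) effective lambda
    fit_residual: np.ndarray  # (n_voxels,) rms residual

    @property
    def n_voxels(self) -> int:
        return self.coefficients.shape[0]

    def predict(self, scheme: AcquisitionScheme) -> np.ndarray:
        """Reconstructed E(q) at the scheme's measurements, (n_voxels, M)."""
        indices = basis_indices(self.radial_order)
        out = np.empty((self.n_voxels, scheme.n_measurements))
        q = scheme.q_vectors
        for v in range(self.n_voxels):
            q_local = q @ self.rotation[v]
            M = _design_matrix(indices, q_local, self.scale_matrix[v])
            out[v] = M @ self.coefficients[v]
        return out


def _gcv_weight(M: np.ndarray, P: np.ndarray, y: np.ndarray,
                grid: np.ndarray) -> float:
    """Generalized cross-validation over a log-spaced weight grid."""
    MtM = M.T @ M
    Mty = M.T @ y
    n = y.size
    best, best_w = np.inf, grid[0]
    for w in grid:
        try:
            A = MtM + w * P
            c = np.linalg.solve(A, Mty)
            edf = np.trace(np.linalg.solve(A, MtM))
        except np.linalg.LinAlgError:
            continue
        resid = y - M @ c
        denom = max(n - edf, 1e-6)
        score = n * float(resid @ resid) / denom**2
        if score < best:
            best, best_w = score, w
    return float(best_w)


def fit_map_basis(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    radial_order: int = 6,
    regularization: float | str = "gcv",
    noise_sigma: float | None = None,
) -> MAPBasisFit:
    """Fit the MAP basis to b0-normalized signals, one row per voxel.

    Parameters
    ----------
    signals : (n_voxels, n_measurements) or (n_measurements,)
        Signal attenuation normalized so E(b=0) = 1.
    radial_order : even int
        Maximum total Hermite order; 6 gives 50 coefficients.
    regularization : float or "gcv"
        Laplacian penalty weight (dimensionless, scaled by
        trace(M'M)/trace(P)), or "gcv" to pick it per voxel by generalized
        cross-validation.
    noise_sigma : float, optional
        Known Rician noise level (relative to b0).  When given, the
        magnitude noise floor is removed by the moment correction
        sqrt(max(s^2 - 2 sigma^2, 0)) (the second moment of a Rician is
        nu^2 + 2 sigma^2); without it RTOP is biased upward at low SNR.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if noise_sigma is not None:
        if noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        signals = np.sqrt(np.clip(signals**2 - 2.0 * noise_sigma**2, 0.0, None))
    if radial_order < 0 or radial_order % 2:
        raise ValueError("radial_order must be a non-negative even integer")
    if scheme.shells.size < 2:
        raise ValueError("need at least 2 nonzero shells")
    nF = n_coefficients(radial_order)
    if scheme.n_measurements < nF:
        raise np.linalg.LinAlgError(
            f"singular design: {scheme.n_measurements} measurements for "
            f"{nF} coefficients; need at least {nF} at radial_order "
            f"{radial_order}"
        )
    if signals.shape[1] != scheme.n_measurements:
        raise ValueError("signals and scheme measurement counts differ")

    indices = basis_indices(radial_order)
    q = scheme.q_vectors
    nv = signals.shape[0]
    coeffs = np.empty((nv, nF))
    scales = np.empty((nv, 3))
    rots = np.empty((nv, 3, 3))
    weights = np.empty(nv)
    resid = np.empty(nv)
    gcv_grid = np.logspace(-8, 0, 9)

    for v in range(nv):
        y = signals[v]
        D = _tensor_prefit(y, scheme)
        u, R = _scales_rotation(D, scheme.tau)
        q_local = q @ R
        M = _design_matrix(indices, q_local, u)
        P = _laplacian_matrix(indices, u)
        scale = np.trace(M.T @ M) / max(np.trace(P), 1e-300)
        Pn = P * scale
        if regularization == "gcv":
            w = _gcv_weight(M, Pn, y, gcv_grid)
        else:
            w = float(regularization)
            if w < 0:
                raise ValueError("regularization weight must be >= 0")
        c = np.linalg.solve(M.T @ M + w * Pn, M.T @ y)
        r = y - M @ c
        coeffs[v] = c
        scales[v] = u
        rots[v] = R
        weights[v] = w
        resid[v] = float(np.sqrt(np.mean(r**2)))

    return MAPBasisFit(coeffs, radial_order, scales, rots, weights, resid)


# ---------------------------------------------------------------------------
# RTOP


def rtop_from_fit(fit: MAPBasisFit, tau: float | None = None) -> np.ndarray:
    """Analytic RTOP (mm^-3) per voxel from the basis coefficients.

    Only basis functions with all-even (n1, n2, n3) contribute; each
    contributes (-1)^{N/2} prod_i sqrt((n_i-1)!!/n_i!!) divided by the
    q-space scale volume (2 pi)^{3/2} u_x u_y u_z.  ``tau`` is accepted for
    interface symmetry; the diffusion time already enters through the
    fitted scales.
    """
    indices = np.asarray(basis_indices(fit.radial_order))
    even = np.all(indices % 2 == 0, axis=1)
    idx = indices[even]
    parity = (-1.0) ** (idx.sum(axis=1) // 2)
    w = parity * np.prod(
        np.sqrt(factorial2(np.maximum(idx - 1, 0)) / factorial2(np.maximum(idx, 1))),
        axis=1,
    )
    vol = (2.0 * np.pi) ** 1.5 * fit.scale_matrix.prod(axis=1)
    return (fit.coefficients[:, even] @ w) / vol


def normalize_rtop(
    rtop: np.ndarray | float,
    free_diffusivity: float = FREE_WATER_DIFFUSIVITY,
    tau: float = 0.0397,
) -> np.ndarray | float:
    """Normalized RTOP: tissue RTOP / free-water RTOP at the same tau.

    Free water has RTOP (4 pi tau D_free)^{-3/2}, so the normalized value is
    rtop * (4 pi tau D_free)^{3/2}; dimensionless and 1 for free diffusion.
    """
    if free_diffusivity <= 0 or tau <= 0:
        raise ValueError("free_diffusivity and tau must be positive")
    return rtop * (4.0 * np.pi * tau * free_diffusivity) ** 1.5
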