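"""Multi-shell diffusion acquisition schemes.

A pulsed-gradient spin-echo acquisition is summarized by per-measurement
b-values (s/mm^2), unit gradient directions, and the pulse timings
``small_delta`` (gradient duration, s) and ``big_delta`` (gradient
separation, s). The effective diffusion time is ``tau = big_delta -
small_delta / 3`` and q-space magnitudes follow ``q = sqrt(b / (4 pi^2
tau))`` (mm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "make_acquisition_scheme", "fibonacci_sphere"]


@dataclass(frozen=True)
class AcquisitionScheme:
    """One row per measurement; b0 volumes have b = 0 and zero direction."""

    b_values: np.ndarray  # (M,) s/mm^2
    directions: np.ndarray  # (M, 3) unit vectors (zero rows for b0)
    small_delta: float  # s
    big_delta: float  # s
    tau: float = field(init=False)  # s, effective diffusion time

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        d = np.asarray(self.directions, dtype=float)
        if d.shape != (b.size, 3):
            raise ValueError(f"directions shape {d.shape} != ({b.size}, 3)")
        if self.small_delta <= 0 or self.big_delta <= self.small_delta:
            raise ValueError("require big_delta > small_delta > 0")
        norms = np.linalg.norm(d[b > 0], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions for b > 0 must be unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "tau", self.big_delta - self.small_delta / 3.0)

    @property
    def n_measurements(self) -> int:
        return int(self.b_values.size)

    @property
    def q_magnitudes(self) -> np.ndarray:
        """|q| per measurement, mm^-1 (q^2 = b / (4 pi^2 tau))."""
        return np.sqrt(self.b_values / (4.0 * np.pi**2 * self.tau))

    @property
    def q_vectors(self) -> np.ndarray:
        """q vectors, mm^-1, one per measurement."""
        return self.q_magnitudes[:, None] * self.directions

    @property
    def shells(self) -> np.ndarray:
        """Sorted distinct nonzero b-values."""
        return np.unique(self.b_values[self.b_values > 0])

    def subset(self, index: np.ndarray) -> "AcquisitionScheme":
        return AcquisitionScheme(
            self.b_values[index], self.directions[index],
            self.small_delta, self.big_delta,
        )


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (spherical Fibonacci spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_acquisition_scheme(
    b_values: list[float] = (1000.0, 2000.0, 3000.0),
    dirs_per_shell: int = 90,
    n_b0: int = 6,
    small_delta: float = 10.0,
    big_delta: float = 43.0,
    seed: int = 0,
) -> AcquisitionScheme:
    """Build a multi-shell scheme with near-uniform directions per shell.

    Directions are a spherical Fibonacci spiral given a Haar-random rotation
    per shell (seeded, so repeated calls with the same seed are identical).
    ``small_delta`` / ``big_delta`` are in milliseconds here for convenience
    and stored in seconds.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size == 0 or np.any(b <= 0) or np.unique(b).size != b.size:
        raise ValueError("b_values must be positive and distinct")
    if dirs_per_shell < 1:
        raise ValueError("dirs_per_shell must be >= 1")
    if n_b0 < 0:
        raise ValueError("n_b0 must be >= 0")
    if small_delta <= 0 or big_delta <= small_delta:
        raise ValueError("require big_delta > small_delta > 0 (ms)")

    rng = np.random.default_rng(seed)
    base = fibonacci_sphere(dirs_per_shell)
    bvals = [np.zeros(n_b0)]
    dirs = [np.zeros((n_b0, 3))]
    for bval in b:
        rot = _random_rotation(rng)
        bvals.append(np.full(dirs_per_shell, bval))
        dirs.append(base @ rot.T)
    return AcquisitionScheme(
        np.concatenate(bvals), np.vstack(dirs),
        small_delta * 1e-3, big_delta * 1e-3,
    )
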