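"""Traveling-wave geometry on a triangular cilia lattice.

Cilia are modelled as phase oscillators at the sites of a triangular
lattice (default 16 x 16 sites, spacing 18 um) with periodic boundary
conditions.  The boundary conditions admit a finite set of perfect
traveling plane waves of cilia phase; each wave is characterized by a wave
vector

    k = (k_x, k_y) = 2 pi / lambda (-sin theta, cos theta),

where theta is measured from the +y axis, the direction of the cilia
effective stroke, and lambda = 2 pi / |k| is the wavelength.  theta = 0 or
180 deg are symplectic/antiplectic waves (along the stroke axis),
theta = +/-90 deg dexioplectic/laeoplectic (perpendicular to it).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "LatticeSpec",
    "WaveVector",
    "PhaseField",
    "build_lattice",
    "lattice_density",
    "admissible_wavevectors",
    "angle_to_wavevector",
    "wavevector_to_angle",
    "noisy_phase_field",
    "wave_table",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Triangular lattice: basis a1 = a (1, 0), a2 = a (1/2, sqrt(3)/2)."""

    n1: int = 16
    n2: int = 16
    spacing: float = 18.0  # um

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("lattice needs at least one site per direction")
        if self.spacing <= 0:
            raise ValueError("lattice spacing must be positive")

    @property
    def a1(self) -> np.ndarray:
        return self.spacing * np.array([1.0, 0.0])

    @property
    def a2(self) -> np.ndarray:
        return self.spacing * np.array([0.5, np.sqrt(3.0) / 2.0])

    @property
    def b1(self) -> np.ndarray:
        """Reciprocal basis vector with b_i . a_j = 2 pi delta_ij."""
        return (2.0 * np.pi / self.spacing) * np.array([1.0, -1.0 / np.sqrt(3.0)])

    @property
    def b2(self) -> np.ndarray:
        return (2.0 * np.pi / self.spacing) * np.array([0.0, 2.0 / np.sqrt(3.0)])

    @property
    def density(self) -> float:
        return lattice_density(self.spacing)


@dataclass(frozen=True)
class WaveVector:
    """A traveling-wave vector in rad/um."""

    kx: float
    ky: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.kx, self.ky))

    @property
    def wavelength(self) -> float:
        """2 pi / |k| in um; infinite for the in-phase wave k = 0."""
        m = self.magnitude
        return np.inf if m == 0 else 2.0 * np.pi / m

    @property
    def theta_deg(self) -> float:
        """Direction in degrees from the effective-stroke (+y) axis, [0, 360)."""
        if self.magnitude == 0:
            return 0.0
        return float(np.degrees(np.arctan2(-self.kx, self.ky)) % 360.0)


@dataclass
class PhaseField:
    """Per-site phases of a (noisy) traveling wave."""

    phases: np.ndarray
    wavevector: WaveVector
    sigma: float
    seed: int | None


def build_lattice(spec: LatticeSpec) -> np.ndarray:
    """Site positions x_ij = i a1 + j a2 (um), shape (n1*n2, 2)."""
    i, j = np.meshgrid(np.arange(spec.n1), np.arange(spec.n2), indexing="ij")
    pos = i[..., None] * spec.a1 + j[..., None] * spec.a2
    return pos.reshape(-1, 2)


def lattice_density(spacing: float) -> float:
    """Sites per um^2 of a triangular lattice: 2 / (sqrt(3) a^2)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return 2.0 / (np.sqrt(3.0) * spacing**2)


def _reduce_to_bz(k: np.ndarray, spec: LatticeSpec) -> np.ndarray:
    """Canonical first-Brillouin-zone representative of ``k``.

    Minimal |k| over reciprocal-lattice translates; ties broken
    lexicographically by (kx, ky) so each wave has a unique representative.
    """
    cands = []
    for m, n in product(range(-2, 3), repeat=2):
        c = k + m * spec.b1 + n * spec.b2
        cands.append((round(float(np.hypot(*c)), 12), round(c[0], 12), round(c[1], 12), c))
    cands.sort(key=lambda t: t[:3])
    return cands[0][3]


def admissible_wavevectors(spec: LatticeSpec) -> list[WaveVector]:
    """All traveling waves compatible with periodic boundary conditions.

    k = (p/n1) b1 + (q/n2) b2 for p in [0, n1), q in [0, n2), reduced to the
    first Brillouin zone; the in-phase wave k = (0, 0) is included.  The set
    is closed under the 6-fold symmetry of the lattice and under k -> -k
    (time reversal).
    """
    waves = []
    seen = set()
    for p in range(spec.n1):
        for q in range(spec.n2):
            k = _reduce_to_bz((p / spec.n1) * spec.b1 + (q / spec.n2) * spec.b2, spec)
            key = (round(k[0], 9), round(k[1], 9))
            if key in seen:
                continue
            seen.add(key)
            waves.append(WaveVector(kx=float(k[0]), ky=float(k[1])))
    return waves


def angle_to_wavevector(theta_deg: float, wavelength: float) -> WaveVector:
    """k = 2 pi / lambda (-sin theta, cos theta), theta from the +y axis."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    th = np.radians(theta_deg)
    k = 2.0 * np.pi / wavelength
    return WaveVector(kx=float(-k * np.sin(th)), ky=float(k * np.cos(th)))


def wavevector_to_angle(wv: WaveVector) -> tuple[float, float]:
    """Inverse of :func:`angle_to_wavevector`: (theta_deg, wavelength_um)."""
    return wv.theta_deg, wv.wavelength


def noisy_phase_field(
    k: WaveVector,
    positions: np.ndarray,
    sigma: float = 0.0,
    seed: int | None = None,
    global_offset: float | None = None,
) -> PhaseField:
    """Plane-wave phases with Gaussian site noise and a global offset.

    phi_i = wrap(k . x_i + eta_i + U) with eta_i ~ N(0, sigma^2) i.i.d. and
    U ~ Uniform[0, 2 pi) unless ``global_offset`` is given.  Reproducible
    for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 2.0 * np.pi) if global_offset is None else float(global_offset)
    eta = rng.normal(0.0, sigma, size=positions.shape[0]) if sigma > 0 else 0.0
    raw = positions @ np.array([k.kx, k.ky]) + eta + u
    phases = np.pi - np.mod(np.pi - raw, 2.0 * np.pi)
    return PhaseField(phases=phases, wavevector=k, sigma=sigma, seed=seed)


def wave_table(spec: LatticeSpec | None = None) -> pd.DataFrame:
    """Admissible waves as a table: kx, ky, wavelength_um, theta_deg."""
    spec = spec or LatticeSpec()
    waves = admissible_wavevectors(spec)
    return pd.DataFrame(
        {
            "kx_rad_per_um": [w.kx for w in waves],
            "ky_rad_per_um": [w.ky for w in waves],
            "wavelength_um": [w.wavelength for w in waves],
            "theta_deg": [w.theta_deg for w in waves],
        }
    )
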