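"""Vectorial back-focal-plane (pupil) field maps for a high-NA objective.

Every pixel of the pupil corresponds to one plane-wave incidence direction
``(kx, ky)``.  For x-polarized illumination the reflected Cartesian field
components follow from the s/p reflection coefficients of the layered
sample:

    Ex = r_p cos^2(phi) + r_s sin^2(phi)
    Ey = (r_p - r_s) sin(phi) cos(phi)

with ``phi = atan2(ky, kx)`` the pupil azimuth.  The captured BFP image is
``|Ex|^2 + |Ey|^2``.

Grid convention: ``kx = ky = 0`` sits at pixel index ``(N/2, N/2)`` (the
FFT centre after an explicit fftshift), pixels are sampled at their
centres, and the NA mask is the strict-interior disk ``k_r < 2 pi NA /
lambda`` so that every in-mask pixel has an exact mirror partner — the
azimuthal factors are computed from ``kx^2/k_r^2`` etc. so the twofold
mirror symmetry about both axes holds bitwise on the sampled grid.

No aplanatic apodization is applied: the pupil illumination is a uniform
plane-wave expansion and only the reflection coefficients shape the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import LayerStack, stack_reflection

__all__ = ["PupilGrid", "BFPField", "build_pupil_grid", "compute_bfp_fields",
           "bfp_intensity", "bfp_phase", "wrap_phase"]


def wrap_phase(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [-pi, pi)."""
    return (np.asarray(x) + np.pi) % (2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class PupilGrid:
    """k-space sampling of the objective pupil.

    kx, ky, kz are in rad/nm; ``mask`` flags pixels strictly inside the NA
    circle.  ``delta_sin_theta0`` is the per-pixel increment of sin(theta0)
    in the substrate, 2 (NA/n0) / n_pixels.
    """

    n_pixels: int
    na: float
    wavelength_nm: float
    n0: float
    kx: np.ndarray
    ky: np.ndarray
    kz: np.ndarray
    phi: np.ndarray
    mask: np.ndarray

    @property
    def k_max(self) -> float:
        return 2.0 * np.pi * self.na / self.wavelength_nm

    @property
    def delta_sin_theta0(self) -> float:
        return 2.0 * (self.na / self.n0) / self.n_pixels

    @property
    def sin_theta0(self) -> np.ndarray:
        """sin of the substrate incidence angle per pixel (0 outside mask)."""
        kr = np.hypot(self.kx, self.ky)
        s = kr * self.wavelength_nm / (2.0 * np.pi * self.n0)
        return np.where(self.mask, s, 0.0)

    @property
    def theta0(self) -> np.ndarray:
        return np.arcsin(self.sin_theta0)


def build_pupil_grid(
    n_pixels: int = 512,
    na: float = 1.49,
    wavelength_nm: float = 633.0,
    n0: float = 1.52,
) -> PupilGrid:
    """Sample the pupil on an ``n_pixels`` square grid.

    Requires NA < n0 so that kz is real inside the mask (oil-immersion
    objective looking through the glass substrate).
    """
    if na >= n0:
        raise ValueError(f"NA ({na}) must be < substrate index ({n0})")
    if n_pixels % 2:
        raise ValueError("n_pixels must be even")
    k_max = 2.0 * np.pi * na / wavelength_nm
    idx = np.arange(n_pixels) - n_pixels // 2
    k1d = idx * (k_max / (n_pixels // 2))
    kx = np.broadcast_to(k1d[None, :], (n_pixels, n_pixels)).copy()
    ky = np.broadcast_to(k1d[:, None], (n_pixels, n_pixels)).copy()
    kr2 = kx * kx + ky * ky
    mask = kr2 < k_max * k_max
    kn = 2.0 * np.pi * n0 / wavelength_nm
    kz = np.where(mask, np.sqrt(np.maximum(kn * kn - kr2, 0.0)), 0.0)
    phi = np.arctan2(ky, kx)
    return PupilGrid(n_pixels, na, wavelength_nm, n0, kx, ky, kz, phi, mask)


@dataclass(frozen=True)
class BFPField:
    """Complex Ex/Ey maps over the pupil (zero outside the NA mask)."""

    Ex: np.ndarray
    Ey: np.ndarray
    grid: PupilGrid
    stack: LayerStack | None = None


def compute_bfp_fields(grid: PupilGrid, stack: LayerStack) -> BFPField:
    """Reflected vectorial pupil field for x-polarized illumination."""
    if stack.wavelength_nm != grid.wavelength_nm:
        raise ValueError("stack and grid wavelengths differ")
    m = grid.mask
    theta0 = np.arcsin(grid.sin_theta0[m])
    r_p = stack_reflection(stack, theta0, "p")
    r_s = stack_reflection(stack, theta0, "s")

    # Azimuthal factors from squared coordinates: bitwise mirror-symmetric.
    kx, ky = grid.kx[m], grid.ky[m]
    kr2 = kx * kx + ky * ky
    centre = kr2 == 0.0
    kr2_safe = np.where(centre, 1.0, kr2)
    cos2 = np.where(centre, 1.0, kx * kx / kr2_safe)
    sin2 = np.where(centre, 0.0, ky * ky / kr2_safe)
    sincos = np.where(centre, 0.0, kx * ky / kr2_safe)

    Ex = np.zeros(m.shape, dtype=complex)
    Ey = np.zeros(m.shape, dtype=complex)
    Ex[m] = r_p * cos2 + r_s * sin2
    Ey[m] = (r_p - r_s) * sincos
    return BFPField(Ex, Ey, grid, stack)


def bfp_intensity(field: BFPField) -> np.ndarray:
    """Captured BFP image |Ex|^2 + |Ey|^2 (zero outside the mask)."""
    return np.abs(field.Ex) ** 2 + np.abs(field.Ey) ** 2


def bfp_phase(field: BFPField, component: str = "x") -> np.ndarray:
    """Wrapped phase (rad, in [-pi, pi)) of Ex or Ey; 0 outside the mask."""
    if component not in ("x", "y"):
        raise ValueError("component must be 'x' or 'y'")
    comp = field.Ex if component == "x" else field.Ey
    ph = wrap_phase(np.angle(comp))
    return np.where(field.grid.mask, ph, 0.0)
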