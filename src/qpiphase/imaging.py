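"""Image-plane formation by Fourier propagation and confocal V(z) signals.

A sample defocus ``z`` (positive = sample moved away from the objective)
multiplies the pupil field by the double-pass transfer function
``exp(2 i kz z)`` — the factor 2 reflects the reflection geometry.  The
image-plane field components are centered inverse Fourier transforms of
the defocused pupil field:

    IMPx = IFFT{ Ex exp(2 i kz z) },  IMPy likewise,
    IMP  = |IMPx|^2 + |IMPy|^2.

Unitary ("ortho") FFT normalization is used so total energy is conserved
exactly across defocus (kz is real inside the NA < n0 pupil, hence the
defocus factor has unit modulus).

The confocal response V(z) integrates the defocused pupil field against a
pupil weight (unity by default):  V(z) = sum_pupil w Ex exp(2 i kz z).
For a plasmonic sample defocused toward the objective (z < 0) the beating
between the surface-plasmon ray bundle and the remaining pupil produces
periodic ripples in |V(z)| with period  lambda / (2 n0 (1 - cos(theta_sp))).

The image-plane pixel pitch is the FFT-conjugate pitch
lambda / (2 NA) (full k-space span 2 k_max over n_pixels samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pupil import BFPField, PupilGrid

__all__ = ["ImageField", "VzCurve", "propagate_defocus", "imp_intensity",
           "vz_signal", "vz_ripple_period"]

_UM_TO_NM = 1000.0


@dataclass(frozen=True)
class ImageField:
    """Complex image-plane field components at defocus ``z_um``."""

    IMPx: np.ndarray
    IMPy: np.ndarray
    z_um: float
    grid: PupilGrid


@dataclass(frozen=True)
class VzCurve:
    """Complex confocal response sampled on ``z_um``."""

    z_um: np.ndarray
    V: np.ndarray

    def magnitude(self, normalize: bool = True) -> np.ndarray:
        mag = np.abs(self.V)
        if normalize and mag.max() > 0:
            mag = mag / mag.max()
        return mag


def _centered_ifft2(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a), norm="ortho"))


def defocus_factor(grid: PupilGrid, z_um: float) -> np.ndarray:
    """Unit-modulus double-pass defocus transfer function exp(2 i kz z)."""
    return np.where(grid.mask, np.exp(2j * grid.kz * (z_um * _UM_TO_NM)), 0.0)


def propagate_defocus(field: BFPField, z_um: float) -> ImageField:
    """Image-plane field of a sample defocused by ``z_um`` micrometres."""
    if not np.isfinite(z_um):
        raise ValueError("z must be finite")
    h = defocus_factor(field.grid, z_um)
    return ImageField(
        IMPx=_centered_ifft2(field.Ex * h),
        IMPy=_centered_ifft2(field.Ey * h),
        z_um=float(z_um),
        grid=field.grid,
    )


def imp_intensity(image: ImageField) -> np.ndarray:
    """Captured image-plane intensity |IMPx|^2 + |IMPy|^2."""
    return np.abs(image.IMPx) ** 2 + np.abs(image.IMPy) ** 2


def vz_signal(
    field: BFPField,
    z_um: np.ndarray,
    pupil_weight: np.ndarray | None = None,
) -> VzCurve:
    """Confocal V(z) of the x field component over the pupil.

    ``pupil_weight`` (same shape as the pupil) defaults to unity over the
    NA mask.
    """
    z_um = np.asarray(z_um, dtype=float)
    if not np.all(np.isfinite(z_um)):
        raise ValueError("z values must be finite")
    m = field.grid.mask
    w = np.ones(m.sum()) if pupil_weight is None else np.asarray(pupil_weight)[m]
    ex = field.Ex[m]
    kz = field.grid.kz[m]
    # phase matrix (n_z, n_pupil) kept explicit; pupil sizes stay modest
    ph = np.exp(2j * np.outer(z_um * _UM_TO_NM, kz))
    V = ph @ (w * ex)
    return VzCurve(z_um, V)


def vz_ripple_period(wavelength_nm: float, n0: float, theta_sp: float) -> float:
    """Closed-form V(z) ripple period (um) for plasmon angle ``theta_sp``.

    Delta z = lambda / (2 n0 (1 - cos(theta_sp))).
    """
    return wavelength_nm / (2.0 * n0 * (1.0 - np.cos(theta_sp))) / _UM_TO_NM
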