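"""Optical constants and reflection of stratified layered samples.

The physical samples are single thin films deposited on a glass coverslip
(index ``n0``) and probed through the substrate in a Kretschmann-style
reflection geometry: glass -> film -> backing medium.  Complex amplitude
reflection coefficients are computed with the Fresnel equations (bare
interface) and the 2x2 characteristic-matrix (transfer-matrix) method for
films of finite thickness.

Conventions
-----------
Time dependence is ``exp(-i omega t)``; absorbing media therefore carry a
*positive* imaginary refractive index (gold at 633 nm has Im(n) > 0).
Evanescent waves beyond a critical angle are handled through complex
transmitted-angle cosines with the decaying branch ``Im(n cos(theta)) >= 0``.

The p-polarized coefficient uses the tilted-admittance convention
(``eta_p = n / cos(theta)``), for which ``r_p`` and ``r_s`` coincide at
normal incidence.  This is the convention under which the vectorial pupil
field ``Ex = r_p cos^2(phi) + r_s sin^2(phi)`` is continuous at the pupil
centre; it preserves the Brewster zero and unit-modulus total internal
reflection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "OpticalConstants",
    "LayerStack",
    "material_index",
    "fresnel_interface",
    "stack_reflection",
    "reflectance_scan",
    "find_reflectance_dip",
    "critical_angle",
    "FIXED_INDEX_MATERIALS",
]

# Nominal indices at 633 nm for materials the tables name without printing
# values.  BK7 is the coverslip substrate; air/water are backing media;
# PMMA is the dielectric waveguide film.
FIXED_INDEX_MATERIALS: dict[str, complex] = {
    "BK7": 1.52 + 0.0j,
    "air": 1.00 + 0.0j,
    "water": 1.33 + 0.0j,
    "PMMA": 1.489 + 0.0j,
}


@dataclass(frozen=True)
class OpticalConstants:
    """Tabulated complex refractive index of one material.

    ``wavelength_nm`` must be strictly increasing; ``index`` holds n + ik
    with k >= 0 (absorbing under the exp(-i omega t) convention).
    """

    material_id: str
    wavelength_nm: np.ndarray
    index: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        nk = np.asarray(self.index, dtype=complex)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if wl.size != nk.size:
            raise ValueError("wavelength and index arrays must have equal length")
        if np.any(nk.imag < 0):
            raise ValueError("imaginary part of the index must be >= 0")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "index", nk)

    def at(self, wavelength_nm: float) -> complex:
        """Linearly interpolated complex index at ``wavelength_nm``."""
        wl = self.wavelength_nm
        if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
            raise ValueError(
                f"{wavelength_nm} nm outside tabulated range "
                f"[{wl[0]:.1f}, {wl[-1]:.1f}] for {self.material_id!r}"
            )
        n = np.interp(wavelength_nm, wl, self.index.real)
        k = np.interp(wavelength_nm, wl, self.index.imag)
        return complex(n, k)


def _load_gold_table(path=None) -> OpticalConstants:
    if path is None:
        src = resources.files("qpiphase.data") / "gold_johnson_christy.csv"
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = list(csv.DictReader(text.splitlines()))
    wl = np.array([float(r["wavelength_nm"]) for r in rows])
    nk = np.array([float(r["n"]) + 1j * float(r["k"]) for r in rows])
    return OpticalConstants("gold", wl, nk)


_GOLD = _load_gold_table()


def material_index(
    material_id: str,
    wavelength_nm: float,
    scale: float = 1.0,
    *,
    table_path: str | None = None,
) -> complex:
    """Complex refractive index of a named material at ``wavelength_nm``.

    ``scale`` multiplies the full complex index (real and imaginary parts
    jointly); it models the +-10% perturbation of the gold index used when
    randomizing the plasmonic training samples.  ``table_path`` overrides
    the embedded gold dispersion table with a user CSV (wavelength_nm,n,k).
    """
    if material_id == "gold":
        table = _GOLD if table_path is None else _load_gold_table(table_path)
        return scale * table.at(wavelength_nm)
    try:
        base = FIXED_INDEX_MATERIALS[material_id]
    except KeyError:
        raise KeyError(f"unknown material {material_id!r}") from None
    return scale * base


@dataclass(frozen=True)
class LayerStack:
    """Glass substrate -> deposited layers -> backing medium.

    ``layers`` is an ordered sequence of ``(complex_index, thickness_nm)``
    from the substrate outward.  The phase of the reflection coefficient is
    referenced at the substrate/first-layer interface.
    """

    n0: float
    layers: tuple[tuple[complex, float], ...]
    ns: float
    wavelength_nm: float
    label: str = ""

    def __post_init__(self) -> None:
        layers = tuple((complex(n), float(d)) for n, d in self.layers)
        if any(d < 0 for _, d in layers):
            raise ValueError("layer thicknesses must be >= 0")
        object.__setattr__(self, "layers", layers)


def _cos_transmitted(n_in: complex, n_out: np.ndarray | complex,
                     theta_in: np.ndarray, branch: int = +1) -> np.ndarray:
    """Complex cosine of the transmitted angle, decaying-wave branch.

    ``branch=+1`` selects Im(n_out cos) >= 0 (exp(-i omega t) convention);
    ``branch=-1`` the conjugate convention.
    """
    sin_t = n_in * np.sin(theta_in) / n_out
    cos_t = np.sqrt((1.0 + 0j) - sin_t * sin_t)
    flip = (branch * np.imag(n_out * cos_t)) < 0
    return np.where(flip, -cos_t, cos_t)


def _admittance(n: complex | np.ndarray, cos_t: np.ndarray, polarization: str) -> np.ndarray:
    if polarization == "s":
        return n * cos_t
    if polarization == "p":
        return n / cos_t
    raise ValueError("polarization must be 's' or 'p'")


def fresnel_interface(
    n1: float,
    n2: complex,
    theta1: float | np.ndarray,
    polarization: str,
    *,
    branch: int = +1,
) -> complex | np.ndarray:
    """Amplitude reflection coefficient of a single planar interface.

    ``theta1`` (rad, in the incidence medium ``n1``) may be an array.
    """
    theta1 = np.asarray(theta1, dtype=float)
    cos1 = np.cos(theta1).astype(complex)
    cos2 = _cos_transmitted(n1, n2 + 0j, theta1, branch)
    e1 = _admittance(n1 + 0j, cos1, polarization)
    e2 = _admittance(n2 + 0j, cos2, polarization)
    r = (e1 - e2) / (e1 + e2)
    return r if r.shape else complex(r)


def stack_reflection(
    stack: LayerStack,
    theta0: float | np.ndarray,
    polarization: str,
    *,
    branch: int = +1,
) -> complex | np.ndarray:
    """Complex reflection coefficient of a layer stack vs substrate angle.

    Characteristic-matrix product over the layers combined with the
    substrate/backing tilted admittances.  Reduces exactly to
    :func:`fresnel_interface` for an empty stack or zero-thickness layers.
    """
    theta0 = np.asarray(theta0, dtype=float)
    k0 = 2.0 * np.pi / stack.wavelength_nm
    cos0 = np.cos(theta0).astype(complex)
    eta0 = _admittance(stack.n0 + 0j, cos0, polarization)

    # (B, C) = product of layer matrices applied to (1, eta_backing)
    cos_b = _cos_transmitted(stack.n0, stack.ns + 0j, theta0, branch)
    eta_b = _admittance(stack.ns + 0j, cos_b, polarization)
    B = np.ones_like(eta_b)
    C = eta_b
    for n_m, d_m in reversed(stack.layers):
        cos_m = _cos_transmitted(stack.n0, n_m, theta0, branch)
        eta_m = _admittance(n_m, cos_m, polarization)
        delta = k0 * n_m * d_m * cos_m
        cd, sd = np.cos(delta), np.sin(delta)
        # characteristic matrix [[cos d, -i sin d / eta], [-i eta sin d, cos d]];
        # the -i entries belong to exp(-i omega t) and flip with the convention
        ji = -1j * branch
        B, C = cd * B + ji * sd * C / eta_m, ji * eta_m * sd * B + cd * C
    r = (eta0 * B - C) / (eta0 * B + C)
    return r if r.shape else complex(r)


def critical_angle(n0: float, ns: float) -> float:
    """Substrate-side critical angle (rad) for total internal reflection."""
    if ns >= n0:
        raise ValueError("no critical angle: backing index >= substrate index")
    return float(np.arcsin(ns / n0))


def reflectance_scan(
    stack: LayerStack,
    polarization: str = "p",
    theta_max: float | None = None,
    n_angles: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """``(theta0, |r|^2)`` scan from normal incidence to ``theta_max``."""
    if theta_max is None:
        theta_max = np.pi / 2 * 0.999
    theta = np.linspace(0.0, theta_max, n_angles)
    r = stack_reflection(stack, theta, polarization)
    return theta, np.abs(r) ** 2


def find_reflectance_dip(
    stack: LayerStack,
    polarization: str = "p",
    theta_min: float = 0.0,
    theta_max: float | None = None,
    n_angles: int = 4000,
) -> tuple[float, float]:
    """Angle (rad) and reflectance at the deepest |r|^2 minimum.

    Brute-force scan refined by one parabolic interpolation step; used as
    the resonance-angle oracle for the surface-plasmon dip.
    """
    theta, R = reflectance_scan(stack, polarization, theta_max, n_angles)
    sel = theta >= theta_min
    theta, R = theta[sel], R[sel]
    i = int(np.argmin(R))
    if 0 < i < len(theta) - 1:
        y0, y1, y2 = R[i - 1], R[i], R[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            shift = 0.5 * (y0 - y2) / denom
            return float(theta[i] + shift * (theta[1] - theta[0])), float(y1)
    return float(theta[i]), float(R[i])
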