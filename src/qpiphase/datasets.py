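"""Supervised dataset generation for pupil-phase regression.

Each record pairs intensity images a microscope could capture (the BFP
image and/or defocused image-plane images) with the ground-truth wrapped
phase of the Ex pupil component as the regression label.  Sample physics
parameters are drawn uniformly within the training ranges:

SPR samples      : gold thickness 30-60 nm, gold index scaled +-10%,
                   backing index 1.0-1.4, wavelength 600-700 nm.
Waveguide samples: dielectric thickness 0.95-1.05 um, film index 1.20-1.50,
                   backing index 1.0-1.4, wavelength 600-700 nm.

Because the BFP/IMP images of these uniform samples have twofold mirror
symmetry about both k-axes, only the upper-right quadrant (kx >= 0,
ky >= 0, including the centre row/column) is kept as network input/label;
the other quadrants are exact mirror copies.

Five input layouts are supported (network variants CAN1-CAN5):
CAN1 [BFP], CAN2 [BFP, IMP(z1)], CAN3 [IMP(z1)], CAN4 [IMP(z1), IMP(z2)],
CAN5 [IMP(z1), IMP(z2), IMP(z3)].  IMP channels are z-score normalized;
the BFP intensity channel is left on its natural [0, ~1] scale unless
requested otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .imaging import imp_intensity, propagate_defocus
from .materials import LayerStack, material_index
from .pupil import PupilGrid, bfp_intensity, bfp_phase, build_pupil_grid, compute_bfp_fields

__all__ = [
    "ParameterSet", "DatasetRecord", "DatasetSplit",
    "TRAINING_RANGES", "DEFAULT_Z_LISTS", "N_CHANNELS",
    "sample_parameters", "make_test_set", "crop_quadrant",
    "reconstruct_from_quadrant", "zscore_normalize", "simulate_fields",
    "assemble_record", "split_dataset", "save_dataset", "load_dataset",
    "min_parameter_distance",
]

TRAINING_RANGES = {
    "spr": {
        "d_m_nm": (30.0, 60.0),
        "gold_scale": (0.9, 1.1),
        "n_s": (1.0, 1.4),
        "wavelength_nm": (600.0, 700.0),
    },
    "waveguide": {
        "d_m_um": (0.95, 1.05),
        "n_m": (1.20, 1.50),
        "n_s": (1.0, 1.4),
        "wavelength_nm": (600.0, 700.0),
    },
}

#: focal-plane image for the BFP+IMP variant; 6 um defocus when learning
#: from image-plane data alone (best single plane found for that layout)
DEFAULT_Z_LISTS = {
    "CAN1": (),
    "CAN2": (0.0,),
    "CAN3": (6.0,),
    "CAN4": (6.0, 9.0),
    "CAN5": (6.0, 7.5, 9.0),
}

#: whether the variant includes the BFP channel, and its IMP-plane count
_VARIANT_LAYOUT = {
    "CAN1": (True, 0),
    "CAN2": (True, 1),
    "CAN3": (False, 1),
    "CAN4": (False, 2),
    "CAN5": (False, 3),
}

N_CHANNELS = {v: int(b) + n for v, (b, n) in _VARIANT_LAYOUT.items()}


@dataclass(frozen=True)
class ParameterSet:
    """Physical parameters of one simulated sample.

    ``d_m`` is in nm for SPR samples and in um for waveguide samples
    (matching how the two sample families are specified).  For SPR samples
    ``gold_scale`` multiplies the tabulated gold index; ``n_m`` is the real
    film index for waveguides.
    """

    sample_type: str
    d_m: float
    n_s: float
    wavelength_nm: float
    gold_scale: float | tuple[float, float] | None = None
    n_m: float | None = None
    case_id: int | None = None

    @property
    def thickness_nm(self) -> float:
        return self.d_m if self.sample_type == "spr" else self.d_m * 1000.0

    @property
    def medium_index(self) -> complex:
        if self.sample_type == "spr":
            base = material_index("gold", self.wavelength_nm)
            s = self.gold_scale if self.gold_scale is not None else 1.0
            if isinstance(s, tuple):  # independent n/k perturbation
                return complex(s[0] * base.real, s[1] * base.imag)
            return s * base
        return complex(self.n_m)

    def to_layer_stack(self, n0: float = 1.52) -> LayerStack:
        return LayerStack(
            n0=n0,
            layers=((self.medium_index, self.thickness_nm),),
            ns=self.n_s,
            wavelength_nm=self.wavelength_nm,
            label=f"{self.sample_type}"
            + (f"#{self.case_id}" if self.case_id is not None else ""),
        )

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("sample_type", "d_m", "n_s", "wavelength_nm", "gold_scale", "n_m", "case_id")}
        if isinstance(d["gold_scale"], tuple):
            d["gold_scale"] = list(d["gold_scale"])
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ParameterSet":
        d = json.loads(s)
        if isinstance(d.get("gold_scale"), list):
            d["gold_scale"] = tuple(d["gold_scale"])
        return cls(**d)


def sample_parameters(
    sample_type: str,
    n_draws: int,
    seed: int,
    independent_gold_scale: bool = False,
) -> list[ParameterSet]:
    """Uniform independent draws of the four physical parameters."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if sample_type not in TRAINING_RANGES:
        raise ValueError(f"unknown sample_type {sample_type!r}")
    rng = np.random.default_rng(seed)
    r = TRAINING_RANGES[sample_type]
    out: list[ParameterSet] = []
    if sample_type == "spr":
        d = rng.uniform(*r["d_m_nm"], n_draws)
        if independent_gold_scale:
            s = np.stack([rng.uniform(*r["gold_scale"], n_draws),
                          rng.uniform(*r["gold_scale"], n_draws)], axis=1)
        else:
            s = rng.uniform(*r["gold_scale"], n_draws)
        ns = rng.uniform(*r["n_s"], n_draws)
        wl = rng.uniform(*r["wavelength_nm"], n_draws)
        for i in range(n_draws):
            scale = tuple(s[i]) if independent_gold_scale else float(s[i])
            out.append(ParameterSet("spr", float(d[i]), float(ns[i]),
                                    float(wl[i]), gold_scale=scale))
    else:
        d = rng.uniform(*r["d_m_um"], n_draws)
        nm = rng.uniform(*r["n_m"], n_draws)
        ns = rng.uniform(*r["n_s"], n_draws)
        wl = rng.uniform(*r["wavelength_nm"], n_draws)
        for i in range(n_draws):
            out.append(ParameterSet("waveguide", float(d[i]), float(ns[i]),
                                    float(wl[i]), n_m=float(nm[i])))
    return out


def make_test_set(sample_type: str) -> list[ParameterSet]:
    """The six fixed held-out evaluation cases for each sample family.

    Three film thicknesses, each with air and water backing, all at the
    HeNe wavelength 633 nm (nominal gold / PMMA film index).
    """
    backing = [("air", 1.0)] * 3 + [("water", 1.33)] * 3
    out: list[ParameterSet] = []
    if sample_type == "spr":
        thick = [30.0, 40.0, 50.0] * 2
        for i, (d, (_, ns)) in enumerate(zip(thick, backing), start=1):
            out.append(ParameterSet("spr", d, ns, 633.0, gold_scale=1.0, case_id=i))
    elif sample_type == "waveguide":
        thick = [0.95, 1.0, 1.05] * 2
        pmma = material_index("PMMA", 633.0).real
        for i, (d, (_, ns)) in enumerate(zip(thick, backing), start=1):
            out.append(ParameterSet("waveguide", d, ns, 633.0, n_m=pmma, case_id=i))
    else:
        raise ValueError(f"unknown sample_type {sample_type!r}")
    return out


def crop_quadrant(image: np.ndarray) -> np.ndarray:
    """Upper-right quadrant (kx >= 0, ky >= 0) incl. the centre row/column."""
    if image.ndim != 2 or image.shape[0] != image.shape[1] or image.shape[0] % 2:
        raise ValueError(f"expected an even square image, got {image.shape}")
    n2 = image.shape[0] // 2
    return image[n2:, n2:]


def reconstruct_from_quadrant(quadrant: np.ndarray) -> np.ndarray:
    """Rebuild the full map from its upper-right quadrant by mirroring.

    Exact inverse of :func:`crop_quadrant` for maps with the twofold
    mirror symmetry of x-polarized pupil responses.  Row/column 0 of the
    full map have no mirror partner and are set to zero; they lie outside
    the strict-interior NA mask.
    """
    if quadrant.ndim != 2 or quadrant.shape[0] != quadrant.shape[1]:
        raise ValueError(f"expected a square quadrant, got {quadrant.shape}")
    n2 = quadrant.shape[0]
    n = 2 * n2
    full = np.zeros((n, n), dtype=quadrant.dtype)
    full[n2:, n2:] = quadrant
    full[n2:, 1:n2] = quadrant[:, n2 - 1:0:-1]
    full[1:n2, :] = full[n - 1:n2:-1, :]
    return full


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance normalization of one image."""
    sd = image.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("z-score normalization of a constant image is degenerate")
    return (image - image.mean()) / sd


@dataclass(frozen=True)
class DatasetRecord:
    """Stacked input channels + wrapped-phase label for one sample."""

    inputs: np.ndarray          # (C, H, W) float32
    label: np.ndarray           # (H, W) float64, wrapped to [-pi, pi)
    params: ParameterSet
    variant: str
    z_list: tuple[float, ...]


def simulate_fields(params: ParameterSet, grid: PupilGrid):
    """Pupil field of one parameter set on a given grid."""
    stack = params.to_layer_stack(n0=grid.n0)
    grid_wl = replace_wavelength(grid, params.wavelength_nm)
    return compute_bfp_fields(grid_wl, stack), grid_wl


def replace_wavelength(grid: PupilGrid, wavelength_nm: float) -> PupilGrid:
    """Grid with identical geometry rebuilt for another wavelength."""
    if wavelength_nm == grid.wavelength_nm:
        return grid
    return build_pupil_grid(grid.n_pixels, grid.na, wavelength_nm, grid.n0)


def assemble_record(
    params: ParameterSet,
    variant: str,
    z_list: Sequence[float] | None = None,
    grid: PupilGrid | None = None,
    normalize_bfp: bool = False,
    imp_amplitude: bool = False,
) -> DatasetRecord:
    """Simulate one sample and stack its input channels per the variant.

    ``imp_amplitude`` switches the IMP channels from intensity to
    amplitude (sqrt of intensity) before z-score normalization.
    """
    if variant not in _VARIANT_LAYOUT:
        raise ValueError(f"unknown variant {variant!r}")
    with_bfp, n_imp = _VARIANT_LAYOUT[variant]
    if z_list is None:
        z_list = DEFAULT_Z_LISTS[variant]
    z_list = tuple(float(z) for z in z_list)
    if len(z_list) != n_imp:
        raise ValueError(f"{variant} needs {n_imp} defocus planes, got {len(z_list)}")
    if grid is None:
        grid = build_pupil_grid(wavelength_nm=params.wavelength_nm)

    field, grid_wl = simulate_fields(params, grid)
    channels: list[np.ndarray] = []
    if with_bfp:
        ch = crop_quadrant(bfp_intensity(field))
        channels.append(zscore_normalize(ch) if normalize_bfp else ch)
    for z in z_list:
        img = imp_intensity(propagate_defocus(field, z))
        if imp_amplitude:
            img = np.sqrt(img)
        channels.append(zscore_normalize(crop_quadrant(img)))
    label = crop_quadrant(bfp_phase(field, "x"))
    return DatasetRecord(
        inputs=np.stack(channels).astype(np.float32),
        label=label.astype(np.float64),
        params=params,
        variant=variant,
        z_list=z_list,
    )


@dataclass(frozen=True)
class DatasetSplit:
    train: list[DatasetRecord]
    validation: list[DatasetRecord]
    fraction: float


def split_dataset(
    records: Sequence[DatasetRecord],
    fraction: float = 0.9,
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic shuffled train/validation split."""
    if not records:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(records)
    n_train = int(round(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in perm[:n_train]]
    val = [records[i] for i in perm[n_train:]]
    return DatasetSplit(train, val, fraction)


def min_parameter_distance(
    draws: Sequence[ParameterSet], tests: Sequence[ParameterSet]
) -> float:
    """Smallest max-norm distance between any draw and any test case.

    Used to assert that the fixed evaluation cases are not present in the
    randomized training draws.
    """
    def vec(p: ParameterSet) -> np.ndarray:
        if p.sample_type == "spr":
            s = p.gold_scale if p.gold_scale is not None else 1.0
            s = s[0] if isinstance(s, tuple) else s
            return np.array([p.d_m, s, p.n_s, p.wavelength_nm])
        return np.array([p.d_m, p.n_m, p.n_s, p.wavelength_nm])

    a = np.stack([vec(p) for p in draws])
    b = np.stack([vec(p) for p in tests])
    d = np.abs(a[:, None, :] - b[None, :, :]).max(axis=2)
    return float(d.min())


def save_dataset(records: Sequence[DatasetRecord], path, config: dict | None = None) -> None:
    """Write records to one HDF5 file (+ JSON sidecar for the config)."""
    if not records:
        raise ValueError("nothing to save")
    inputs = np.stack([r.inputs for r in records])
    labels = np.stack([r.label for r in records])
    params = [r.params.to_json() for r in records]
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=inputs)
        f.create_dataset("labels", data=labels)
        f.create_dataset("params", data=params)
        f.attrs["variant"] = records[0].variant
        f.attrs["z_list"] = list(records[0].z_list)
    if config is not None:
        with open(f"{path}.json", "w") as fh:
            json.dump(config, fh, indent=2, sort_keys=True)


def load_dataset(path) -> list[DatasetRecord]:
    with h5py.File(path, "r") as f:
        inputs = f["inputs"][...]
        labels = f["labels"][...]
        params = [ParameterSet.from_json(s.decode() if isinstance(s, bytes) else s)
                  for s in f["params"][...]]
        variant = f.attrs["variant"]
        z_list = tuple(float(z) for z in f.attrs["z_list"])
    return [
        DatasetRecord(inputs[i], labels[i], params[i], variant, z_list)
        for i in range(len(params))
    ]
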