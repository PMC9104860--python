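"""Offset-invariant SSIM evaluation of recovered wrapped-phase maps.

A recovered pupil phase is physically meaningful only up to a global
phase constant, so the structural similarity index is maximized over a
uniform grid of constant offsets delta in [0, 2pi): both maps are
compared wrapped to [-pi, pi) with SSIM dynamic range 2pi (standard
11-pixel Gaussian window, sigma 1.5, K1 = 0.01, K2 = 0.03).  Evaluation
tables report the per-test-case SSIM, the maximizing offset, and their
average.

The functional check compares confocal V(z) curves computed from the
theoretical pupil field and from a surrogate field |Ex| e^{i phi_rec}
rebuilt from the recovered quadrant phase; a global phase constant
cancels in |V(z)|, so matching ripple structure indicates a practically
usable recovered phase.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .can import CAN, ablate_channel, predict
from .datasets import DatasetRecord, reconstruct_from_quadrant
from .imaging import VzCurve, vz_signal
from .pupil import BFPField, wrap_phase

__all__ = ["EvalResult", "EvalTable", "wrap_phase", "ssim_phase",
           "evaluate_model", "compare_vz"]

_ABLATION_CHANNEL = {"none": None, "bfp_off": 0, "imp_off": 1}


def ssim_phase(
    recovered: np.ndarray,
    theoretical: np.ndarray,
    n_offsets: int = 360,
) -> tuple[float, float]:
    """Best SSIM between wrapped phase maps over constant offsets.

    Returns ``(ssim, best_offset)`` with the offset (rad, in [0, 2pi))
    that maximizes similarity of ``wrap(recovered + offset)`` against
    ``wrap(theoretical)``.
    """
    recovered = np.asarray(recovered, dtype=float)
    theoretical = np.asarray(theoretical, dtype=float)
    if recovered.shape != theoretical.shape:
        raise ValueError("phase maps must have the same shape")
    if n_offsets < 2:
        raise ValueError("n_offsets must be >= 2")
    ref = wrap_phase(theoretical)
    best = (-np.inf, 0.0)
    for delta in np.linspace(0.0, 2.0 * np.pi, n_offsets, endpoint=False):
        s = structural_similarity(
            wrap_phase(recovered + delta), ref,
            data_range=2.0 * np.pi, win_size=11,
            gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03)
        if s > best[0]:
            best = (float(s), float(delta))
    return best


@dataclass(frozen=True)
class EvalResult:
    case_id: int | None
    ssim: float
    best_offset: float
    variant: str
    ablation: str = "none"


@dataclass(frozen=True)
class EvalTable:
    rows: tuple[EvalResult, ...]

    @property
    def average(self) -> float:
        return float(np.mean([r.ssim for r in self.rows]))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["case", "variant", "ablation", "ssim", "best_offset_rad"])
            for r in self.rows:
                w.writerow([r.case_id, r.variant, r.ablation,
                            f"{r.ssim:.4f}", f"{r.best_offset:.4f}"])
            w.writerow(["Average", self.rows[0].variant if self.rows else "",
                        self.rows[0].ablation if self.rows else "",
                        f"{self.average:.4f}", ""])

    def render(self) -> str:
        lines = [f"{'Data No.':>8}  {'SSIM':>8}  {'offset (rad)':>12}"]
        for r in self.rows:
            lines.append(f"{str(r.case_id):>8}  {r.ssim:8.4f}  {r.best_offset:12.4f}")
        lines.append(f"{'Average':>8}  {self.average:8.4f}")
        return "\n".join(lines)


def evaluate_model(
    model: CAN,
    records: Sequence[DatasetRecord],
    ablation: str = "none",
    n_offsets: int = 360,
) -> EvalTable:
    """Per-case offset-invariant SSIM of model predictions vs labels."""
    if ablation not in _ABLATION_CHANNEL:
        raise ValueError(f"ablation must be one of {sorted(_ABLATION_CHANNEL)}")
    rows = []
    for rec in records:
        x = np.asarray(rec.inputs, dtype=np.float32)
        ch = _ABLATION_CHANNEL[ablation]
        if ch is not None:
            x = ablate_channel(x, ch)
        pred = predict(model, x)
        s, off = ssim_phase(pred, rec.label, n_offsets=n_offsets)
        rows.append(EvalResult(rec.params.case_id, s, off, rec.variant, ablation))
    return EvalTable(tuple(rows))


def compare_vz(
    field: BFPField,
    recovered_quadrant: np.ndarray,
    z_um: np.ndarray,
    pupil_weight: np.ndarray | None = None,
) -> tuple[VzCurve, VzCurve, float]:
    """V(z) curves from the true field and from a recovered quadrant phase.

    The recovered quadrant is mirrored back to the full pupil, a surrogate
    field |Ex| e^{i phi} is formed, and both |V(z)| curves (max-normalized)
    are returned with their maximum absolute discrepancy.
    """
    phi = reconstruct_from_quadrant(np.asarray(recovered_quadrant, dtype=float))
    if phi.shape != field.Ex.shape:
        raise ValueError("recovered quadrant does not match the pupil size")
    surrogate_ex = np.where(field.grid.mask, np.abs(field.Ex) * np.exp(1j * phi), 0.0)
    surrogate = BFPField(surrogate_ex, np.zeros_like(surrogate_ex), field.grid)
    v_theory = vz_signal(field, z_um, pupil_weight)
    v_rec = vz_signal(surrogate, z_um, pupil_weight)
    disc = float(np.max(np.abs(v_theory.magnitude() - v_rec.magnitude())))
    return v_theory, v_rec, disc
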