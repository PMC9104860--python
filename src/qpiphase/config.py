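"""Run configuration, presets, and end-to-end pipeline orchestration.

A :class:`RunConfig` captures everything needed to reproduce a run:
sample family, network variant, pupil geometry, dataset sizes, defocus
planes, training settings and seeds.  ``run_pipeline`` executes
simulate -> dataset -> split -> train -> evaluate and writes its
artifacts (dataset, checkpoint, evaluation CSV, JSON manifest with the
resolved config and a config hash) into the output directory.

Presets: ``spr-paper`` / ``waveguide-paper`` use the full-scale settings
(512-pixel pupil, M = 64, 1000 records, 100 epochs, learning rate 1e-4);
``spr-desk`` / ``waveguide-desk`` are CPU-scale profiles (128-pixel pupil
-> 64x64 inputs, M = 8, 200 records, 30 epochs, learning rate 1e-3).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .can import CAN, CANConfig, TrainConfig, build_can, train
from .datasets import (DEFAULT_Z_LISTS, N_CHANNELS, assemble_record,
                       make_test_set, sample_parameters, save_dataset,
                       split_dataset)
from .evaluation import EvalTable, evaluate_model
from .pupil import build_pupil_grid

__all__ = ["RunConfig", "PRESETS", "load_config", "run_pipeline", "simulate_case"]


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run."""

    sample_type: Literal["spr", "waveguide"] = "spr"
    variant: Literal["CAN1", "CAN2", "CAN3", "CAN4", "CAN5"] = "CAN1"
    n_pixels: int = Field(512, ge=16)
    na: float = Field(1.49, gt=0)
    n0: float = Field(1.52, gt=0)
    n_records: int = Field(1000, ge=2)
    split_fraction: float = Field(0.9, gt=0, lt=1)
    z_list: list[float] | None = None
    features: int = Field(64, ge=1)
    epochs: int = Field(100, ge=1)
    learning_rate: float = Field(1e-4, gt=0)
    seed: int = 0
    normalize_bfp: bool = False
    imp_amplitude: bool = False
    n_offsets: int = Field(360, ge=2)
    save_dataset_file: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.na >= self.n0:
            raise ValueError("NA must be < n0")
        if self.n_pixels % 2:
            raise ValueError("n_pixels must be even")
        return self

    @property
    def resolved_z_list(self) -> tuple[float, ...]:
        if self.z_list is None:
            return DEFAULT_Z_LISTS[self.variant]
        return tuple(self.z_list)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


PRESETS: dict[str, dict] = {
    "spr-paper": dict(sample_type="spr", n_pixels=512, features=64,
                      n_records=1000, epochs=100, learning_rate=1e-4),
    "waveguide-paper": dict(sample_type="waveguide", n_pixels=512, features=64,
                            n_records=1000, epochs=100, learning_rate=1e-4),
    "spr-desk": dict(sample_type="spr", n_pixels=128, features=8,
                     n_records=200, epochs=30, learning_rate=1e-3),
    "waveguide-desk": dict(sample_type="waveguide", n_pixels=128, features=8,
                           n_records=200, epochs=30, learning_rate=1e-3),
}


def load_config(path=None, preset: str | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file and/or a named preset."""
    data: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
        data.update(PRESETS[preset])
    if path is not None:
        with open(path) as fh:
            data.update(yaml.safe_load(fh) or {})
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def build_records(cfg: RunConfig, params_list):
    grid = build_pupil_grid(cfg.n_pixels, cfg.na, 633.0, cfg.n0)
    return [
        assemble_record(p, cfg.variant, cfg.resolved_z_list, grid,
                        normalize_bfp=cfg.normalize_bfp,
                        imp_amplitude=cfg.imp_amplitude)
        for p in params_list
    ]


def run_pipeline(cfg: RunConfig, out_dir, verbose: bool = False) -> EvalTable:
    """Dataset generation -> training -> test-case evaluation.

    Writes model checkpoint, evaluation CSV (plus ablation CSVs for
    two-channel variants), and a JSON run manifest into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.model_dump(), "config_hash": cfg.config_hash(),
                      "stages": {}}

    t0 = time.time()
    params_list = sample_parameters(cfg.sample_type, cfg.n_records, cfg.seed)
    records = build_records(cfg, params_list)
    split = split_dataset(records, cfg.split_fraction, seed=cfg.seed + 1)
    if cfg.save_dataset_file:
        save_dataset(records, out / "dataset.h5", config=cfg.model_dump())
    manifest["stages"]["dataset"] = {"seconds": round(time.time() - t0, 2),
                                     "n_train": len(split.train),
                                     "n_validation": len(split.validation)}

    t0 = time.time()
    model = build_can(
        CANConfig(input_channels=N_CHANNELS[cfg.variant], features=cfg.features,
                  input_size=cfg.n_pixels // 2),
        seed=cfg.seed + 2)
    tc = TrainConfig(learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                     seed=cfg.seed + 3)
    train(model, split, tc, verbose=verbose)
    model.save(out / "model")
    manifest["stages"]["train"] = {
        "seconds": round(time.time() - t0, 2),
        "final_train_loss": model.history["train_loss"][-1],
        "final_val_loss": (model.history["val_loss"][-1]
                           if model.history["val_loss"] else None)}

    t0 = time.time()
    test_records = build_records(cfg, make_test_set(cfg.sample_type))
    table = evaluate_model(model, test_records, n_offsets=cfg.n_offsets)
    table.to_csv(out / "evaluation.csv")
    manifest["stages"]["evaluate"] = {"seconds": round(time.time() - t0, 2),
                                      "average_ssim": table.average}
    if N_CHANNELS[cfg.variant] >= 2:
        for ab in ("bfp_off", "imp_off"):
            t = evaluate_model(model, test_records, ablation=ab,
                               n_offsets=cfg.n_offsets)
            t.to_csv(out / f"evaluation_{ab}.csv")
            manifest["stages"][f"evaluate_{ab}"] = {"average_ssim": t.average}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return table


def simulate_case(cfg: RunConfig, params, z_list=None):
    """BFP intensity, Ex phase, and IMP intensities for one parameter set."""
    from .imaging import imp_intensity, propagate_defocus
    from .pupil import bfp_intensity, bfp_phase, compute_bfp_fields

    grid = build_pupil_grid(cfg.n_pixels, cfg.na, params.wavelength_nm, cfg.n0)
    field = compute_bfp_fields(grid, params.to_layer_stack(n0=cfg.n0))
    z_list = cfg.resolved_z_list if z_list is None else tuple(z_list)
    imps = {z: imp_intensity(propagate_defocus(field, z)) for z in z_list}
    return {"bfp_intensity": bfp_intensity(field),
            "ex_phase": bfp_phase(field, "x"),
            "imp": imps,
            "field": field}
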