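"""Configuration loading and HDF5 persistence of simulation results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .mc_engine import SimulationResult
from .optics import OpticalProperties

__all__ = ["load_config", "save_result", "load_result_summary", "props_from_config"]


def load_config(path) -> dict:
    """Read a YAML (or JSON) run configuration."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg


def props_from_config(entry: dict) -> OpticalProperties:
    """Material entry: {mu_a, mu_s_reduced, g, unit: cm|mm}."""
    return OpticalProperties(
        mu_a=float(entry["mu_a"]),
        mu_s_reduced=float(entry["mu_s_reduced"]),
        g=float(entry["g"]),
        unit=entry.get("unit", "cm"),
    )


def save_result(result: SimulationResult, path, config_echo: dict | None = None,
                projected_map: np.ndarray | None = None):
    """Persist a simulation result (fluence, paths, ledger, provenance) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("voxel_labels", data=result.scene.voxel_labels,
                          compression="gzip")
        h5.create_dataset("fluence", data=result.fluence, compression="gzip")
        h5.create_dataset("paths", data=result.paths, compression="gzip")
        h5.create_dataset("path_offsets", data=result.path_offsets)
        h5.create_dataset("record_info", data=result.record_info)
        if projected_map is not None:
            h5.create_dataset("projected_map", data=projected_map, compression="gzip")
        h5.attrs["n_launched"] = result.n_launched
        h5.attrs["n_detected"] = result.n_detected
        h5.attrs["seed"] = result.seed
        h5.attrs["voxel_size_mm"] = result.scene.voxel_size
        h5.attrs["tip_apex_depth_mm"] = result.scene.tip_apex_depth
        h5.attrs["ledger"] = json.dumps(result.ledger)
        meta = {k: v for k, v in result.scene.meta.items() if not k.startswith("_")}
        h5.attrs["scene_meta"] = json.dumps(meta)
        if config_echo is not None:
            h5.attrs["config"] = json.dumps(config_echo)


def load_result_summary(path) -> dict:
    """Read back the scalar summary of a persisted result (no path arrays)."""
    with h5py.File(path, "r") as h5:
        return {
            "n_launched": int(h5.attrs["n_launched"]),
            "n_detected": int(h5.attrs["n_detected"]),
            "seed": int(h5.attrs["seed"]),
            "voxel_size_mm": float(h5.attrs["voxel_size_mm"]),
            "tip_apex_depth_mm": float(h5.attrs["tip_apex_depth_mm"]),
            "ledger": json.loads(h5.attrs["ledger"]),
            "scene_meta": json.loads(h5.attrs["scene_meta"]),
            "fluence_shape": tuple(h5["fluence"].shape),
        }
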