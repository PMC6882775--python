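"""Sidecar persistence for simulator configs and ground truth.

Configs round-trip through YAML; ground truth through JSON (scalar and
per-breath/per-frame fields only — full-rate traces are regenerable from
the config and seed and are not serialized).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .breathing import GroundTruth, SimConfig
from .phantom import PhantomConfig

__all__ = [
    "save_config_yaml",
    "load_config_yaml",
    "save_ground_truth_json",
    "load_ground_truth_json",
]

_GT_FIELDS = (
    "peep", "rr", "breath_start_t", "breath_insp_end_t", "breath_end_t",
    "tv", "pmus_amp", "peak_flow", "ptp_max",
    "frame_t_true", "frame_non_aerated_ml", "breath_rd_ml",
    "ct_lag", "lung_volume_ml",
)


def _tupleize(obj):
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config_yaml(path: str | Path, sim: SimConfig | None = None,
                     phantom: PhantomConfig | None = None) -> None:
    doc = {}
    if sim is not None:
        doc["sim"] = {k: _tupleize(v) for k, v in dataclasses.asdict(sim).items()}
    if phantom is not None:
        doc["phantom"] = {k: _tupleize(v) for k, v in dataclasses.asdict(phantom).items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config_yaml(path: str | Path) -> tuple[SimConfig | None, PhantomConfig | None]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = phantom = None
    if "sim" in doc:
        d = dict(doc["sim"])
        sim = SimConfig(**d)
    if "phantom" in doc:
        d = dict(doc["phantom"])
        for key in ("grid_shape", "pixel_size", "opening_pressure_dist",
                    "closing_pressure_dist"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        phantom = PhantomConfig(**d)
    return sim, phantom


def save_ground_truth_json(path: str | Path, gt: GroundTruth) -> None:
    doc = {}
    for name in _GT_FIELDS:
        val = getattr(gt, name)
        if val is None:
            continue
        if isinstance(val, np.ndarray):
            doc[name] = val.tolist()
        else:
            doc[name] = float(val)
    Path(path).write_text(json.dumps(doc, indent=1))


def load_ground_truth_json(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    gt = GroundTruth()
    for name, val in doc.items():
        if isinstance(val, list):
            setattr(gt, name, np.asarray(val, dtype=float))
        else:
            setattr(gt, name, val)
    return gt
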