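"""Quantitative-CT lung aeration: Hounsfield-unit compartments per slice.

A masked HU slice is decomposed into the four classical aeration
compartments — non-inflated [-100, +100] HU, poorly inflated [-500, -100),
normally inflated [-900, -500), hyperinflated [-1000, -900) — and into
physical totals using the linear gas/tissue mixing model:

    density (g/ml) = (HU + 1000) / 1000, clamped to [0, 1.1]
    gas fraction   = -HU / 1000,         clamped to [0, 1]

Boundary values shared by two printed ranges are assigned half-open
downward (to the denser band), which is conservative for atelectasis.
In-mask HU outside [-1000, +100] are clamped and counted, not dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CtFrame",
    "LungMask",
    "AerationProfile",
    "COMPARTMENTS",
    "LABEL_CODES",
    "classify_voxels",
    "compute_aeration_profile",
    "read_tiff_frames",
    "write_tiff_frames",
    "read_dicom_series",
    "read_mask",
]

COMPARTMENTS = ("non", "poor", "normal", "hyper")
#: integer label codes used by :func:`classify_voxels`
LABEL_CODES = {"excluded": -1, "non": 0, "poor": 1, "normal": 2, "hyper": 3}

HU_MIN, HU_MAX = -1000.0, 100.0
_BAND_EDGES = np.array([-900.0, -500.0, -100.0])  # half-open downward


@dataclass
class CtFrame:
    """One HU slice: 2-D attenuation matrix plus voxel geometry."""

    attenuation: np.ndarray           # HU
    pixel_size: tuple[float, float] = (0.5, 0.5)  # mm
    slice_thickness: float = 5.0      # mm
    timestamp: float = 0.0            # s

    def __post_init__(self) -> None:
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        if self.attenuation.ndim != 2:
            raise ValueError("attenuation must be a 2-D matrix")
        if not np.all(np.isfinite(self.attenuation)):
            raise ValueError("attenuation contains non-finite values")
        if self.voxel_volume_ml <= 0:
            raise ValueError("voxel volume must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        # mm^3 -> ml
        return self.pixel_size[0] * self.pixel_size[1] * self.slice_thickness / 1000.0


@dataclass
class LungMask:
    """Binary region of interest congruent with the frames it applies to."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D matrix")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class AerationProfile:
    """Four-compartment decomposition of one masked slice.

    ``voxel_count``/``volume_ml``/``weight_g`` map compartment name to its
    value; totals are sums over compartments by construction, so the
    conservation invariants hold exactly.
    """

    voxel_count: dict[str, int]
    volume_ml: dict[str, float]
    weight_g: dict[str, float]
    lung_volume_ml: float
    tissue_weight_g: float
    gas_volume_ml: float
    timestamp: float = 0.0
    n_clamped: int = 0

    @property
    def non_aerated_ml(self) -> float:
        return self.volume_ml["non"]

    @property
    def non_aerated_g(self) -> float:
        return self.weight_g["non"]

    def as_row(self) -> dict:
        row = {"timestamp": self.timestamp,
               "lung_volume_ml": self.lung_volume_ml,
               "tissue_weight_g": self.tissue_weight_g,
               "gas_volume_ml": self.gas_volume_ml,
               "n_clamped": self.n_clamped}
        for c in COMPARTMENTS:
            row[f"{c}_count"] = self.voxel_count[c]
            row[f"{c}_ml"] = self.volume_ml[c]
            row[f"{c}_g"] = self.weight_g[c]
        return row


def _clamped_hu(frame: CtFrame, mask: LungMask) -> tuple[np.ndarray, int]:
    if frame.attenuation.shape != mask.mask.shape:
        raise ValueError("frame and mask shapes differ")
    hu = frame.attenuation[mask.mask]
    n_out = int(np.count_nonzero((hu < HU_MIN) | (hu > HU_MAX)))
    if n_out:
        logger.warning("%d in-mask voxels outside [%g, %g] HU were clamped",
                       n_out, HU_MIN, HU_MAX)
    return np.clip(hu, HU_MIN, HU_MAX), n_out


def classify_voxels(frame: CtFrame, mask: LungMask) -> np.ndarray:
    """Label every pixel with its aeration compartment.

    Returns an integer matrix using :data:`LABEL_CODES`; off-mask pixels are
    ``excluded`` (-1).  Band ownership of the shared printed boundaries:
    -100 HU -> non, -500 HU -> poor, -900 HU -> normal.
    """
    hu, _ = _clamped_hu(frame, mask)
    # digitize against ascending edges: 0: hyper, 1: normal, 2: poor, 3: non
    bins = np.digitize(hu, _BAND_EDGES, right=False)
    codes = np.array([LABEL_CODES["hyper"], LABEL_CODES["normal"],
                      LABEL_CODES["poor"], LABEL_CODES["non"]])
    labels = np.full(frame.attenuation.shape, LABEL_CODES["excluded"], dtype=np.int8)
    labels[mask.mask] = codes[bins]
    return labels


def compute_aeration_profile(frame: CtFrame, mask: LungMask) -> AerationProfile:
    """Compartment volumes/weights and slice totals from one masked frame."""
    hu, n_clamped = _clamped_hu(frame, mask)
    labels = classify_voxels(frame, mask)[mask.mask]
    vox = frame.voxel_volume_ml
    density = np.clip((hu + 1000.0) / 1000.0, 0.0, 1.1)     # g/ml
    gas_frac = np.clip(-hu / 1000.0, 0.0, 1.0)

    counts: dict[str, int] = {}
    vols: dict[str, float] = {}
    wts: dict[str, float] = {}
    for name in COMPARTMENTS:
        sel = labels == LABEL_CODES[name]
        counts[name] = int(np.count_nonzero(sel))
        vols[name] = counts[name] * vox
        wts[name] = float(np.sum(density[sel])) * vox
    return AerationProfile(
        voxel_count=counts,
        volume_ml=vols,
        weight_g=wts,
        lung_volume_ml=sum(vols.values()),
        tissue_weight_g=sum(wts.values()),
        gas_volume_ml=float(np.sum(gas_frac)) * vox,
        timestamp=frame.timestamp,
        n_clamped=n_clamped,
    )


def profiles_to_table(profiles: list[AerationProfile]) -> pd.DataFrame:
    """One row per frame; columns per compartment plus totals."""
    return pd.DataFrame([p.as_row() for p in profiles])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_tiff_frames(
    path: str | Path,
    frames: list[CtFrame],
    hu_offset: int = 1024,
) -> None:
    """Write frames as a multi-page uint16 TIFF storing ``HU + hu_offset``.

    A YAML sidecar ``<path>.yaml`` records the offset, voxel geometry and
    per-frame timestamps so the stack is self-describing.
    """
    import tifffile
    import yaml

    stack = np.stack([f.attenuation for f in frames]).astype(np.int32) + hu_offset
    if stack.min() < 0 or stack.max() > np.iinfo(np.uint16).max:
        raise ValueError("HU values do not fit uint16 with this offset")
    tifffile.imwrite(str(path), stack.astype(np.uint16), photometric="minisblack")
    meta = {
        "hu_offset": hu_offset,
        "pixel_size_mm": list(frames[0].pixel_size),
        "slice_thickness_mm": frames[0].slice_thickness,
        "timestamps_s": [float(f.timestamp) for f in frames],
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta))


def read_tiff_frames(path: str | Path) -> list[CtFrame]:
    """Read a multi-page TIFF written by :func:`write_tiff_frames`."""
    import tifffile
    import yaml

    meta = yaml.safe_load(Path(str(path) + ".yaml").read_text())
    stack = tifffile.imread(str(path)).astype(float) - meta["hu_offset"]
    if stack.ndim == 2:
        stack = stack[None]
    ts = meta.get("timestamps_s") or [0.0] * len(stack)
    return [
        CtFrame(
            attenuation=img,
            pixel_size=tuple(meta["pixel_size_mm"]),
            slice_thickness=meta["slice_thickness_mm"],
            timestamp=ts[i],
        )
        for i, img in enumerate(stack)
    ]


def read_dicom_series(paths: list[str | Path]) -> list[CtFrame]:
    """Read a DICOM series into HU frames (RescaleSlope/Intercept applied).

    Frames are ordered by acquisition/instance number; timestamps are taken
    from AcquisitionTime when present (seconds past midnight), else 0.
    """
    import pydicom

    dsets = [pydicom.dcmread(str(p)) for p in paths]
    dsets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = []
    for d in dsets:
        hu = d.pixel_array.astype(float) * float(getattr(d, "RescaleSlope", 1.0)) + \
            float(getattr(d, "RescaleIntercept", 0.0))
        px = getattr(d, "PixelSpacing", [0.5, 0.5])
        tstr = str(getattr(d, "AcquisitionTime", "") or "")
        ts = 0.0
        if tstr:
            ts = int(tstr[0:2]) * 3600 + int(tstr[2:4]) * 60 + float(tstr[4:])
        frames.append(CtFrame(
            attenuation=hu,
            pixel_size=(float(px[0]), float(px[1])),
            slice_thickness=float(getattr(d, "SliceThickness", 5.0)),
            timestamp=ts,
        ))
    return frames


def read_mask(path: str | Path) -> LungMask:
    """Read a 0/1 mask from a single-page TIFF or PNG."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return LungMask(mask=arr > 0)
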