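"""Alignment of the CT frame clock with the spirometry clock.

The slice gas content computed from the dynamic CT frames breathes with the
subject, so it is a surrogate volume signal.  Cross-correlating it (linearly
interpolated to the 200 Hz spirometry grid) against the integrated airway
flow yields the clock offset between the two acquisition systems; the peak
normalized correlation doubles as an alignment quality score.  With the
clocks aligned, the end-inspiratory and end-expiratory frame of each breath
are selected by nearest timestamp to the breath's spirometric phase
landmarks (an extremal-gas-content alternative is available for sensitivity
analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ct_aeration import CtFrame, LungMask, HU_MIN, HU_MAX
from .resp_mechanics import Breath, WaveformSet

logger = logging.getLogger(__name__)

__all__ = ["SyncMap", "BreathFramePair", "ct_gas_series", "synchronize",
           "select_breath_frames"]


@dataclass
class SyncMap:
    """Clock alignment: add ``offset`` to CT timestamps to land on the
    spirometry timebase; ``quality`` is the peak normalized cross-correlation."""

    offset: float   # s
    quality: float  # in [-1, 1]
    reliable: bool  # quality >= threshold


@dataclass
class BreathFramePair:
    breath_id: int
    ee_frame_idx: int   # end-expiratory frame
    ei_frame_idx: int   # end-inspiratory frame
    ee_time: float      # s, offset-corrected timestamps
    ei_time: float

    def __post_init__(self) -> None:
        if self.ee_frame_idx == self.ei_frame_idx:
            raise ValueError("end-expiratory and end-inspiratory frames coincide")


def ct_gas_series(
    frames: list[CtFrame], mask: LungMask
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame slice gas volume (ml) at the frames' own timestamps.

    Uses the same linear mixing model as the aeration profiles
    (gas fraction = -HU/1000 on the clamped HU), so the series equals the
    ``gas_volume_ml`` of :func:`peeprd.ct_aeration.compute_aeration_profile`
    frame by frame.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    m = mask.mask
    if not m.any():
        raise ValueError("mask is empty")
    vox = frames[0].voxel_volume_ml
    t = np.array([f.timestamp for f in frames])
    gas = np.empty(len(frames))
    for i, f in enumerate(frames):
        hu = np.clip(f.attenuation[m], HU_MIN, HU_MAX)
        gas[i] = float(np.sum(np.clip(-hu / 1000.0, 0.0, 1.0))) * vox
    return t, gas


def synchronize(
    ct_t: np.ndarray,
    gas_ml: np.ndarray,
    t: np.ndarray,
    volume: np.ndarray,
    max_lag: float = 2.0,
    quality_min: float = 0.5,
) -> SyncMap:
    """Find the CT-clock offset by normalized cross-correlation.

    The CT gas series is linearly interpolated onto the spirometry grid and
    correlated against the (demeaned) spirometric volume over lags up to
    ``max_lag`` (default 2 s — acquisition-clock offsets are sub-second;
    a wide search window risks locking onto a breath-period alias when
    breathing is very regular; pass ``None`` for half the overlap).  The
    normalization uses exact per-lag overlap norms, so the quality score is
    a true correlation coefficient.
    """
    ct_t = np.asarray(ct_t, float)
    gas_ml = np.asarray(gas_ml, float)
    t = np.asarray(t, float)
    volume = np.asarray(volume, float)
    if np.std(gas_ml) == 0 or np.std(volume) == 0:
        raise ValueError("degenerate (constant) series cannot be synchronized")

    dt = t[1] - t[0]
    # restrict to samples where the interpolated gas series is defined
    k0 = int(np.searchsorted(t, ct_t[0]))
    k1 = int(np.searchsorted(t, ct_t[-1], side="right"))
    if k1 - k0 < 10:
        raise ValueError("CT and spirometry records barely overlap")
    y = np.interp(t[k0:k1], ct_t, gas_ml)
    x = volume[k0:k1]
    n = x.size
    x = x - x.mean()
    y = y - y.mean()
    if max_lag is None:
        max_lag = 0.5 * n * dt
    mmax = min(int(round(max_lag / dt)), n - 2)

    # corr(m) = sum_k y[k] x[k+m] / (||x over overlap|| * ||y over overlap||)
    from scipy.signal import correlate

    c = correlate(x, y, mode="full", method="fft")  # c[i], lag m = i - (n-1)
    lags = np.arange(-mmax, mmax + 1)
    cs_x2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cs_y2 = np.concatenate([[0.0], np.cumsum(y * y)])
    corr = np.empty(lags.size)
    for j, m in enumerate(lags):
        num = c[m + n - 1]
        if m >= 0:
            nx = cs_x2[n] - cs_x2[m]
            ny = cs_y2[n - m]
        else:
            nx = cs_x2[n + m]
            ny = cs_y2[n] - cs_y2[-m]
        den = np.sqrt(nx * ny)
        corr[j] = num / den if den > 0 else 0.0
    # near-periodic breathing yields period-aliased peaks of almost equal
    # height; among near-maximal peaks prefer the smallest clock offset
    c_max = float(np.max(corr))
    near = np.flatnonzero(corr >= 0.995 * c_max) if c_max > 0 else np.array([int(np.argmax(corr))])
    j_best = int(near[np.argmin(np.abs(lags[near]))])
    offset = float(lags[j_best] * dt)
    quality = float(corr[j_best])
    reliable = quality >= quality_min
    if not reliable:
        logger.warning("synchronize: low alignment quality %.3f", quality)
    return SyncMap(offset=offset, quality=quality, reliable=reliable)


def select_breath_frames(
    sync: SyncMap,
    breaths: list[Breath],
    frames: list[CtFrame],
    waves: WaveformSet,
    mask: LungMask | None = None,
    method: str = "nearest-time",
) -> list[BreathFramePair]:
    """Pick the end-inspiratory and end-expiratory frame of each breath.

    ``nearest-time`` (default): the frames whose offset-corrected timestamps
    are nearest the breath's inspiratory end and breath end.  ``extremal-gas``:
    the frames of maximal/minimal slice gas content within the breath
    (requires ``mask``); robust when tidal R/D makes gas content non-monotone.
    Breaths without two distinct frames inside their span are skipped.
    """
    tau = np.array([f.timestamp for f in frames]) + sync.offset
    half_frame = 0.5 * float(np.median(np.diff(tau))) if len(tau) > 1 else 0.0
    if method == "extremal-gas":
        if mask is None:
            raise ValueError("extremal-gas selection requires the lung mask")
        _, gas = ct_gas_series(frames, mask)
    pairs: list[BreathFramePair] = []
    n_skipped = 0
    for i, b in enumerate(breaths):
        t0 = waves.t[b.start_idx]
        t_ie = waves.t[b.insp_end_idx]
        t1 = waves.t[b.end_idx]
        in_span = np.flatnonzero((tau >= t0 - half_frame) & (tau <= t1 + half_frame))
        if in_span.size < 2:
            n_skipped += 1
            continue
        if method == "nearest-time":
            ei = in_span[np.argmin(np.abs(tau[in_span] - t_ie))]
            ee = in_span[np.argmin(np.abs(tau[in_span] - t1))]
        elif method == "extremal-gas":
            ei = in_span[np.argmax(gas[in_span])]
            ee = in_span[np.argmin(gas[in_span])]
        else:
            raise ValueError(f"unknown frame-selection method {method!r}")
        if ee == ei:
            n_skipped += 1
            continue
        pairs.append(BreathFramePair(
            breath_id=i, ee_frame_idx=int(ee), ei_frame_idx=int(ei),
            ee_time=float(tau[ee]), ei_time=float(tau[ei]),
        ))
    if n_skipped:
        logger.info("select_breath_frames: skipped %d breaths without usable frames",
                    n_skipped)
    return pairs
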