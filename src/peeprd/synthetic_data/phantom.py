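"""Dynamic CT lung phantom with per-region opening/closing pressures.

A 2-D slice of lung pixels (elliptical mask, 0.5 x 0.5 mm pixels, 5 mm
thickness) is imaged at 20 Hz while the breathing simulator runs.  A
configurable fraction of lung pixels is *recruitable*: each carries an
opening pressure and a (lower) closing pressure and follows a hysteresis
rule against the regional recruiting pressure

    P_r(t) = PEEP + Ers * V(t) + Rrs * max(flow(t), 0),

i.e. the elastic transpulmonary distension plus the inspiratory resistive
pressure acting on closed units during inflation; during expiration the
floor is the elastic recoil, so P_r returns to PEEP at end-expiration.  A
closed pixel renders at the collapsed-tissue attenuation (default -20 HU);
an open or non-recruitable pixel renders at an attenuation tracking its
instantaneous regional gas content.  Rapid shallow breathing at low PEEP
produces a large tidal excursion of P_r, so cyclic recruitment/
derecruitment (R/D) is largest at PEEP 0 and vanishes as PEEP stabilizes
the recruitable regions — the behaviour the downstream statistics probe.

Pixel states are evolved at the waveform sampling rate, so hysteresis is
resolved much finer than the frame clock.  Emitted frame timestamps are
shifted by ``ct_lag`` to emulate an unsynchronized CT clock; the ground
truth records per-frame non-aerated volume and per-breath R/D on the true
(spirometry) clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ..ct_aeration import CtFrame, LungMask
from ..resp_mechanics import WaveformSet, detect_breaths
from .breathing import GroundTruth

logger = logging.getLogger(__name__)

__all__ = ["PhantomConfig", "simulate_ct_sequence"]


@dataclass
class PhantomConfig:
    """Geometry, recruitment behaviour and rendering of the CT phantom."""

    grid_shape: tuple[int, int] = (96, 96)
    pixel_size: tuple[float, float] = (0.5, 0.5)    # mm
    slice_thickness: float = 5.0                    # mm
    recruitable_fraction: float = 0.5               # of lung pixels
    opening_pressure_dist: tuple[float, float] = (8.0, 6.0)   # mean, sd cmH2O (lognormal)
    closing_pressure_dist: tuple[float, float] = (4.0, 6.0)   # mean, sd cmH2O (lognormal)
    hu_nonaerated: float = -20.0                    # HU of collapsed tissue
    hu_gas_gain: float = 980.0                      # HU decrease per unit gas content
    frame_rate: float = 20.0                        # Hz
    duration: float = 100.0                         # s of acquisition
    ct_lag: float = 0.35                            # s added to emitted timestamps
    hu_noise_sd: float = 12.0                       # HU, truncated at 3 sd
    gas_frac_base: float = 0.45                     # aerated-pixel gas content at V=0
    gas_frac_spread: float = 0.05                   # per-pixel sd of the base
    gas_frac_per_peep: float = 0.012                # gas content gain per cmH2O PEEP
    gas_frac_per_l: float = 0.30                    # gas content gain per L of volume
    gas_frac_recruited: float = 0.30                # base gas content of open recruitable px
    background_hu: float = 60.0                     # outside the lung mask
    fixed_toggle_fraction: float | None = None      # program an exact tidal R/D fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")
        if not 0 <= self.recruitable_fraction <= 1:
            raise ValueError("recruitable_fraction must be in [0, 1]")

    @property
    def voxel_volume_ml(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1] * self.slice_thickness / 1000.0

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration))


def _lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and sd."""
    if mean <= 0:
        raise ValueError("threshold-pressure mean must be positive")
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    a, b = 0.42 * rows, 0.36 * cols
    return ((rr - (rows - 1) / 2) / a) ** 2 + ((cc - (cols - 1) / 2) / b) ** 2 <= 1.0


def _recruit_pressure_estimate(waves: WaveformSet) -> tuple[np.ndarray, float]:
    """Fallback recruiting pressure from the measured channels alone."""
    peep = float(np.median(waves.pao))
    ptp = waves.pao - waves.peso
    base = float(np.percentile(ptp, 5))
    return peep + np.clip(ptp - base, 0.0, None), peep


def _evolve_states(
    p: np.ndarray,
    p_open: np.ndarray,
    p_close: np.ndarray,
    record_at: np.ndarray,
) -> np.ndarray:
    """Hysteresis state machine; returns open-state snapshots at ``record_at``.

    Pixels start closed; a pixel opens when P >= its opening pressure and
    closes when P <= its closing pressure.
    """
    open_state = np.zeros(p_open.shape, dtype=bool)
    snaps = np.empty((record_at.size, p_open.size), dtype=bool)
    rec_pos = 0
    rec_sorted = np.argsort(record_at, kind="stable")
    rec_idx = record_at[rec_sorted]
    for i in range(p.size):
        pi = p[i]
        open_state |= pi >= p_open
        open_state &= pi > p_close
        while rec_pos < rec_idx.size and rec_idx[rec_pos] == i:
            snaps[rec_sorted[rec_pos]] = open_state
            rec_pos += 1
    if rec_pos != rec_idx.size:
        raise ValueError("record indices beyond pressure series")
    return snaps


def simulate_ct_sequence(
    pcfg: PhantomConfig,
    waves: WaveformSet,
    gt: GroundTruth | None = None,
) -> tuple[list[CtFrame], LungMask, GroundTruth]:
    """Render the dynamic CT acquisition for one PEEP step.

    When the breathing simulator's ground truth is supplied, the phantom is
    driven by the noise-free recruiting pressure and volume and the breath
    boundaries it carries; otherwise both are estimated from the waveforms.
    Returns the frames (timestamps shifted by ``ct_lag``), the lung mask and
    a ground truth carrying per-frame non-aerated volume and per-breath R/D.
    """
    if waves.duration + 1.0 / waves.fs < pcfg.duration:
        raise ValueError(
            f"waveform record ({waves.duration:.1f} s) shorter than the CT "
            f"acquisition ({pcfg.duration} s)"
        )
    rng = np.random.default_rng(pcfg.seed)
    mask_arr = _ellipse_mask(pcfg.grid_shape)
    mask = LungMask(mask=mask_arr)
    n_lung = mask.n_pixels
    vox = pcfg.voxel_volume_ml

    if gt is not None and gt.recruit_pressure is not None:
        p_r = gt.recruit_pressure
        peep = float(gt.peep)
        volume = gt.clean["volume"]
    else:
        p_r, peep = _recruit_pressure_estimate(waves)
        volume = waves.volume
        if volume is None:
            from ..resp_mechanics import integrate_volume

            volume = integrate_volume(waves.flow, t=waves.t)

    # breath boundaries (true clock) for ground-truth R/D
    if gt is not None and gt.breath_start_t is not None:
        b_start, b_ie, b_end = gt.breath_start_t, gt.breath_insp_end_t, gt.breath_end_t
    else:
        det = detect_breaths(waves)
        b_start = np.array([waves.t[b.start_idx] for b in det])
        b_ie = np.array([waves.t[b.insp_end_idx] for b in det])
        b_end = np.array([waves.t[b.end_idx] for b in det])

    # recruitable pixels and their thresholds
    lung_idx = np.flatnonzero(mask_arr.ravel())
    if pcfg.fixed_toggle_fraction is not None:
        n_rec = int(round(pcfg.fixed_toggle_fraction * n_lung))
    else:
        n_rec = int(round(pcfg.recruitable_fraction * n_lung))
    rec_sel = rng.choice(lung_idx, size=n_rec, replace=False) if n_rec else np.array([], int)

    n_wave = min(int(round(pcfg.duration * waves.fs)) + 1, waves.t.size)
    p_series = p_r[:n_wave]

    if pcfg.fixed_toggle_fraction is not None:
        # program every recruitable pixel to toggle exactly once per breath:
        # thresholds placed inside the excursion band common to all breaths
        in_win = b_end <= waves.t[n_wave - 1]
        peaks, troughs, p_ies = [], [], []
        for s, ie, e in zip(b_start[in_win], b_ie[in_win], b_end[in_win]):
            i0, i1 = np.searchsorted(waves.t, [s, e])
            peaks.append(np.max(p_series[i0:i1 + 1]))
            troughs.append(np.min(p_series[i0:i1 + 1]))
            p_ies.append(p_series[min(int(round(ie * waves.fs)), n_wave - 1)])
        lo, hi = float(np.max(troughs)), float(np.min(peaks))
        p_ie_min = float(np.min(p_ies))
        if hi <= lo or p_ie_min <= lo:
            raise ValueError("breaths have no common pressure excursion band")
        # close above the floor but below every end-inspiratory pressure, so
        # each region is open at end-inspiration and closed at end-expiration
        close = lo + 0.5 * (p_ie_min - lo)
        p_close = np.full(n_rec, close)
        p_open = np.full(n_rec, close + 0.5 * (hi - close))
    else:
        # lognormal opening/closing pressures (moment-matched to the given
        # mean/sd): peaked at low pressure with a heavy right tail, the
        # distribution shape reported for airway opening pressures in
        # surfactant-depleted lungs; the tail keeps a little R/D alive at
        # high PEEP while most units stabilize early
        p_open = _lognormal(rng, *pcfg.opening_pressure_dist, n_rec)
        p_close = np.maximum(
            np.minimum(_lognormal(rng, *pcfg.closing_pressure_dist, n_rec),
                       p_open - 0.1),
            0.01,
        )

    # pixel-state snapshots at every frame time (true clock)
    frame_t_true = np.arange(pcfg.n_frames) / pcfg.frame_rate
    frame_idx = np.clip(np.round(frame_t_true * waves.fs).astype(int), 0, n_wave - 1)
    nf = pcfg.n_frames
    frame_open = _evolve_states(p_series, p_open, p_close, frame_idx)

    # ground truth: per-frame non-aerated volume and per-breath R/D, the
    # latter sampled at the frames nearest each breath's end-inspiration and
    # breath end — the same sampling the frame-selection stage performs, so
    # this is the oracle for the measured quantity
    closed_per_frame = n_rec - frame_open.sum(axis=1)
    rd_ml = np.full(b_start.size, np.nan)
    t_last = frame_t_true[-1] if nf else 0.0
    half_f = 0.5 / pcfg.frame_rate
    for j, (ts, tie, te) in enumerate(zip(b_start, b_ie, b_end)):
        if ts < -half_f or te > t_last + half_f:
            continue
        ei_f = int(np.clip(np.round(tie * pcfg.frame_rate), 0, nf - 1))
        ee_f = int(np.clip(np.round(te * pcfg.frame_rate), 0, nf - 1))
        rd_ml[j] = (closed_per_frame[ee_f] - closed_per_frame[ei_f]) * vox

    # render frames
    flat_shape = pcfg.grid_shape[0] * pcfg.grid_shape[1]
    g0 = np.clip(
        rng.normal(pcfg.gas_frac_base, pcfg.gas_frac_spread, size=n_lung), 0.15, 0.90
    )
    g0_flat = np.zeros(flat_shape)
    g0_flat[lung_idx] = g0
    g0_flat[rec_sel] = pcfg.gas_frac_recruited
    frames: list[CtFrame] = []
    for k in range(nf):
        v_k = float(volume[frame_idx[k]])
        gas = np.clip(
            g0_flat + pcfg.gas_frac_per_peep * peep + pcfg.gas_frac_per_l * v_k,
            0.05, 0.95,
        )
        img = np.full(flat_shape, pcfg.background_hu)
        img[lung_idx] = pcfg.hu_nonaerated - pcfg.hu_gas_gain * gas[lung_idx]
        closed_px = rec_sel[~frame_open[k]]
        img[closed_px] = pcfg.hu_nonaerated
        if pcfg.hu_noise_sd > 0:
            noise = rng.normal(0.0, pcfg.hu_noise_sd, size=flat_shape)
            img += np.clip(noise, -3 * pcfg.hu_noise_sd, 3 * pcfg.hu_noise_sd)
        img = np.clip(np.round(img), -1000.0, 100.0)
        frames.append(
            CtFrame(
                attenuation=img.reshape(pcfg.grid_shape),
                pixel_size=pcfg.pixel_size,
                slice_thickness=pcfg.slice_thickness,
                timestamp=float(frame_t_true[k] + pcfg.ct_lag),
            )
        )

    out = replace(gt) if gt is not None else GroundTruth(peep=peep)
    out.frame_t_true = frame_t_true
    out.frame_non_aerated_ml = closed_per_frame * vox
    out.breath_rd_ml = rd_ml
    out.ct_lag = pcfg.ct_lag
    out.lung_volume_ml = n_lung * vox
    if gt is None:
        out.breath_start_t, out.breath_insp_end_t, out.breath_end_t = b_start, b_ie, b_end
    out.validate()
    return frames, mask, out
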