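"""Per-breath respiratory mechanics from multichannel ventilatory tracings.

Channels follow the usual conventions of esophageal-manometry studies:
airway pressure ``pao`` and esophageal pressure ``peso`` in cmH2O, ``flow``
in L/s with inspiration positive, integrated ``volume`` in L referenced to
each breath onset, all sampled on a common 200 Hz timebase; diaphragm
electrical activity ``eadi`` (uV) runs on its own 100 Hz timebase.

The central model is the single-compartment equation of motion,

    P(t) = P0 + Rrs * flow(t) + Ers * volume(t),

fitted per breath by ordinary least squares ("multilinear fitting").  With
``P = pao - peso`` (transpulmonary referencing, the default) the fit returns
pulmonary resistance and lung elastance and remains unbiased during
spontaneous inspiratory effort, because the esophageal channel carries the
muscle pressure.  With ``P = pao`` it returns total respiratory-system
constants and is only valid for passive (relaxed) breaths.

The maximal transpulmonary pressure of a breath is reported both raw,
``ptp_max_prel = max(pao - peso)``, and with the resistive component removed,
``ptp_max = ptp_max_prel - Rrs * Fpeak`` where ``Fpeak`` is the breath's peak
inspiratory flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

logger = logging.getLogger(__name__)

__all__ = [
    "WaveformSet",
    "Breath",
    "MechFit",
    "PtpResult",
    "EadiStats",
    "IndeterminateFitError",
    "integrate_volume",
    "detect_breaths",
    "fit_multilinear",
    "compute_ptp_max",
    "extract_eadi_stats",
    "smooth_waveforms",
    "build_breath_table",
]


class IndeterminateFitError(ValueError):
    """Raised when the equation-of-motion design matrix is rank deficient.

    Typical causes: a static hold (flow identically zero) or flow exactly
    proportional to volume, either of which leaves Rrs/Ers unidentifiable.
    """


@dataclass
class WaveformSet:
    """Synchronized pressure/flow recordings plus an optional EAdi channel."""

    t: np.ndarray                      # s, strictly increasing, uniform
    pao: np.ndarray                    # cmH2O
    peso: np.ndarray                   # cmH2O
    flow: np.ndarray                   # L/s, inspiration positive
    volume: np.ndarray | None = None   # L, from integrate_volume
    pga: np.ndarray | None = None      # cmH2O, carried but not analyzed
    eadi_t: np.ndarray | None = None   # s, EAdi timebase (typically 100 Hz)
    eadi: np.ndarray | None = None     # uV

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("pao", "peso", "flow"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length differs from timebase")
            setattr(self, name, arr)
        if self.t.size < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("timebase must be strictly increasing with >= 2 samples")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def with_volume(self, breaths: Sequence["Breath"] | None = None) -> "WaveformSet":
        """Return a copy whose volume channel is the drift-corrected flow integral."""
        vol = integrate_volume(self.flow, t=self.t, breaths=breaths)
        return replace(self, volume=vol)

    def to_csv(self, path: str | Path, eadi_path: str | Path | None = None) -> None:
        """Write the 200 Hz channels (and optionally EAdi) as CSV."""
        cols = {"t": self.t, "pao": self.pao, "peso": self.peso, "flow": self.flow}
        if self.pga is not None:
            cols["pga"] = self.pga
        if self.volume is not None:
            cols["volume"] = self.volume
        pd.DataFrame(cols).to_csv(path, index=False)
        if eadi_path is not None and self.eadi is not None:
            pd.DataFrame({"t": self.eadi_t, "eadi": self.eadi}).to_csv(
                eadi_path, index=False
            )

    @classmethod
    def from_csv(cls, path: str | Path, eadi_path: str | Path | None = None) -> "WaveformSet":
        df = pd.read_csv(path)
        eadi_t = eadi = None
        if eadi_path is not None and Path(eadi_path).exists():
            edf = pd.read_csv(eadi_path)
            eadi_t = edf["t"].to_numpy()
            eadi = edf["eadi"].to_numpy()
        return cls(
            t=df["t"].to_numpy(),
            pao=df["pao"].to_numpy(),
            peso=df["peso"].to_numpy(),
            flow=df["flow"].to_numpy(),
            volume=df["volume"].to_numpy() if "volume" in df else None,
            pga=df["pga"].to_numpy() if "pga" in df else None,
            eadi_t=eadi_t,
            eadi=eadi,
        )


@dataclass
class Breath:
    """One detected breath, as sample indices into the 200 Hz channels."""

    start_idx: int
    insp_end_idx: int
    end_idx: int
    tv: float          # L, inspired volume after drift correction
    peak_flow: float   # L/s, maximal inspiratory flow
    rr_local: float    # breaths/min, 60 / breath period

    def __post_init__(self) -> None:
        if not self.start_idx < self.insp_end_idx < self.end_idx:
            raise ValueError("breath indices must satisfy start < insp_end < end")


@dataclass
class MechFit:
    """Equation-of-motion least-squares fit for one breath."""

    rrs: float           # cmH2O s/L
    ers: float           # cmH2O/L
    p0: float            # cmH2O
    r2: float
    rms_residual: float  # cmH2O
    reliable: bool = True


@dataclass
class PtpResult:
    ptp_max_prel: float  # cmH2O, max(pao - peso) over the breath
    ptp_max: float       # cmH2O, after subtracting Rrs * Fpeak
    peak_idx: int        # sample index of the raw maximum


@dataclass
class EadiStats:
    eadi_max: float  # uV, breath peak
    eadi_min: float  # uV, minimum over the end-expiratory window


def integrate_volume(
    flow: np.ndarray,
    t: np.ndarray | None = None,
    fs: float | None = None,
    breaths: Sequence[Breath] | None = None,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Trapezoidal flow integral with optional per-breath drift correction.

    When ``breaths`` is given, a linear baseline is removed inside each breath
    so that the volume is zero at both the breath onset and the breath end;
    this removes integration drift from sensor offset and leak.
    """
    flow = np.asarray(flow, dtype=float)
    if t is not None:
        t = np.asarray(t, dtype=float)
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=rtol, atol=rtol * abs(dt[0])):
            raise ValueError("non-uniform time grid")
        step = float(dt[0])
    elif fs is not None:
        step = 1.0 / fs
    else:
        raise ValueError("either t or fs is required")

    vol = cumulative_trapezoid(flow, dx=step, initial=0.0)
    if breaths:
        vol = vol.copy()
        for b in breaths:
            s, e = b.start_idx, b.end_idx
            span = e - s
            drift = (vol[e] - vol[s]) / span
            vol[s : e + 1] = vol[s : e + 1] - vol[s] - drift * np.arange(span + 1)
    return vol


def _zero_cross_back(flow: np.ndarray, idx: int, rising: bool) -> int:
    """Walk back from a hysteresis-threshold crossing to the flow zero crossing."""
    j = idx
    if rising:
        while j > 0 and flow[j - 1] > 0:
            j -= 1
    else:
        while j > 0 and flow[j - 1] < 0:
            j -= 1
    return j


def detect_breaths(
    waves: WaveformSet,
    hysteresis: float = 0.02,
    min_tv: float = 0.01,
    rel_hysteresis: float = 0.05,
) -> list[Breath]:
    """Segment the record into breaths at expiratory-to-inspiratory flow crossings.

    A crossing only counts once flow exceeds ``+hysteresis`` (onset) or falls
    below ``-hysteresis`` (inspiratory end); the boundary itself is placed at
    the preceding zero crossing.  The band is widened to ``rel_hysteresis``
    times the record's peak flow when that is larger, so slow deep breathing
    with long quiescent expirations is not fragmented by channel noise.
    Breaths with inspired volume below ``min_tv`` (L) are discarded as noise
    blips (count logged).  The trailing partial breath, whose end is unknown,
    is not returned.
    """
    flow = waves.flow
    n = flow.size
    hysteresis = max(hysteresis, rel_hysteresis * float(np.max(np.abs(flow), initial=0.0)))
    state = np.zeros(n, dtype=np.int8)
    state[flow > hysteresis] = 1
    state[flow < -hysteresis] = -1
    nz = np.flatnonzero(state)
    if nz.size == 0:
        return []
    # forward-fill the +-1 states to find -1 -> +1 transitions
    filled = state[nz]
    trans = np.flatnonzero(np.diff(filled) != 0) + 1  # positions in nz
    onsets: list[int] = []
    insp_ends: list[int] = []
    if filled[0] == 1:  # record starts mid-inspiration
        onsets.append(_zero_cross_back(flow, nz[0], rising=True))
    for p in trans:
        i = nz[p]
        if filled[p] == 1:
            onsets.append(_zero_cross_back(flow, i, rising=True))
        else:
            insp_ends.append(_zero_cross_back(flow, i, rising=False))

    if len(onsets) < 2:
        return []

    # provisional breaths between consecutive onsets
    raw: list[tuple[int, int, int]] = []
    for s, e in zip(onsets[:-1], onsets[1:]):
        ie = next((k for k in insp_ends if s < k < e), None)
        if ie is None:
            continue
        raw.append((s, ie, e))

    pre = [Breath(s, ie, e, tv=0.0, peak_flow=max(float(np.max(flow[s : ie + 1])), 1e-12),
                  rr_local=60.0 / float(waves.t[e] - waves.t[s]))
           for s, ie, e in raw]
    vol = integrate_volume(flow, t=waves.t, breaths=pre)
    breaths: list[Breath] = []
    n_rejected = 0
    for b in pre:
        b.tv = float(vol[b.insp_end_idx] - vol[b.start_idx])
        if b.tv < min_tv:
            n_rejected += 1
            continue
        breaths.append(b)
    if n_rejected:
        logger.info("detect_breaths: rejected %d breaths with TV < %.3g L",
                    n_rejected, min_tv)
    return breaths


def fit_multilinear(
    waves: WaveformSet,
    breath: Breath,
    pressure: str = "transpulmonary",
    r2_min: float = 0.8,
) -> MechFit:
    """Least-squares equation-of-motion fit over all samples of one breath.

    Parameters
    ----------
    pressure
        ``"transpulmonary"`` fits ``pao - peso`` (pulmonary Rrs, lung Ers;
        valid during spontaneous effort), ``"airway"`` fits ``pao`` alone
        (respiratory-system constants; passive breaths only).
    """
    sl = slice(breath.start_idx, breath.end_idx + 1)
    if breath.end_idx - breath.start_idx + 1 < 20:
        raise ValueError("breath too short for a mechanics fit (< 20 samples)")
    if pressure == "transpulmonary":
        y = waves.pao[sl] - waves.peso[sl]
    elif pressure == "airway":
        y = waves.pao[sl]
    else:
        raise ValueError(f"unknown pressure referencing {pressure!r}")
    f = waves.flow[sl]
    # volume referenced to the breath start: integrate flow over the breath
    v = cumulative_trapezoid(f, dx=1.0 / waves.fs, initial=0.0)
    if np.max(np.abs(f)) < 1e-12:
        raise IndeterminateFitError("flow identically zero over the breath")

    X = np.column_stack([np.ones_like(f), f, v])
    # condition check on the column-scaled design to catch flow ~ volume
    norms = np.linalg.norm(X, axis=0)
    sv = np.linalg.svd(X / norms, compute_uv=False)
    if sv[-1] < 1e-8:
        raise IndeterminateFitError("design matrix is rank deficient")

    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return MechFit(
        rrs=float(coef[1]),
        ers=float(coef[2]),
        p0=float(coef[0]),
        r2=r2,
        rms_residual=float(np.sqrt(ss_res / y.size)),
        reliable=r2 >= r2_min,
    )


def compute_ptp_max(waves: WaveformSet, breath: Breath, fit: MechFit) -> PtpResult:
    """Maximal transpulmonary pressure of a breath, resistive-corrected.

    ``ptp_max_prel`` is the raw per-breath maximum of ``pao - peso``; the
    resistive component ``Rrs * Fpeak`` (peak inspiratory flow of the same
    breath) is then subtracted to obtain ``ptp_max``.
    """
    sl = slice(breath.start_idx, breath.end_idx + 1)
    ptp = waves.pao[sl] - waves.peso[sl]
    k = int(np.argmax(ptp))
    prel = float(ptp[k])
    fpeak = float(np.max(waves.flow[breath.start_idx : breath.insp_end_idx + 1]))
    return PtpResult(
        ptp_max_prel=prel,
        ptp_max=prel - fit.rrs * fpeak,
        peak_idx=breath.start_idx + k,
    )


def extract_eadi_stats(
    waves: WaveformSet,
    breath: Breath,
    end_exp_frac: float = 0.25,
    offset: float = 0.0,
) -> EadiStats:
    """Breath-by-breath EAdi peak and end-expiratory minimum.

    ``eadi_max`` is the maximum over the whole breath; ``eadi_min`` the
    minimum over the final ``end_exp_frac`` of the expiratory time (the
    tonic, end-expiratory diaphragm activity).  ``offset`` (s) is added to
    the EAdi timebase before windowing, for externally synchronized clocks.
    """
    if waves.eadi is None or waves.eadi_t is None:
        raise ValueError("waveform set has no EAdi channel")
    et = waves.eadi_t + offset
    t0 = waves.t[breath.start_idx]
    t_ie = waves.t[breath.insp_end_idx]
    t1 = waves.t[breath.end_idx]
    i0, i1 = np.searchsorted(et, [t0, t1])
    if i1 <= i0:
        raise ValueError("EAdi samples do not cover the breath window")
    w0 = t1 - end_exp_frac * (t1 - t_ie)
    j0, j1 = np.searchsorted(et, [w0, t1])
    if j1 <= j0:
        raise ValueError("end-expiratory EAdi window is empty")
    return EadiStats(
        eadi_max=float(np.max(waves.eadi[i0:i1])),
        eadi_min=float(np.min(waves.eadi[j0:j1])),
    )


def smooth_waveforms(waves: WaveformSet, window_s: float = 0.025) -> WaveformSet:
    """Moving-average denoising of the 200 Hz pressure/flow channels.

    A short (default 25 ms) boxcar with reflected edges; applied before
    breath detection and mechanics fitting when channel noise is present.
    """
    win = max(int(round(window_s * waves.fs)), 1)
    if win % 2 == 0:
        win += 1
    if win == 1:
        return waves

    def _smooth(x: np.ndarray) -> np.ndarray:
        pad = win // 2
        xp = np.pad(x, pad, mode="reflect")
        return np.convolve(xp, np.ones(win) / win, mode="valid")

    return replace(
        waves,
        pao=_smooth(waves.pao),
        peso=_smooth(waves.peso),
        flow=_smooth(waves.flow),
        pga=_smooth(waves.pga) if waves.pga is not None else None,
        volume=None,
    )


def build_breath_table(
    waves: WaveformSet,
    peep: float | None = None,
    direction: str | None = None,
    hysteresis: float = 0.02,
    min_tv: float = 0.01,
    r2_min: float = 0.8,
    end_exp_frac: float = 0.25,
    pressure: str = "transpulmonary",
) -> tuple[pd.DataFrame, list[Breath]]:
    """Run the full per-breath mechanics chain and return one row per breath.

    Columns: breath id, peep, direction, timing, tv, rr_local, peak_flow,
    rrs, ers, r2, ptp_max_prel, ptp_max, eadi_max, eadi_min and an
    ``included`` flag (False for fits with r2 below ``r2_min``).  Breaths
    with unreliable fits are retained in the table but flagged, so exclusion
    counts stay auditable downstream.
    """
    breaths = detect_breaths(waves, hysteresis=hysteresis, min_tv=min_tv)
    waves = waves.with_volume(breaths)
    rows = []
    for i, b in enumerate(breaths):
        row: dict = {
            "breath": i,
            "peep": peep,
            "direction": direction,
            "t_start": float(waves.t[b.start_idx]),
            "t_insp_end": float(waves.t[b.insp_end_idx]),
            "t_end": float(waves.t[b.end_idx]),
            "tv": b.tv,
            "rr_local": b.rr_local,
            "peak_flow": b.peak_flow,
        }
        try:
            fit = fit_multilinear(waves, b, pressure=pressure, r2_min=r2_min)
            ptp = compute_ptp_max(waves, b, fit)
            row.update(
                rrs=fit.rrs, ers=fit.ers, r2=fit.r2,
                ptp_max_prel=ptp.ptp_max_prel, ptp_max=ptp.ptp_max,
                included=fit.reliable,
            )
        except (IndeterminateFitError, ValueError) as exc:
            logger.warning("breath %d: %s", i, exc)
            row.update(rrs=np.nan, ers=np.nan, r2=np.nan,
                       ptp_max_prel=np.nan, ptp_max=np.nan, included=False)
        if waves.eadi is not None:
            try:
                es = extract_eadi_stats(waves, b, end_exp_frac=end_exp_frac)
                row.update(eadi_max=es.eadi_max, eadi_min=es.eadi_min)
            except ValueError:
                row.update(eadi_max=np.nan, eadi_min=np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    n_flagged = int((~df["included"]).sum()) if len(df) else 0
    if n_flagged:
        logger.info("build_breath_table: %d/%d breaths flagged unreliable",
                    n_flagged, len(df))
    return df, breaths
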