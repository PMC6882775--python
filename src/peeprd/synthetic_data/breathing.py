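"""Single-compartment breathing simulator with NAVA-style proportional assist.

Model
-----
Volume above the end-expiratory level obeys the equation of motion

    Ptot(t) = (Ers + Ecw) * V(t) + Rrs * V'(t),

where ``Ptot = Pmus + Passist`` is the total driving pressure, ``Ers`` the
lung elastance, ``Ecw`` the chest-wall elastance and ``Rrs`` the (pulmonary)
resistance.  Each inspiration imposes a half-cosine volume ramp of amplitude
TV over the inspiratory time Ti; expiration is passive, a first-order decay
with time constant tau = Rrs / (Ers + Ecw).  Because the system is linear,
the volume of the whole record is the superposition of per-breath
contributions, and every emitted channel is computed from closed-form
identities, so the equation of motion holds to machine precision on the
noiseless channels.

Assist partitioning: the ventilator delivers ``Passist = nava_level * EAdi``
above PEEP, with ``EAdi = Pmus / pmus_per_eadi + tonic``; writing
``g = nava_level / pmus_per_eadi`` the assist share of the total drive is
``g / (1 + g)`` (1.0 in passive mode, where Pmus = 0 and the ventilator
drives the whole breath).  Derived channels:

    pao  = PEEP + share * Ptot
    peso = peso_ee + Ecw * V - Pmus
    pao - peso = (PEEP - peso_ee) + Ers * V + Rrs * V'   (transpulmonary)

Respiratory drive follows the pooled PEEP trends: RR(PEEP) linear with
negative slope, TV(PEEP) linear with positive slope, with log-free Gaussian
breath-to-breath TV jitter.  Noise is additive Gaussian per channel with
standard deviation ``noise_sd_frac`` times the channel's dynamic range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..resp_mechanics import WaveformSet
from .protocol import generate_protocol

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "GroundTruth", "simulate_breathing"]


def _default_peeps() -> list[float]:
    return [s.peep for s in generate_protocol(15.0, 3.0)]


@dataclass
class SimConfig:
    """Study conditions for the breathing simulator.

    Defaults mirror the PEEP-ramp protocol conditions: resistance
    16.7 cmH2O s/L after mild surfactant-depletion injury, a 0-15-0 cmH2O
    PEEP staircase in 3 cmH2O steps, drive trends RR = 95.47 - 5.8*PEEP
    (breaths/min) and TV = 0.06 + 0.0206*PEEP (L), and NAVA assist of
    2 cmH2O per uV of EAdi.
    """

    rrs: float = 16.7             # cmH2O s/L, pulmonary resistance
    ers: float = 30.0             # cmH2O/L, lung elastance
    ecw: float = 6.0              # cmH2O/L, chest-wall elastance
    nava_level: float = 2.0       # cmH2O/uV assist gain
    peep_sequence: list[float] = field(default_factory=_default_peeps)
    rr_intercept: float = 95.47   # breaths/min at PEEP 0
    rr_slope: float = -5.8        # breaths/min per cmH2O
    tv_intercept: float = 0.06    # L at PEEP 0
    tv_slope: float = 0.0206      # L per cmH2O
    tv_jitter_frac: float = 0.10  # sd of fractional breath-to-breath TV jitter
    noise_sd_frac: float = 0.02   # channel noise sd as fraction of dynamic range
    fs_wave: float = 200.0        # Hz, pressure/flow sampling
    fs_eadi: float = 100.0        # Hz, EAdi sampling
    duty_cycle: float = 1.0 / 3.0  # Ti / Ttot
    ti_max: float = 1.0           # s, inspiratory-time cap at low RR
    exp_onset_tau: float = 0.02   # s, post-inspiratory braking of expiratory flow
    pmus_per_eadi: float = 1.0    # cmH2O of muscle pressure per uV
    eadi_tonic: float = 0.5       # uV, end-expiratory tonic activity
    peso_ee: float = -3.0         # cmH2O, esophageal baseline at V = 0 (offset-corrected)
    pga_ee: float = 8.0           # cmH2O, gastric baseline
    passive: bool = False         # True: no muscle activity, ventilator-driven
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rrs <= 0 or self.ers <= 0:
            raise ValueError("rrs and ers must be positive")
        if self.ecw < 0:
            raise ValueError("ecw must be non-negative")
        if any(p < 0 for p in self.peep_sequence):
            raise ValueError("all PEEP levels must be non-negative")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must be in (0, 1)")

    @property
    def tau(self) -> float:
        """Expiratory time constant Rrs / (Ers + Ecw), in s."""
        return self.rrs / (self.ers + self.ecw)

    @property
    def assist_share(self) -> float:
        """Ventilator share g/(1+g) of the total driving pressure."""
        if self.passive:
            return 1.0
        g = self.nava_level / self.pmus_per_eadi
        return g / (1.0 + g)

    def rr_at(self, peep: float) -> float:
        rr = self.rr_intercept + self.rr_slope * peep
        if rr < 1.0:
            warnings.warn(
                f"drive model gives RR {rr:.2f}/min at PEEP {peep}; clipped to 1",
                RuntimeWarning,
            )
            rr = 1.0
        return rr

    def tv_at(self, peep: float) -> float:
        return max(self.tv_intercept + self.tv_slope * peep, 1e-4)


@dataclass
class GroundTruth:
    """Oracle values emitted alongside synthetic data.

    Waveform fields are filled by :func:`simulate_breathing`; the CT fields
    (``frame_*``, ``breath_rd_ml``, ``ct_lag``, ``lung_volume_ml``) by
    :func:`peeprd.synthetic_data.simulate_ct_sequence`.
    """

    peep: float | None = None
    rr: float | None = None                      # breaths/min of the drive model
    breath_start_t: np.ndarray | None = None     # s
    breath_insp_end_t: np.ndarray | None = None  # s
    breath_end_t: np.ndarray | None = None       # s
    tv: np.ndarray | None = None                 # L, per breath (drift-corrected)
    pmus_amp: np.ndarray | None = None           # cmH2O, per breath
    peak_flow: np.ndarray | None = None          # L/s, per breath
    ptp_max: np.ndarray | None = None            # cmH2O, per breath (resistive-corrected)
    ptp_trace: np.ndarray | None = None          # cmH2O, clean pao - peso at fs_wave
    recruit_pressure: np.ndarray | None = None   # cmH2O, phantom recruiting pressure
    clean: dict[str, np.ndarray] = field(default_factory=dict)
    # CT phantom fields
    frame_t_true: np.ndarray | None = None       # s, frame times on the spirometry clock
    frame_non_aerated_ml: np.ndarray | None = None
    breath_rd_ml: np.ndarray | None = None       # ml, per breath (ee minus ei)
    ct_lag: float | None = None                  # s added to emitted CT timestamps
    lung_volume_ml: float | None = None          # total masked slice volume

    @property
    def n_breaths(self) -> int:
        return 0 if self.breath_start_t is None else len(self.breath_start_t)

    def validate(self) -> None:
        nb = self.n_breaths
        for name in ("breath_insp_end_t", "breath_end_t", "tv", "pmus_amp",
                     "peak_flow", "ptp_max"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != nb:
                raise ValueError(f"{name} length {len(arr)} != breath count {nb}")
        if self.frame_t_true is not None and self.frame_non_aerated_ml is not None:
            if len(self.frame_t_true) != len(self.frame_non_aerated_ml):
                raise ValueError("frame arrays have mismatched lengths")


def simulate_breathing(
    cfg: SimConfig,
    peep: float,
    duration: float,
) -> tuple[WaveformSet, GroundTruth]:
    """Simulate one PEEP step of NAVA-assisted spontaneous breathing.

    Returns the (noisy) waveform set and the clean ground truth.  The record
    starts in quasi-steady state: the end-expiratory volume excess left by
    incomplete expiration at high breathing rates is pre-loaded, so early
    breaths are statistically like late ones.
    """
    rr = cfg.rr_at(peep)
    period = 60.0 / rr
    if duration < period:
        raise ValueError(
            f"duration {duration} s is shorter than one breath period {period:.2f} s"
        )
    ti = min(cfg.duty_cycle * period, cfg.ti_max)
    te = period - ti
    tau = cfg.tau
    etot = cfg.ers + cfg.ecw
    share = cfg.assist_share
    fs = cfg.fs_wave
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(cfg.seed)

    tv_mean = cfg.tv_at(peep)
    n_breaths = int(np.ceil(duration / period)) + 1
    jit = np.clip(rng.normal(0.0, cfg.tv_jitter_frac, size=n_breaths), -0.5, 0.5)
    tvs = tv_mean * (1.0 + jit)

    flow = np.zeros(n)

    # quasi-steady-state end-expiratory excess from incomplete expiration
    v0 = tv_mean * np.exp(-te / tau) / (1.0 - np.exp(-period / tau))
    if v0 > 1e-9:
        flow += -(v0 / tau) * np.exp(-t / tau)

    omega = np.pi / ti
    for k in range(n_breaths):
        t0 = k * period
        i0 = int(np.ceil(t0 * fs - 1e-9))
        if i0 >= n:
            break
        i_ie = min(int(np.ceil((t0 + ti) * fs - 1e-9)), n)
        tv_k = tvs[k]
        # inspiration: half-cosine volume ramp -> half-sine flow
        ph = omega * (t[i0:i_ie] - t0)
        flow[i0:i_ie] += 0.5 * tv_k * omega * np.sin(ph)
        # passive expiration: first-order relaxation with a brief
        # post-inspiratory braking onset (keeps flow continuous at the
        # inspiratory end), computed to record end
        if i_ie < n:
            s = t[i_ie:] - (t0 + ti)
            if cfg.exp_onset_tau > 0:
                # scale so the braked envelope still expires exactly tv_k
                scale = (tau + cfg.exp_onset_tau) / tau
                brake = scale * (1.0 - np.exp(-s / cfg.exp_onset_tau))
            else:
                brake = 1.0
            flow[i_ie:] += -(tv_k / tau) * np.exp(-s / tau) * brake

    # the emitted volume is the *trapezoidal* integral of the emitted flow —
    # the same quadrature the analysis chain applies — so the discrete
    # channels satisfy the equation of motion identically, not merely up to
    # integration error
    from scipy.integrate import cumulative_trapezoid

    vol = v0 + cumulative_trapezoid(flow, dx=1.0 / fs, initial=0.0)
    ptot = etot * vol + cfg.rrs * flow

    pmus = (1.0 - share) * ptot
    pao = peep + share * ptot
    peso = cfg.peso_ee + cfg.ecw * vol - pmus
    pga = cfg.pga_ee + 0.3 * pmus
    ptp = pao - peso

    # EAdi on its own (coarser) timebase
    if abs(fs / cfg.fs_eadi - round(fs / cfg.fs_eadi)) < 1e-9:
        stride = int(round(fs / cfg.fs_eadi))
        eadi_t = t[::stride].copy()
        pmus_e = pmus[::stride]
    else:  # pragma: no cover - non-integer ratios
        eadi_t = np.arange(int(round(duration * cfg.fs_eadi))) / cfg.fs_eadi
        pmus_e = np.interp(eadi_t, t, pmus)
    eadi = cfg.eadi_tonic + pmus_e / cfg.pmus_per_eadi

    # ground truth per complete breath: segment the *clean* channels with the
    # same zero-crossing rule the analysis chain uses, so oracle quantities
    # share the analysis windowing convention and differ only by noise
    from ..resp_mechanics import detect_breaths

    clean_ws = WaveformSet(t=t, pao=pao.copy(), peso=peso.copy(), flow=flow.copy())
    gt_breaths = detect_breaths(clean_ws)
    s_i = np.array([b.start_idx for b in gt_breaths], dtype=int)
    ie_i = np.array([b.insp_end_idx for b in gt_breaths], dtype=int)
    e_i = np.array([b.end_idx for b in gt_breaths], dtype=int)
    tv_true = np.array([b.tv for b in gt_breaths])
    pf_true = np.array([b.peak_flow for b in gt_breaths])
    ptpmax_true = np.empty(len(s_i))
    pmusamp_true = np.empty(len(s_i))
    for j, (s, ie, e) in enumerate(zip(s_i, ie_i, e_i)):
        ptpmax_true[j] = np.max(ptp[s : e + 1]) - cfg.rrs * pf_true[j]
        pmusamp_true[j] = np.max(pmus[s : e + 1])

    recruit = peep + cfg.ers * vol + cfg.rrs * np.maximum(flow, 0.0)

    gt = GroundTruth(
        peep=peep,
        rr=rr,
        breath_start_t=t[s_i],
        breath_insp_end_t=t[ie_i],
        breath_end_t=t[e_i],
        tv=tv_true,
        pmus_amp=pmusamp_true,
        peak_flow=pf_true,
        ptp_max=ptpmax_true,
        ptp_trace=ptp,
        recruit_pressure=recruit,
        clean={
            "t": t, "pao": pao.copy(), "peso": peso.copy(), "flow": flow.copy(),
            "volume": vol.copy(), "pga": pga.copy(),
            "eadi_t": eadi_t, "eadi": eadi.copy(),
        },
    )
    gt.validate()

    def _noisy(x: np.ndarray) -> np.ndarray:
        if cfg.noise_sd_frac <= 0:
            return x.copy()
        rng_range = float(np.max(x) - np.min(x))
        if rng_range == 0.0:
            return x.copy()
        return x + rng.normal(0.0, cfg.noise_sd_frac * rng_range, size=x.shape)

    waves = WaveformSet(
        t=t,
        pao=_noisy(pao),
        peso=_noisy(peso),
        flow=_noisy(flow),
        pga=_noisy(pga),
        eadi_t=eadi_t,
        eadi=np.maximum(_noisy(eadi), 0.0),
    )
    return waves, gt
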