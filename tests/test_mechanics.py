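import numpy as np
import pytest

from peeprd.resp_mechanics import (
    Breath,
    IndeterminateFitError,
    WaveformSet,
    compute_ptp_max,
    detect_breaths,
    extract_eadi_stats,
    fit_multilinear,
    integrate_volume,
    smooth_waveforms,
)
from peeprd.synthetic_data import SimConfig, simulate_breathing


def _ws(t, flow, pao=None, peso=None, **kw):
    n = len(t)
    return WaveformSet(
        t=np.asarray(t, float),
        pao=np.zeros(n) if pao is None else np.asarray(pao, float),
        peso=np.zeros(n) if peso is None else np.asarray(peso, float),
        flow=np.asarray(flow, float),
        **kw,
    )


# ---------------------------------------------------------------------------
# volume integration
# ---------------------------------------------------------------------------

def test_zero_flow_integrates_to_zero():
    t = np.arange(0, 1, 0.005)
    assert np.all(integrate_volume(np.zeros_like(t), t=t) == 0.0)


def test_half_sine_inspiration_closed_form():
    # flow A*sin(pi t/T) over [0, T] inspires TV = 2AT/pi
    fs, A, T = 200.0, 0.8, 0.6
    t = np.arange(0, T + 1 / fs, 1 / fs)
    vol = integrate_volume(A * np.sin(np.pi * t / T), t=t)
    assert vol[-1] == pytest.approx(2 * A * T / np.pi, rel=1e-4)


def test_drift_correction_zeroes_breath_ends():
    t = np.arange(0, 2, 0.005)
    flow = np.sin(2 * np.pi * t) + 0.05     # constant leak adds drift
    b = Breath(0, 100, 199, tv=1.0, peak_flow=1.0, rr_local=60.0)
    vol = integrate_volume(flow, t=t, breaths=[b])
    assert vol[0] == pytest.approx(0.0, abs=1e-12)
    assert vol[199] == pytest.approx(0.0, abs=1e-12)


def test_non_uniform_grid_rejected():
    t = np.array([0.0, 0.005, 0.011, 0.015])
    with pytest.raises(ValueError, match="non-uniform"):
        integrate_volume(np.ones(4), t=t)


def test_simulator_tv_matches_ground_truth(clean_waves_p6):
    waves, gt = clean_waves_p6
    breaths = detect_breaths(waves)
    assert len(breaths) == gt.n_breaths
    for b in breaths:
        j = np.argmin(np.abs(gt.breath_start_t - waves.t[b.start_idx]))
        assert b.tv == pytest.approx(gt.tv[j], rel=0.01)


# ---------------------------------------------------------------------------
# breath detection
# ---------------------------------------------------------------------------

def test_constant_zero_flow_yields_no_breaths():
    t = np.arange(0, 5, 0.005)
    assert detect_breaths(_ws(t, np.zeros_like(t))) == []


def test_breath_count_at_thirty_per_minute():
    cfg = SimConfig(rr_intercept=30.0, rr_slope=0.0, noise_sd_frac=0.0,
                    tv_jitter_frac=0.0, seed=8)
    waves, _ = simulate_breathing(cfg, 0.0, 100.0)
    breaths = detect_breaths(waves)
    assert abs(len(breaths) - 50) <= 1


@pytest.mark.parametrize("peep", [0.0, 6.0, 12.0])
def test_detected_rate_tracks_drive_model(peep):
    cfg = SimConfig(noise_sd_frac=0.0, tv_jitter_frac=0.0, seed=9)
    waves, gt = simulate_breathing(cfg, peep, 20.0)
    breaths = detect_breaths(waves)
    assert np.mean([b.rr_local for b in breaths]) == pytest.approx(gt.rr, rel=0.02)


def test_detection_is_stable_under_resegmentation(clean_waves_p6):
    """Re-running detection on the record cut at the first breath onset
    reproduces the same breath boundaries (shifted by the cut)."""
    waves, _ = clean_waves_p6
    breaths = detect_breaths(waves)
    s0 = breaths[0].start_idx
    cut = _ws(waves.t[s0:] - waves.t[s0], waves.flow[s0:],
              waves.pao[s0:], waves.peso[s0:])
    again = detect_breaths(cut)
    for b1, b2 in zip(breaths[:-1], again[: len(breaths) - 1]):
        assert abs((b1.start_idx - s0) - b2.start_idx) <= 1
        assert abs((b1.insp_end_idx - s0) - b2.insp_end_idx) <= 1


# ---------------------------------------------------------------------------
# equation-of-motion fitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rrs", [5.0, 10.0, 20.0, 30.0])
@pytest.mark.parametrize("ers", [15.0, 30.0, 60.0])
def test_noiseless_parameter_recovery(rrs, ers):
    cfg = SimConfig(rrs=rrs, ers=ers, noise_sd_frac=0.0, tv_jitter_frac=0.0, seed=10)
    waves, _ = simulate_breathing(cfg, 6.0, 8.0)
    b = detect_breaths(waves)[1]
    fit = fit_multilinear(waves, b)
    assert fit.rrs == pytest.approx(rrs, rel=1e-6)
    assert fit.ers == pytest.approx(ers, rel=1e-6)
    assert fit.r2 > 0.999999


def test_airway_mode_recovers_total_elastance_on_passive_breath():
    cfg = SimConfig(noise_sd_frac=0.0, tv_jitter_frac=0.0, passive=True, seed=12)
    waves, _ = simulate_breathing(cfg, 6.0, 8.0)
    b = detect_breaths(waves)[1]
    fit = fit_multilinear(waves, b, pressure="airway")
    assert fit.rrs == pytest.approx(cfg.rrs, rel=1e-6)
    assert fit.ers == pytest.approx(cfg.ers + cfg.ecw, rel=1e-6)


def test_fit_agrees_with_normal_equations(clean_waves_p6):
    waves, _ = clean_waves_p6
    b = detect_breaths(waves)[2]
    fit = fit_multilinear(waves, b)
    sl = slice(b.start_idx, b.end_idx + 1)
    from scipy.integrate import cumulative_trapezoid

    f = waves.flow[sl]
    v = cumulative_trapezoid(f, dx=1.0 / waves.fs, initial=0.0)
    X = np.column_stack([np.ones_like(f), f, v])
    y = waves.pao[sl] - waves.peso[sl]
    beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent normal-equations solve
    assert fit.p0 == pytest.approx(beta[0], rel=1e-9, abs=1e-9)
    assert fit.rrs == pytest.approx(beta[1], rel=1e-9)
    assert fit.ers == pytest.approx(beta[2], rel=1e-9)


def test_flow_rescaling_rescales_resistance(clean_waves_p6):
    waves, _ = clean_waves_p6
    b = detect_breaths(waves)[2]
    fit = fit_multilinear(waves, b)
    scaled = _ws(waves.t, waves.flow * 60.0, waves.pao, waves.peso)  # L/min flow
    fit2 = fit_multilinear(scaled, b)
    assert fit2.rrs == pytest.approx(fit.rrs / 60.0, rel=1e-9)
    assert fit2.ers == pytest.approx(fit.ers / 60.0, rel=1e-9)


def test_static_hold_is_indeterminate():
    t = np.arange(0, 1, 0.005)
    ws = _ws(t, np.zeros_like(t), pao=np.full_like(t, 10.0))
    b = Breath(0, 100, 199, tv=0.1, peak_flow=1e-9, rr_local=60.0)
    with pytest.raises(IndeterminateFitError):
        fit_multilinear(ws, b)


def test_constant_flow_is_rank_deficient():
    t = np.arange(0, 1, 0.005)
    ws = _ws(t, np.full_like(t, 0.5), pao=10.0 + t)
    b = Breath(0, 100, 199, tv=0.25, peak_flow=0.5, rr_local=60.0)
    with pytest.raises(IndeterminateFitError):
        fit_multilinear(ws, b)


def test_short_breath_rejected(clean_waves_p6):
    waves, _ = clean_waves_p6
    b = Breath(0, 5, 10, tv=0.1, peak_flow=0.5, rr_local=60.0)
    with pytest.raises(ValueError, match="short"):
        fit_multilinear(waves, b)


def test_monte_carlo_resistance_recovery_under_noise():
    """200 noisy breaths (2% channel noise): median |Rrs error| below 5%."""
    errs = []
    for seed in (1, 2):
        cfg = SimConfig(noise_sd_frac=0.02, tv_jitter_frac=0.10, seed=seed)
        waves, _ = simulate_breathing(cfg, 3.0, 80.0)
        sm = smooth_waveforms(waves)
        for b in detect_breaths(sm):
            fit = fit_multilinear(sm, b)
            errs.append(abs(fit.rrs - cfg.rrs) / cfg.rrs)
    assert len(errs) >= 200
    assert np.median(errs) < 0.05


# ---------------------------------------------------------------------------
# maximal transpulmonary pressure
# ---------------------------------------------------------------------------

def test_ptp_resistive_correction_formula():
    # constructed breath: (pao - peso)max = 30, rrs = 10, peak flow = 1.0
    t = np.arange(0, 1, 0.005)
    flow = np.sin(np.pi * t / 0.5) * np.where(t < 0.5, 1.0, 0.3)
    pao = 30.0 * np.sin(np.pi * t / 0.5).clip(0)
    ws = _ws(t, flow, pao=pao)
    b = Breath(0, 100, 199, tv=0.3, peak_flow=1.0, rr_local=60.0)
    from peeprd.resp_mechanics import MechFit

    fit = MechFit(rrs=10.0, ers=30.0, p0=0.0, r2=1.0, rms_residual=0.0)
    res = compute_ptp_max(ws, b, fit)
    assert res.ptp_max_prel == pytest.approx(30.0, rel=1e-6)
    assert res.ptp_max == pytest.approx(20.0, rel=1e-6)
    fit0 = MechFit(rrs=0.0, ers=30.0, p0=0.0, r2=1.0, rms_residual=0.0)
    assert compute_ptp_max(ws, b, fit0).ptp_max == pytest.approx(30.0, rel=1e-6)


def test_ptp_never_exceeds_preliminary_value(noisy_waves_p6):
    waves, _ = noisy_waves_p6
    sm = smooth_waveforms(waves)
    for b in detect_breaths(sm):
        fit = fit_multilinear(sm, b)
        res = compute_ptp_max(sm, b, fit)
        if fit.rrs > 0 and b.peak_flow > 0:
            assert res.ptp_max <= res.ptp_max_prel


def test_ptp_matches_ground_truth_on_simulated_breaths(noisy_waves_p6):
    waves, gt = noisy_waves_p6
    sm = smooth_waveforms(waves)
    errs = []
    for b in detect_breaths(sm):
        j = np.argmin(np.abs(gt.breath_start_t - sm.t[b.start_idx]))
        fit = fit_multilinear(sm, b)
        res = compute_ptp_max(sm, b, fit)
        errs.append(abs(res.ptp_max - gt.ptp_max[j]) / abs(gt.ptp_max[j]))
    assert np.median(errs) < 0.05


# ---------------------------------------------------------------------------
# EAdi statistics
# ---------------------------------------------------------------------------

def test_constant_eadi_collapses_to_single_value():
    t = np.arange(0, 2, 0.005)
    ws = _ws(t, np.sin(2 * np.pi * t),
             eadi_t=np.arange(0, 2, 0.01), eadi=np.ones(200))
    b = Breath(0, 100, 300, tv=0.3, peak_flow=1.0, rr_local=30.0)
    st = extract_eadi_stats(ws, b)
    assert st.eadi_max == st.eadi_min == 1.0


def test_simulator_eadi_peak_and_tonic_level(clean_waves_p6):
    waves, gt = clean_waves_p6
    breaths = detect_breaths(waves)
    b = breaths[3]
    st = extract_eadi_stats(waves, b)
    j = np.argmin(np.abs(gt.breath_start_t - waves.t[b.start_idx]))
    expected_peak = 0.5 + gt.pmus_amp[j]  # tonic + Pmus / (cmH2O per uV)
    assert st.eadi_max == pytest.approx(expected_peak, rel=0.05)
    assert st.eadi_min == pytest.approx(0.5, rel=0.05)


def test_rising_assist_raises_peak_not_tonic():
    common = dict(noise_sd_frac=0.0, tv_jitter_frac=0.0, seed=2)
    # larger tidal drive at higher PEEP: phasic EAdi peak grows
    _, gt_low = simulate_breathing(SimConfig(**common), 3.0, 10.0)
    _, gt_high = simulate_breathing(SimConfig(**common), 12.0, 10.0)
    assert gt_high.clean["eadi"].max() > gt_low.clean["eadi"].max()
    assert gt_high.clean["eadi"].min() == pytest.approx(0.5, abs=0.05)


def test_missing_eadi_channel_errors(clean_waves_p6):
    waves, _ = clean_waves_p6
    b = detect_breaths(waves)[0]
    ws = _ws(waves.t, waves.flow, waves.pao, waves.peso)
    with pytest.raises(ValueError, match="EAdi"):
        extract_eadi_stats(ws, b)
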