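# Methods

This note documents the models, the synthetic study generator, the analysis
conventions, and the numerical choices behind `peeprd`, in the spirit of a
package methods appendix.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Breathing simulator

### Model

One respiratory compartment with linear mechanics.  Volume above the
end-expiratory level obeys

    Ptot(t) = (Ers + Ecw)·V(t) + Rrs·V̇(t),        Ptot = Pmus + Passist,

with lung elastance `Ers`, chest-wall elastance `Ecw`, and resistance `Rrs`
placed entirely in the airways (so the esophageal-referenced pressure
carries the full resistive drop).  Each inspiration imposes a half-cosine
volume ramp of amplitude TV over the inspiratory time Ti (hence a half-sine
inspiratory flow); expiration is passive first-order relaxation with
τ = Rrs/(Ers + Ecw), preceded by a brief post-inspiratory braking onset
(time constant `exp_onset_tau`, default 20 ms, amplitude-rescaled so the
full tidal volume is still expired).  Braking keeps the flow channel
continuous at the inspiratory end; a discontinuity there would otherwise
inject a first-order quadrature error into every integral of flow.  The
linearity of the system lets the record be built as a superposition of
per-breath contributions, including a pre-loaded quasi-steady end-expiratory
volume excess when the expiratory time is short relative to τ (dynamic
hyperinflation at high breathing rates).

The muscle/ventilator split follows proportional assist: with gain ratio
g = `nava_level`/`pmus_per_eadi`, the ventilator contributes a share
g/(1+g) of the total drive (`passive=True` sets the share to 1, i.e. a
relaxed, ventilator-driven subject).  Derived channels are algebraic
identities:

    pao  = PEEP + share·Ptot
    peso = peso_ee + Ecw·V − Pmus
    eadi = tonic + Pmus/pmus_per_eadi          (100 Hz timebase)
    pao − peso = (PEEP − peso_ee) + Ers·V + Rrs·V̇

The last identity is what makes the transpulmonary multilinear fit unbiased
during spontaneous effort (§3).

**Discrete consistency.** The emitted volume channel is the trapezoidal
integral of the emitted flow — the same quadrature the analysis chain uses —
and the pressures are built from that discrete volume.  Consequently the
equation of motion holds on the sampled channels to machine precision, and
noiseless parameter recovery is exact rather than limited by integration
error.  This is a deliberate simulation-design choice: the oracle should
test the analysis, not the quadrature.

### Drive model and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| `rrs` | 16.7 | cmH2O·s/L | respiratory resistance after mild surfactant-depletion injury |
| `ers` | 30 | cmH2O/L | injured-lung elastance, porcine scale |
| `ecw` | 6 | cmH2O/L | chest-wall elastance, supine pig |
| `rr_intercept`, `rr_slope` | 95.47, −5.8 | bpm, bpm/cmH2O | pooled rate-vs-PEEP trend of the emulated protocol |
| `tv_intercept`, `tv_slope` | 0.06, 0.0206 | L, L/cmH2O | tidal-volume trend; see note below |
| `tv_jitter_frac` | 0.10 | — | breath-to-breath TV variability (sd as a fraction) |
| `nava_level` | 2.0 | cmH2O/µV | middle of the per-subject assist range |
| `pmus_per_eadi` | 1.0 | cmH2O/µV | neuromechanical coupling |
| `eadi_tonic` | 0.5 | µV | end-expiratory diaphragm activity |
| `peso_ee` | −3 | cmH2O | offset-corrected esophageal baseline so end-expiratory transpulmonary pressure is mildly positive |
| `duty_cycle`, `ti_max` | 1/3, 1.0 s | — | Ti scales with the period but is capped: at 8 breaths/min an uncapped Ti of 2.4 s would collapse peak flow and, with it, the resistive component of P_TP,MAX |
| `noise_sd_frac` | 0.02 | — | additive Gaussian noise, sd = fraction × channel dynamic range |
| `fs_wave`, `fs_eadi` | 200, 100 | Hz | acquisition rates of the emulated hardware |

The tidal-volume *intercept* deserves a note: the pooled trend this
simulator emulates extrapolates to a vanishing TV at ZEEP, which is below
any breath-detection floor (an 0.4 ml breath is not a breath).  The default
intercept of 0.06 L (~2 ml/kg for a 27 kg animal — rapid shallow breathing)
keeps ZEEP breaths real while preserving the slope.

Breath-to-breath variability is a single TV jitter parameter; the generator
makes no claim about the autocorrelation structure of real drive
variability.

## 2. Dynamic CT phantom

A 2-D slice (default 96×96 pixels of 0.5×0.5 mm, 5 mm thick, elliptical
lung mask of ≈4,400 pixels ≈ 5.5 ml) imaged at 20 Hz for 100 s (2,000
frames), with timestamps shifted by a configurable CT-clock lag (default
0.35 s) so the synchronization stage has something to recover.

A fraction (default 0.5) of lung pixels is *recruitable*, each with an
opening pressure and a lower closing pressure and a hysteresis rule against
the regional recruiting pressure

    P_r(t) = PEEP + Ers·V(t) + Rrs·max(V̇(t), 0).

The inspiratory resistive term matters: at low PEEP the subject breathes
fast and shallow, so the elastic excursion Ers·TV is small but peak flows
are high; including Rrs·V̇ during inflation gives the low-PEEP steps the
large recruiting-pressure excursions that make cyclic R/D biggest at ZEEP.
During deflation the floor is the elastic recoil, so P_r returns exactly to
PEEP at end-expiration and a unit whose closing pressure lies below PEEP
stays open once recruited — the PEEP-stabilization mechanism.

Opening/closing thresholds are lognormal (moment-matched to the configured
mean/sd; defaults mean 8/sd 6 and mean 4/sd 6 cmH2O, closing clipped below
opening).  The lognormal shape — most units operable at low pressure, a
heavy right tail of stubborn units — is what published airway-opening
pressure distributions in surfactant-depleted lungs look like, and it is
the shape that yields a strictly decreasing mean R/D over the up-ramp
*with* a nonzero residual at PEEP 15.  The distributions were fixed at
design time by computing the per-PEEP toggle-window mass from the drive
model, not by iterating on test outcomes.

Rendering: closed pixels take the collapsed-tissue attenuation (−20 HU);
open and non-recruitable pixels take HU = −20 − 980·g with regional gas
content g tracking a per-pixel baseline plus PEEP- and volume-dependent
terms, clipped to [0.05, 0.95].  HU noise (sd 12, truncated at ±3 sd) is
added and the image clipped to [−1000, +100].  Truncation is what keeps
the aeration oracle *exact*: no noise excursion can carry a pixel across a
compartment boundary, so the measured non-aerated volume equals the
ground-truth closed-pixel volume voxel for voxel.

Ground truth records the per-frame non-aerated volume and a per-breath R/D
sampled at the frames nearest each breath's end-inspiration and breath end
on the true clock — i.e. the same sampling the analysis performs, so the
oracle and the measurement differ only through noise, synchronization and
selection errors.  `fixed_toggle_fraction` programs an exact tidal R/D: the
chosen fraction of lung pixels gets identical thresholds placed inside the
excursion band common to all breaths (closing below every end-inspiratory
pressure, opening midway up the common peak), so every programmed pixel
toggles exactly once per cycle.

What the phantom does *not* emulate: 3-D geometry and gravitational
gradients, gas exchange, cardiogenic oscillations, slice-position drift
with diaphragm displacement, beam hardening, or scanner reconstruction
artifacts.  Tests passing on the phantom therefore validate the *analysis
arithmetic and logic*, not robustness to those real-data effects.

## 3. Analysis conventions

**Breath detection.** Expiratory-to-inspiratory flow zero crossings with a
hysteresis band of ±0.02 L/s, widened to 5% of the record's peak flow when
larger — without the adaptive floor, channel noise fragments the long
quiescent expirations of slow deep breathing at high PEEP.  Breaths with
inspired volume < 0.01 L are dropped as noise blips.  Volume is the
trapezoidal flow integral with per-breath linear drift correction (zero at
both breath ends).

**Equation-of-motion fit.** Ordinary least squares of
`P = P0 + Rrs·V̇ + Ers·V` over *all* samples of the breath, with the volume
regressor re-integrated from flow and referenced to the breath start.  The
default pressure is transpulmonary (`pao − peso`): during spontaneous
effort the airway-pressure-only regression is confounded by the unobserved
muscle pressure (it returns assist-share-scaled coefficients), whereas the
esophageal-referenced fit recovers pulmonary resistance and lung elastance
exactly — this is precisely why esophageal manometry is part of the
protocol.  An `"airway"` mode is provided for passive recordings (it then
returns respiratory-system constants, Ers+Ecw).  Rank deficiency (static
hold, constant flow) raises an explicit indeterminate-fit error; fits with
R² < 0.8 are flagged and excluded from downstream statistics but kept in
the table with counts logged.

**P_TP,MAX.** Raw maximum of `pao − peso` over the breath minus
`Rrs × F_PEAK` with F_PEAK the maximal inspiratory flow of the same breath
(inspiration positive).  The ground-truth oracle applies the same
definition to the noise-free channels with the true Rrs, isolating
measurement and fitting error.  Noisy channels are denoised by a 25 ms
moving average before analysis; the bias of a max over noisy samples would
otherwise dominate small-P_TP breaths.

**EAdi statistics.** Peak over the breath; minimum over the last 25% of
expiratory time (configurable), aligned to the 200 Hz timebase by nearest
sample.

**Synchronization.** The slice gas-content series (identical arithmetic to
the aeration profile) is linearly interpolated to the 200 Hz grid and
cross-correlated with spirometric volume using exact per-lag overlap
normalization.  The default search window is ±2 s — acquisition-clock
offsets are sub-second, and a wide window risks locking onto a
breath-period alias when breathing is very regular; among peaks within 0.5%
of the maximum the smallest |lag| is taken, for the same reason.  Peak
correlation below 0.5 flags the alignment unreliable.

**Frame selection.** Nearest offset-corrected frame timestamp to the
breath's inspiratory end and to the breath end (a half-frame tolerance at
the span edges).  An extremal-gas-content alternative (`"extremal-gas"`)
is available for sensitivity analysis; nearest-time is the default because
heavy tidal R/D makes gas content non-monotone within a phase.  At 20 Hz
and very high breathing rates the ±25 ms frame quantization is a real
error source; the phantom's frame-sampled ground truth makes it visible
rather than hiding it.

**R/D.** `non-aerated(ee) − non-aerated(ei)` in ml and g; percentages use
the end-expiratory totals.  The %eeLV denominator is the *total* masked
slice volume (tissue + gas); a gas-only denominator is one flag away.
Negative R/D is retained and flagged, never clipped — truncation would bias
the dispersion statistics of Q4.  Aggregates (mean, n−1 sd, n) are emitted
both pooled per PEEP and split by ramp direction.

## 4. Statistical battery

* **Kruskal–Wallis** (tie-corrected, χ² approximation) via scipy behind the
  module surface; verified against closed-form rank arithmetic.
* **Dunn–Šidák post hoc:** pairwise Dunn z-tests on pooled mean ranks
  (tie-corrected rank variance), Šidák adjustment
  `p_adj = 1 − (1 − p)^m`.  Tables also report raw mean differences with
  pooled-variance normal confidence intervals at the Šidák-adjusted
  simultaneous level; the significance flag follows the rank-based p.  The
  same-PEEP ascending-vs-descending couples are the restricted pair set of
  the per-limb grouping.
* **Ansari–Bradley** implemented in-package: symmetric scores (mid-scores
  on ties) on the pooled, by-default median-centered samples; exact null by
  dynamic-programming enumeration for pooled n ≤ 20 without ties, otherwise
  a finite-population normal approximation (tie-aware; continuity
  correction when untied).  `alternative="greater"` means the first sample
  is more dispersed (small score sums).  Median-centering guards the scale
  test against location differences at the cost of mild conservatism
  (empirically ~0.03 attained level at nominal 0.05 for n = 10 per group);
  the null-calibration checks therefore run on the exchangeable
  (uncentered) null, where the one-sided exact test at n = 10 vs 9 attains
  size 0.0500 exactly.  scipy's implementation serves only as an
  independent cross-check in the tests.
* **Wilcoxon signed-rank** (Q2) via scipy, exact for small n, verified
  against full sign-flip enumeration.  Because breaths are not naturally
  paired across PEEP levels, Q2 pairs them by within-level order truncated
  to the common length — a pragmatic convention, flagged here.
* **Polynomial regressions** (degrees 1–3) by least squares on the
  Vandermonde design with the overall F-test; verified against statsmodels.
* α = 0.05 throughout, configurable.  TV enters the battery in litres.

## 5. Problem sizes and determinism

The default study is the full protocol: 11 PEEP steps × 100 s dynamic CT at
20 Hz (2,000 frames/step) with 102 s of 200 Hz waveforms per step — about
1,000 analyzed breaths — and completes in well under a minute on one CPU.
The analysis scripts accept `--quick` (30 s acquisitions) for interactive
use.  Every random draw descends from a single seed through
`numpy.random.SeedSequence` spawning, so identical seeds give bit-identical
waveforms, frames, and tables; the per-step child seeds are reduced
modulo 2³¹.

## 6. Known limitations

* Single-compartment, time-invariant mechanics: no intra-breath R/D–
  mechanics feedback (recruitment does not change Ers within the
  simulator), no flow-dependent resistance, no expiratory muscle activity.
* The recruiting-pressure construction (inspiratory resistive term, elastic
  floor) is a phantom design, not a validated micromechanical model; it
  exists to give the analysis a controllable, hysteretic target with the
  right qualitative PEEP dependence.
* Frame-timing sensitivity: at breathing rates near 95/min a 20 Hz frame
  clock samples each breath only ~12 times, and measured R/D at ZEEP
  depends noticeably on the selected frames.  The frame-sampled ground
  truth quantifies, but does not remove, this effect.
* Wilcoxon pairing in Q2 (order-based) and the %eeLV denominator choice are
  conventions; both alternatives are computable with the exposed flags.
* The Ansari–Bradley exact path is disabled in the presence of ties
  (mid-score approximation is used and marked in the output).
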