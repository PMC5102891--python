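# Methods

This note documents the models, parameters and design choices behind
`lamsync`, and what validation on synthetic data does and does not
establish about real recordings.

## The measurement problem

Under stepped isoflurane anesthesia the cortical field potential moves
through three stereotyped states: *suppression* (a near-flat trace at
deep anesthesia), *burst/suppression* (a suppressed trace interrupted by
1–3 s bursts of 4–12 Hz activity recurring roughly 1–12 times per
minute — a hyperexcitable state), and continuous high-amplitude
*slow-wave* (1–4 Hz) activity at light anesthesia.  In a brain with a
focal cortical malformation (the freeze-lesion microgyrus model),
burst/suppression appears at higher doses than in controls, and burst
activity recorded across a laminar probe loses its normal
cortico–subcortical synchrony near the lesion: subcortical channels flip
anti-phase to the cortex, the flip strengthening with proximity to the
malformation.  Unanesthetized animals with the lesion additionally show
7–9 spikes/s spike-wave discharges during slow-wave sleep.  The package
quantifies all three phenomena from multichannel extracellular
recordings and single-channel EEG.

## Synthetic-data generator

The generator produces the signal structure the analysis assumes, with
ground-truth labels, and its defaults encode the emulated study
conditions.

**Laminar recordings.**  A single latent burst source is mixed into all
channels: bursts appear near-simultaneously over the whole probe depth
with no focal layer of origin, so a shared source is the appropriate
model.  Each burst is one dominant sinusoid plus 1–3 weak partials
drawn from 5–11 Hz under a Tukey (flat-top) envelope with mild 1–2 Hz
modulation; the dominant-carrier construction avoids deep beat nulls
that would make a single physiological burst look like several to an
envelope detector, and the carrier margin keeps modulation sidebands
inside the 4–12 Hz band.  Inter-onset intervals are gamma(shape 2) with
mean 60/`burst_rate_per_min` s; durations are lognormal
(mean 2.0 s, SD 0.5 s, clipped to 0.5–4 s).  Key amplitudes, as
multiples of the 5 µV suppressed noise floor: bursts ×10, slow-wave
×8, the 1–4 Hz background during burst/suppression ×0.3.  The
background is deliberately below the burst-detection floor — raising it
to the noise SD makes the fixed envelope thresholds fire on background
alone, which is not the regime "low-amplitude delta background"
describes.

Channel *i* carries `gain_i × mix_i × source + noise`.  The gain vector
has a jump (default ×2) at the cortex/subcortex boundary (first
subcortical channel, default 13), reproducing the abrupt amplitude
change used as a physiological depth marker.  The mixing coefficient is
+1 for cortical channels and `inversion_alpha` ∈ [−1, +1] for
subcortical ones; α = −1 is a full instantaneous phase reversal
(sign-mixing, not a delay, because the anti-phase relation is observed
at zero lag).  When a lesion distance is supplied, α follows the
monotone default map `α(d) = clip(d/1200 − 1, −1, +1)`: full reversal
at the lesion, zero crossing at 1200 µm (the range over which strong
negative correlations occur), in-phase beyond 2400 µm.  Multi-unit
spikes are Poisson (20 Hz in-burst, 2 Hz out-of-burst per channel,
1 ms refractory); biphasic waveforms are injected into the trace only
when the sampling rate supports the 300–3000 Hz band (≥6 kHz) — spike
times are always in the ground truth.

**EEG days.**  Sleep stages follow a semi-Markov chain
(ActiveWake → QuietWake → NREM ⇄ REM …) with exponential dwell times
(base 120 s, scaled per stage).  NREM epochs carry strong 1–4 Hz and
mild 10–16 Hz content, REM strong 5.5–8 Hz with low delta, wake
low-amplitude broadband; movement activity is large only in ActiveWake.
SWDs are placed only inside NREM runs, as regular spike trains (sharp
negative Gaussians riding a wave at the spike frequency) at 8 spikes/s
for 2 s, amplitude 200 µV ≈ 6× the NREM background SD; the event count
is Poisson at `swd_rate_per_hour` over the recording.

Determinism: identical `(config, seed)` give bit-identical output; the
cohort pipeline derives per-animal/per-session seeds from the master
seed via `numpy.random.SeedSequence`.

## Analysis stages and numerical choices

**Filters.** 4th-order Butterworth applied forward–backward
(`sosfiltfilt`) — the filter family and order are not dictated by the
measurement chain being emulated, but zero phase is essential so that
synchrony lags are not filter artifacts.  Edge effects are confined to
roughly the first/last 100 ms by odd-reflection padding.  The notch is
a Q = 30 IIR at 60 Hz.

**Spectra.**  Welch average of Hann-windowed 2 s segments, 50% overlap,
zero-padded to a ≤0.01 Hz grid and density-normalized (integral over
[0, Nyquist] ≈ variance).  A literal sub-millihertz bin is not
attainable from a 2 s sample by raw FFT; zero-padding preserves the
stated 1–20 Hz integration and overlap while remaining computable, and
since every group comparison is ratio-based the normalization choice
cancels.  σ and β band edges (12–15, 15–20 Hz) are the conventional
rodent values and are configurable.  Band powers are trapezoidal
integrals with the density interpolated at the exact band edges, so the
five bands tile [1, 20) and sum to the total.

**Burst detector.**  Envelope = RMS in 100 ms sliding windows; baseline
= 10th percentile of the envelope; onset above 3× baseline, offset
below 1.5×; gaps < 0.2 s merged, events < 0.3 s discarded.  The
detector replaces what is classically scored by eye; all five constants
are keyword arguments.  On pure noise the 100 ms RMS concentrates
tightly around σ, so 3× the 10th percentile is effectively never
crossed (measured false positives ≈ 0.05/min).

**State labels** are assigned per 10 s epoch (an invented resolution —
states are classically reported per recording).  Slow-wave is declared
when the envelope exceeds the offset threshold for >70% of the epoch:
event-coverage fraction systematically under-measures continuous
slow-wave activity because the short RMS window dips at every 1–4 Hz
cycle null, whereas the high-amplitude time fraction captures
"continuous activity without suppression gaps" directly.  Suppression
requires a burst fraction < 0.05 *and* a median envelope < 2× baseline;
everything else is burst/suppression.  One labelling ambiguity is
intrinsic: a 10 s epoch inside a burst/suppression segment that happens
to contain no burst (probability e^{−rate×10/60}; ≈ 0.31 at 7/min) is
locally indistinguishable from suppression.  Accuracy figures are
therefore pooled over seeds, and sit near 92% under the default regime.

**Synchrony.**  Correlograms are per-lag Pearson correlations of the
overlapping extents over ±0.3 s, one bin per sample.  The fast path
computes cross-products by FFT and per-lag means/variances by
cumulative sums; a brute-force per-lag implementation is retained and
agrees to ≤1e−10 (a standing test).  The group-level "cross-correlation
value" of a channel is its zero-lag correlation with cortical channel 5
(granular-layer reference); the peak value and lag are reported
alongside, with a positive lag meaning the test channel lags the
reference.  Profiles are computed on concatenated burst segments when
bursts are present (the phenomenon of interest), otherwise on the whole
window; the choice is recorded in the profile metadata.  Phase-reversed
channels are those at or below a −0.3 zero-lag threshold.

**MUA.**  Noise σ = median(|x|)/0.6745; spikes are negative-going
crossings of 4.5 σ, peak-aligned, 1 ms refractory.  No spike sorting:
the quantity of interest is multi-unit burst coupling (in/out rate
ratio), not unit identity.

**Sleep staging.**  Per 2 s epoch the five band powers are computed by
Hann periodogram, log-transformed, and z-scored across the recording —
the log stabilizes the chi-square sampling noise of short-epoch
spectral estimates and separates the stage modes far more cleanly than
raw power.  Rules in priority order: ActiveWake on movement; REM when
θz > +0.5 with δz < 0 and σz < 0; NREM when δz > +0.5; else QuietWake.
The movement cutoff is the 75th percentile of integrated activity,
guarded at both ends: a mostly-moving recording (median above an
absolute floor of 1 activity unit) uses the floor so all moving epochs
flag, and a mostly-quiet one raises the cutoff above the sensor-noise
tail (20× median).  All thresholds are operational stand-ins for visual
scoring and are keyword-exposed.

**SWD detector.**  Candidate spikes exceed 4× a rolling 30 s background
SD; the signal is clipped at 4× a global MAD sigma before the rolling
variance so discharges do not inflate their own threshold.  Spikes
chain into events when consecutive intervals stay within [1/12, 1/4] s
(instantaneous 4–12 Hz); chains closer than 1 s are merged *before* the
≥4-spike / ≥0.5 s filters, so a single missed spike cannot split one
discharge into two.  An event's duration is its spike span plus one
mean inter-spike interval (a train of n spikes spans n−1 intervals), so
the spike rate of a regular train is recovered exactly.

**Statistics.**  The incidence of burst/suppression is analysed as
survival over the ordered dose axis 3.0→2.0→1.0→0.5% (steps 1–4), with
animals that never burst censored at the last step; estimation and the
log-rank test (with the discrete ties correction) come from lifelines,
cross-checked in tests against a hand-worked O−E implementation over
exhaustive label assignments.  Factorial ANOVA uses Type-III sums of
squares with sum contrasts (statsmodels), appropriate for the
unbalanced 8-vs-9 cohort, with the empty-cell check naming the missing
cell.  Holm–Šidák uses statsmodels' step-down implementation, verified
against hand-computed stepwise thresholds.  Animals are the unit of
analysis in the cohort pipeline (one record per animal per dose).

## Cohort pipeline defaults

8 control and 9 freeze-lesion animals, four 60 s sessions each at
1 kHz (a deliberate scale-down from acquisition-grade 20 kHz; every
analysis parameter is expressed in physical units so the rate is
transparent, and the 1–100 Hz LFP band is unaffected).
Burst/suppression onset: 2.0% isoflurane (70%) or 1.0% (30%) for
lesioned animals; 0.5% (75%) or never (censored, 25%) for controls —
yielding median onsets of 2.0% and 0.5%.  Lesion distances are uniform
over 200–2400 µm with ±100 µm per-session repositioning jitter, and
lesioned bursts carry √3.7 × the control source amplitude so the
near-lesion subcortical power contrast is ≈3.7-fold.  With these
defaults the pipeline reproduces the qualitative study contrasts
(earlier onset dose, negative near-lesion subcortical synchrony,
positive distance–synchrony correlation) deterministically under a
fixed seed.

## What passing tests do and do not show

The generator's bursts are sinusoid mixtures with smooth envelopes,
noise is Gaussian and stationary, the phase reversal is exact
sign-mixing, and sleep stages have cleanly separated spectral modes.
Real recordings contain movement and electrode artifacts, non-stationary
noise floors, volume-conduction mixtures, partial/lagged phase
relationships and ambiguous stage transitions.  Recovery on synthetic
data therefore validates the *implementations* (thresholds behave as
specified, estimators are unbiased in-model, statistics match their
analytic forms) — it does not certify detector performance on real
data, where the config-exposed constants are expected to need
recalibration.

## Known limitations

- No spike sorting, coherence/phase-spectrum analysis, spatial
  interpolation between contacts, or laminar source localization.
- The EDF container quantizes to 16 bits over each channel's range
  (exact for integer-valued µV signals; otherwise within half a
  quantization step).
- The SWD and burst detectors assume a roughly stationary background
  within their baseline windows (30 s and the whole recording,
  respectively).
- Multi-unit waveforms are only injected at sampling rates ≥ 6 kHz;
  at the 1 kHz test rate spike analysis runs on ground-truth times.
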