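# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order data flows through it.

## Stimulus construction

**Tonebursts.** Five octave-spaced frequencies (500, 1000, 2000, 4000,
8000 Hz).  The burst envelope and length are configurable; the default is
a 5-cycle Blackman-windowed sine, the common choice for frequency-specific
ABR work.  Duration is `n_cycles / frequency`, so bursts span 10 ms at
500 Hz down to 0.625 ms at 8 kHz.  The synthesized burst is mean-removed
(zero DC) and scaled by peak equivalence.

**Digital level convention.** There is no acoustic calibration in a pure
software pipeline, so levels are defined against a stated convention: a
full-scale sinusoid (peak 1.0) is 110 dB SPL.  A toneburst "at L dB peSPL"
has its waveform peak equal to the peak of a sinusoid at L dB SPL
(default 75 dB peSPL); noise "at L dB SPL" is scaled to that sinusoid's
RMS (defaults 69 dB SPL, with 72 dB — exactly +3 dB of gain — as the
stronger alternative).  These are conventions, not physical claims; all
level-dependent logic (the 3 dB step, peak equivalence within 0.1 dB) is
exercised in the tests.

**Impulse trains.** Timing is a homogeneous Poisson process (rates 20, 40
or 100 stimuli/s per frequency), with no dead time: overlapping bursts
simply sum.  Event times are quantized to the 48 kHz stimulus grid
(coincident events merge).  Exactly half of the impulses are sign-flipped
(rarefaction/condensation), the extra impulse of an odd count getting a
random sign, so any stimulus-proportional electrical artifact cancels in
the rectified average; the residual is bounded by 1/n.

**Maskers.** Pink (1/f power) noise is generated by spectral shaping,
scaled to its nominal level *before* filtering — so the passband spectrum
level is identical across cutoff conditions — then high-passed with an
8th-order Butterworth applied forward-backward (zero phase).  The design
requirement is steep attenuation, verified by Welch PSD: > 60 dB one
octave below the cutoff.  Sixty independent 1 s tokens per condition are
supported, with seeded uniform token pairing per trial.

**Condition grids.** Parallel masker cutoffs span 250–16,000 Hz in half
octaves (13 conditions); serial cutoffs span half to four times the test
frequency (7 conditions).  Grid frequencies are labeled by integer
rounding of 250·2^(k/2) (354, 707, 1414, …).  Derived bands are labeled
by the geometric mean of their cutoff pair snapped to that grid.  The
session plan reproduces the arithmetic of the recording protocol: the 7
serial conditions for the two serial test frequencies share presentation
slots (one frequency per ear), giving 13 + 7 = 20 masker conditions × 3
rates; 4 sessions × 150 min = 600 min total, hence 10 min per condition.

## Synthetic EEG forward model

The simulator is phenomenological and entirely the package's own: no
parameter value is a measured quantity, and passing tests show the
*pipeline* behaves correctly under the model's assumptions, not that real
ears behave like the model.

* The cochlea is the half-octave grid of 13 bands (250–16,000 Hz).  A
  toneburst excites bands by a log-frequency Gaussian centred on its
  frequency: σ = 0.5 octaves apically and 0.5·(1 + basal_skew) basally
  (default skew 1.0), encoding the asymmetric basal spread of excitation
  at high levels.
* Each band contributes a wave-V-like kernel — one cosine cycle (4 ms
  period) under a 1 ms-σ Gaussian, truncated at ±2 ms — with latency
  `5.0 + 7.0·(CF/250)^−0.4` ms, strictly decreasing in characteristic
  frequency (12 ms at 250 Hz to ~6.3 ms at 16 kHz).  Only monotonicity
  and rough scale matter for the analyses.
* On-frequency peak amplitude is 150 nV at 20 stimuli/s (wave V sums to a
  few hundred nV, typical of adult ABRs); amplitude adapts as
  `(rate/20)^−0.3`.
* High-pass masking multiplies excitation of bands at or above the cutoff
  by `masking_residual` ε (default 0.05, reflecting the empirically
  incomplete masking of real recordings; ε = 0 gives perfect masking, and
  the 250 Hz cutoff then silences the response entirely).
* Under parallel presentation, off-frequency excitation is multiplied by
  `1 − parallel_suppression·rate/100` (default suppression 0.6): the
  other trains act as maskers, more effectively at higher rates.  This
  one term generates the qualitative serial-vs-parallel predictions the
  acceptance checks probe.
* Background noise (default pink, 2 µV broadband — a quiet, low-impedance
  recording) is seeded independently of the stimulus ensemble, so
  recordings that differ only in stimuli share their noise exactly; this
  makes superposition testable.  Per-trial noise SD is scaled by a
  log-normal draw (σ = 0.5 on the log-variance), which is what makes
  inverse-variance trial weighting consequential.  An optional line
  component exercises the notch filters.

What the model does **not** emulate: biophysical cochlear mechanics or
auditory-nerve dynamics, waves I–IV morphology, artifacts other than
stimulus-proportional leakage, electrode or montage effects, and
non-stationary subject state.  Conclusions about real EEG require real
EEG through the same EDF path.

## Response extraction

Raw EEG (10 kHz) is filtered causally: first-order Butterworth bandpass
30–2000 Hz, then IIR notches (5 Hz bandwidth) at odd multiples of 60 Hz
up to 2500 Hz (21 notches).  Causal filtering shifts latencies slightly
but identically across conditions, so within-study comparisons are
unaffected.  Impulse indices are mapped to the EEG grid by
`floor(i·fs_eeg/fs_stim + 0.5)` (half-up tie-break), rectified to unit
magnitude; collisions keep a single unit impulse and are logged.

Each 1 s token is a trial.  Per trial, the impulse train is zero-padded
by 1 s per side and the EEG padded with its surrounding recording (zeros
past the ends), the cross-correlation is computed by FFT and normalized
by the trial's impulse count, and lags −500…+600 ms are stored.  The pad
exceeds the largest stored lag, so the circular correlation never wraps
data into the window — extraction of a token is bit-identical whether the
whole session or just the token plus pad is supplied.  The stored
prestimulus half-second exists to hold the forty 12 ms noise windows of
the size estimator.  Trials are combined with weights proportional to the
inverse variance of each trial's *raw* (unfiltered) EEG, normalized to
sum to one.

## Derived bands and read-outs

Responses whose cutoffs sit one octave apart (two half-octave grid steps)
are subtracted, higher minus lower.  Non-overlapping derived bands
telescope exactly to the widest-band difference — an algebraic identity
used as a machine-precision regression check.

**Response size.**  σ²_{R+N} is the variance in the 12 ms window centred
on the expected latency; σ²_N is the mean variance of 40 contiguous
non-overlapping 12 ms windows ending at −12 ms (the gap at zero avoids
filter-edge effects).  Since response and noise are independent, the
difference estimates the response variance; the signed root
`sign(v)·√|v|` keeps negative, over-corrected estimates representable so
downstream statistics see an unbiased, zero-centred null.  The window
centre is the mean of the two parent latencies taken from *grand-average*
waveforms (individual subjects do not always show a response); a band
whose parents lack a grand-average peak is excluded and flagged.

**Wave-V picking.**  Peak picking is manual in clinical practice; this
package substitutes an automated surrogate, a deliberate deviation with
documented, configurable parameters.  The pick is the largest positive
peak in a physiologic search window (default 4–20 ms, widened to 24 ms
for 500 Hz stimuli or cutoffs ≤ 500 Hz) that is followed within 8 ms by a
trough and whose topographic prominence exceeds 6 prestimulus standard
deviations.  Band-limited noise is strongly oscillatory, so a window
extremum reaches 4–5 SD prominence by chance; the 6 SD default was
calibrated on noise-only waveforms to hold the false-pick rate near 1%
(≤ 5%) while detecting peaks of ~4× the residual noise essentially
always.  Returning no pick is a valid outcome and propagates as an
excluded condition.

## Problem sizes and determinism

All randomness flows from one master seed through `SeedSequence` spawn
keys (per condition × subject × component), logged with each run; equal
configurations produce byte-identical output tables.  The shipped
analysis runs the study at desk scale — 6 subject seeds and 2 of the
protocol's 10 min per condition — which leaves the smallest effects (the
serial-parallel gap at 20 stimuli/s, a few nV) near their measurement
noise, exactly as the derived-band method's halved SNR predicts.  The
acceptance script uses 12 subject seeds (the protocol's cohort size) at
2 min per condition.  Monte-Carlo checks use 100–500 seeds as noted in
each test.

## Known limitations

* The EDF writer emits plain EDF (16-bit) with 1 s records; recordings
  are padded to whole seconds on write.
* The forward model's parallel suppression is a single multiplicative
  factor; it does not model suppression asymmetry along the cochlea or
  level dependence.
* Latency-based analyses inherit the causal filters' small constant
  delay; absolute latencies are therefore model-convention quantities.
* The exported tables are deliberately statistics-free; mixed-effects
  modeling is left to external tools.
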