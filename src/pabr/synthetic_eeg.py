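"""Parametric forward simulation of pABR EEG.

Generates single-channel EEG containing wave-V-like responses whose
amplitude and latency depend on cochlear place, so the whole extraction
and derived-band pipeline can be exercised against known ground truth.

The model is phenomenological, not biophysical.  The cochlea is a
half-octave grid of bands; a toneburst excites bands around its frequency
with an asymmetric spread (wider toward high characteristic frequencies,
mimicking basal spread of excitation at high levels).  Each band
contributes a stereotyped wave-V-like kernel whose latency decreases with
characteristic frequency.  High-pass masking noise suppresses bands at or
above its cutoff (a residual ``masking_residual`` fraction survives,
emulating incomplete masking); response amplitude adapts with stimulus
rate; and under parallel presentation the other tonebursts mutually mask
off-frequency excitation (``parallel_suppression``), increasingly so at
higher rates.  None of these parameter values come from measured data —
they are the simulator's own, chosen to be physiologically plausible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .response_extraction import downsample_impulses
from .stimulus import ImpulseTrain, half_octave_steps

__all__ = [
    "CochlearBandModel",
    "NoiseModel",
    "EEGRecording",
    "wave_v_kernel",
    "simulate_condition",
]

EEG_FS_HZ = 10_000.0


@dataclass(frozen=True)
class CochlearBandModel:
    """Tonotopic excitation, latency, adaptation and masking parameters.

    Parameters
    ----------
    band_centers_hz
        Characteristic frequencies of the simulated cochlear bands
        (half-octave grid 250-16,000 Hz).
    peak_amplitude_v
        Wave-V kernel peak contributed by the band at the stimulus
        frequency, at 20 stim/s, serial (volts).
    spread_octaves_apical, spread_octaves_basal
        Gaussian widths (in octaves) of the excitation pattern below and
        above the stimulus frequency; ``basal = apical * (1 + basal_skew)``
        by default, giving the asymmetric basal spread.
    latency_offset_ms, latency_scale_ms, latency_exponent
        ``latency(cf) = offset + scale * (cf / 250)**(-exponent)`` —
        strictly decreasing in characteristic frequency.
    adaptation_exponent
        Amplitude scales as ``(rate / 20)**(-adaptation_exponent)``.
    parallel_suppression
        Fraction of off-frequency excitation removed under parallel
        presentation at 100 stim/s; scales linearly with rate
        (``1 - parallel_suppression * rate / 100``).
    masking_residual
        Fraction of excitation surviving in bands at or above the
        high-pass-noise cutoff (0 = perfect masking).
    """

    band_centers_hz: tuple[int, ...] = tuple(half_octave_steps(250.0, 13))
    peak_amplitude_v: float = 150e-9
    basal_skew: float = 1.0
    spread_octaves_apical: float = 0.5
    latency_offset_ms: float = 5.0
    latency_scale_ms: float = 7.0
    latency_exponent: float = 0.4
    adaptation_exponent: float = 0.3
    parallel_suppression: float = 0.6
    masking_residual: float = 0.05

    @property
    def spread_octaves_basal(self) -> float:
        return self.spread_octaves_apical * (1.0 + self.basal_skew)

    def latency_ms(self, cf_hz: float) -> float:
        return self.latency_offset_ms + self.latency_scale_ms * (cf_hz / 250.0) ** (
            -self.latency_exponent
        )

    def excitation(self, stim_frequency_hz: float) -> np.ndarray:
        """Per-band excitation amplitudes for one toneburst frequency."""
        d = np.log2(np.asarray(self.band_centers_hz, dtype=float) / stim_frequency_hz)
        sigma = np.where(d < 0, self.spread_octaves_apical, self.spread_octaves_basal)
        return self.peak_amplitude_v * np.exp(-0.5 * (d / sigma) ** 2)

    def effective_excitation(
        self,
        stim_frequency_hz: float,
        rate_per_s: float,
        paradigm: str,
        hpn_cutoff_hz: float | None,
    ) -> np.ndarray:
        """Excitation after adaptation, parallel suppression and masking."""
        a = self.excitation(stim_frequency_hz) * (rate_per_s / 20.0) ** (
            -self.adaptation_exponent
        )
        centers = np.asarray(self.band_centers_hz, dtype=float)
        if paradigm == "parallel":
            off = ~np.isclose(centers, stim_frequency_hz, rtol=0.05)
            a[off] *= 1.0 - self.parallel_suppression * rate_per_s / 100.0
        if hpn_cutoff_hz is not None:
            a[centers >= 0.99 * hpn_cutoff_hz] *= self.masking_residual
        return a


@dataclass(frozen=True)
class NoiseModel:
    """Additive EEG background noise with per-trial variance heterogeneity.

    ``base_std_v`` is the broadband standard deviation (volts); the
    per-trial standard deviation is multiplied by a log-normal draw
    (``sigma_log`` on the log-variance), which makes inverse-variance
    trial weighting consequential.  An optional power-line component at
    ``line_hz`` can be added to exercise the notch filters.
    """

    spectrum: str = "pink"
    base_std_v: float = 2e-6
    sigma_log: float = 0.5
    line_hz: float | None = None
    line_amplitude_v: float = 0.0

    def __post_init__(self) -> None:
        if self.spectrum not in ("pink", "white"):
            raise ValueError("noise spectrum must be 'pink' or 'white'")
        if self.base_std_v < 0:
            raise ValueError("base_std_v must be nonnegative")


@dataclass
class EEGRecording:
    """A sampled voltage trace with trial bookkeeping.

    ``ground_truth`` (simulated recordings only) carries the effective
    per-band amplitudes and latencies that produced the trace.
    """

    samples: np.ndarray
    fs_hz: float
    trial_boundaries: np.ndarray
    ground_truth: dict | None = None

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


def wave_v_kernel(latency_ms: float, amplitude: float, fs_hz: float = EEG_FS_HZ) -> np.ndarray:
    """Smooth biphasic wave-V surrogate peaking at ``latency_ms``.

    A single cosine cycle (4 ms period) under a Gaussian window (sigma
    1 ms), truncated to +/- 2 ms around the peak; the waveform starts at
    lag 0 and its maximum equals ``amplitude`` at the latency sample.
    """
    if latency_ms < 0:
        raise ValueError("latency must be nonnegative")
    half_width_ms = 2.0
    n = int(round((latency_ms + half_width_ms) * 1e-3 * fs_hz)) + 1
    t_ms = np.arange(n) / fs_hz * 1e3 - latency_ms
    k = amplitude * np.cos(2.0 * np.pi * t_ms / (2.0 * half_width_ms)) * np.exp(
        -0.5 * (t_ms / 1.0) ** 2
    )
    k[t_ms < -half_width_ms] = 0.0
    return k


def _background_noise(n: int, model: NoiseModel, fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    if model.base_std_v == 0:
        noise = np.zeros(n)
    elif model.spectrum == "white":
        noise = rng.standard_normal(n) * model.base_std_v
    else:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        shape = np.zeros_like(f)
        shape[1:] = 1.0 / np.sqrt(f[1:])
        noise = np.fft.irfft(spec * shape, n)
        noise *= model.base_std_v / noise.std()
    if model.line_hz and model.line_amplitude_v:
        t = np.arange(n) / fs_hz
        noise = noise + model.line_amplitude_v * np.sin(
            2.0 * np.pi * model.line_hz * t + rng.uniform(0, 2 * np.pi)
        )
    return noise


def simulate_condition(
    paradigm: str,
    rate_per_s: float,
    hpn_cutoff_hz: float | None,
    trains: dict[float, ImpulseTrain],
    band_model: CochlearBandModel | None = None,
    noise_model: NoiseModel | None = None,
    seed: int | None = None,
    test_frequency_hz: float | None = None,
    fs_hz: float = EEG_FS_HZ,
    trial_duration_s: float = 1.0,
) -> EEGRecording:
    """Forward-simulate one recording condition.

    The trace is the superposition, over active toneburst trains and
    cochlear bands, of the band kernels convolved with the (rectified,
    EEG-rate) impulse trains, plus background noise:

        y = sum_f sum_b A'[f, b] * (x_f (*) kernel(latency_b)) + noise

    where ``A'`` applies rate adaptation, parallel suppression of
    off-frequency terms, and high-pass masking.  Noise is seeded
    independently of the signal path, so recordings with different
    stimulus ensembles but the same seed share their noise exactly.
    """
    band_model = band_model or CochlearBandModel()
    noise_model = noise_model or NoiseModel()
    if paradigm not in ("parallel", "serial"):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if paradigm == "serial":
        if test_frequency_hz is None or test_frequency_hz not in trains:
            raise ValueError("serial paradigm requires a test frequency present in trains")
        active = {test_frequency_hz: trains[test_frequency_hz]}
    else:
        active = dict(trains)
    durations = {t.duration_s for t in active.values()}
    if len(durations) != 1:
        raise ValueError("all trains must share one duration")
    duration_s = durations.pop()
    n = int(round(duration_s * fs_hz))

    lo, hi = min(band_model.band_centers_hz), max(band_model.band_centers_hz)
    for f in active:
        if not (lo / 1.5 <= f <= hi * 1.5):
            raise ValueError(f"stimulus frequency {f} Hz outside the modeled cochlear bands")

    truth: dict = {
        "paradigm": paradigm,
        "rate_per_s": rate_per_s,
        "hpn_cutoff_hz": hpn_cutoff_hz,
        "seed": seed if isinstance(seed, (int, type(None))) else repr(seed),
        "band_centers_hz": list(band_model.band_centers_hz),
        "latencies_ms": [band_model.latency_ms(c) for c in band_model.band_centers_hz],
        "amplitudes_v": {},
    }
    y = np.zeros(n)
    for f, train in active.items():
        amps = band_model.effective_excitation(f, rate_per_s, paradigm, hpn_cutoff_hz)
        truth["amplitudes_v"][f] = amps.tolist()
        kernels = [
            wave_v_kernel(band_model.latency_ms(c), a, fs_hz)
            for c, a in zip(band_model.band_centers_hz, amps)
        ]
        resp = np.zeros(max(k.size for k in kernels))
        for k in kernels:
            resp[: k.size] += k
        impulses = np.zeros(n)
        eeg_idx = downsample_impulses(train, fs_hz, warn_on_collision=False)
        impulses[eeg_idx[eeg_idx < n]] = 1.0
        y += sps.fftconvolve(impulses, resp)[:n]

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    noise_rng, trial_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    noise = _background_noise(n, noise_model, fs_hz, noise_rng)
    trial_len = int(round(trial_duration_s * fs_hz))
    boundaries = np.arange(0, n, trial_len, dtype=np.int64)
    if noise_model.base_std_v > 0 and noise_model.sigma_log > 0:
        scales = np.exp(
            trial_rng.normal(0.0, noise_model.sigma_log, size=boundaries.size) / 2.0
        )
        truth["trial_noise_scales"] = scales.tolist()
        for b, s in zip(boundaries, scales):
            noise[b : b + trial_len] *= s
    y = y + noise
    return EEGRecording(samples=y, fs_hz=fs_hz, trial_boundaries=boundaries, ground_truth=truth)
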