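"""Parallel-ABR stimulus construction.

Builds the pieces of the parallel auditory brainstem response (pABR)
paradigm: brief windowed tonebursts at octave-spaced frequencies, Poisson
impulse trains that time them, summed multi-frequency stimulus tokens, and
high-pass pink-noise maskers for the derived-band procedure.

Digital level convention
------------------------
There is no physical calibration in this package.  Levels are defined
against a documented digital convention: a full-scale sinusoid (peak
amplitude 1.0) is ``FULL_SCALE_DB_SPL`` = 110 dB SPL.  A toneburst "at
L dB peSPL" is scaled so its waveform peak equals the peak of a sinusoid
at L dB SPL; noise "at L dB SPL" is scaled to the RMS of that sinusoid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FULL_SCALE_DB_SPL",
    "STANDARD_FREQUENCIES_HZ",
    "STANDARD_RATES_PER_S",
    "ToneburstSpec",
    "ImpulseTrain",
    "MaskerSpec",
    "ConditionGrid",
    "db_spl_peak",
    "db_spl_rms",
    "half_octave_steps",
    "nominal_frequency",
    "make_toneburst",
    "draw_impulse_train",
    "assemble_stimulus",
    "make_hpn_masker",
    "make_masker_tokens",
    "enumerate_conditions",
    "derived_band_center",
]

FULL_SCALE_DB_SPL = 110.0

#: Octave-spaced toneburst frequencies presented in parallel.
STANDARD_FREQUENCIES_HZ = (500, 1000, 2000, 4000, 8000)

#: Stimulus rates under test (tonebursts per second per frequency).
STANDARD_RATES_PER_S = (20, 40, 100)


def db_spl_peak(level_db_spl: float) -> float:
    """Peak amplitude of a sinusoid at ``level_db_spl`` under the digital convention."""
    return 10.0 ** ((level_db_spl - FULL_SCALE_DB_SPL) / 20.0)


def db_spl_rms(level_db_spl: float) -> float:
    """RMS of a sinusoid at ``level_db_spl`` under the digital convention."""
    return db_spl_peak(level_db_spl) / math.sqrt(2.0)


def half_octave_steps(start_hz: float, n_steps: int) -> list[int]:
    """Nominal half-octave frequency grid: ``round(start * 2**(k/2))``.

    Rounding to the nearest integer reproduces the conventional labels
    354, 707, 1414, 2828, 5657, 11314 Hz.
    """
    return [int(round(start_hz * 2.0 ** (k / 2.0))) for k in range(n_steps)]


def nominal_frequency(f_hz: float) -> int:
    """Snap a frequency to the nearest nominal half-octave grid value.

    The grid is anchored at 1000 Hz: {round(1000 * 2**(k/2)) : k integer}.
    """
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    k = round(2.0 * math.log2(f_hz / 1000.0))
    return int(round(1000.0 * 2.0 ** (k / 2.0)))


@dataclass(frozen=True)
class ToneburstSpec:
    """A brief windowed sinusoid used as a frequency-specific ABR stimulus."""

    frequency_hz: float
    n_cycles: int = 5
    envelope: str = "blackman"
    level_db_pespl: float = 75.0
    sample_rate_hz: float = 48_000.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be a positive integer")
        if self.envelope not in ("blackman", "hann", "cosine-squared"):
            raise ValueError(f"unknown envelope {self.envelope!r}")

    @property
    def duration_s(self) -> float:
        return self.n_cycles / self.frequency_hz


@dataclass(frozen=True)
class ImpulseTrain:
    """Timing record for one frequency's toneburst train.

    ``indices`` are 0-based sample indices at ``sample_rate_hz``;
    ``polarities`` hold the rarefaction/condensation sign of each toneburst.
    """

    indices: np.ndarray
    polarities: np.ndarray
    rate_per_s: float
    duration_s: float
    sample_rate_hz: float
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "polarities", np.asarray(self.polarities, dtype=np.int8))
        if self.indices.size != self.polarities.size:
            raise ValueError("indices and polarities must have equal length")
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")

    @property
    def n(self) -> int:
        """Number of stimuli (the normalizer of the deconvolution average)."""
        return int(self.indices.size)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


@dataclass(frozen=True)
class MaskerSpec:
    """High-pass filtered pink-noise masker for derived-band recording."""

    cutoff_hz: float | None
    spectrum: str = "pink"
    level_db_spl: float = 69.0
    filter_design: str = "butterworth order=8 zero-phase (sosfiltfilt)"
    sample_rate_hz: float = 48_000.0

    def __post_init__(self) -> None:
        if self.spectrum != "pink":
            raise ValueError("only pink masker noise is supported")
        if self.cutoff_hz is not None and self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive or None")


@dataclass(frozen=True)
class ConditionGrid:
    """The masker-cutoff grid for one paradigm (and test frequency, if serial)."""

    paradigm: str
    hpn_cutoffs_hz: tuple[int, ...]
    rates: tuple[int, ...] = STANDARD_RATES_PER_S
    test_frequency_hz: float | None = None
    tokens: int = 60
    token_duration_s: float = 1.0

    @property
    def n_conditions(self) -> int:
        return len(self.hpn_cutoffs_hz)


def make_toneburst(spec: ToneburstSpec, scale: float = 1.0) -> np.ndarray:
    """Synthesize a windowed toneburst scaled to its peSPL level.

    The waveform is a sine carrier under the spec'd envelope, mean-removed
    (zero DC) and scaled so its peak equals ``scale`` times the peak of a
    reference sinusoid at ``level_db_pespl``.
    """
    fs = spec.sample_rate_hz
    if spec.frequency_hz >= fs / 2.0:
        raise ValueError("unrepresentable toneburst: frequency at or above Nyquist")
    n = int(round(fs * spec.duration_s))
    t = np.arange(n) / fs
    carrier = np.sin(2.0 * np.pi * spec.frequency_hz * t)
    if spec.envelope == "blackman":
        win = np.blackman(n)
    elif spec.envelope == "hann":
        win = np.hanning(n)
    else:  # cosine-squared ramp over the full burst
        win = np.sin(np.pi * np.arange(n) / max(n - 1, 1)) ** 2
    w = carrier * win
    w = w - w.mean()
    peak = np.max(np.abs(w))
    if peak > 0:
        w = w / peak * db_spl_peak(spec.level_db_pespl)
    return w * scale


def draw_impulse_train(
    rate_per_s: float,
    duration_s: float = 1.0,
    seed: int | None = None,
    sample_rate_hz: float = 48_000.0,
) -> ImpulseTrain:
    """Draw a homogeneous Poisson impulse train with balanced polarities.

    Event times are Poisson with the given rate, quantized to sample
    indices (coincident events merge).  Exactly half of the impulses are
    assigned negative polarity (the extra impulse of an odd count gets a
    random sign), so rarefaction and condensation tonebursts cancel any
    stimulus-proportional electrical artifact in the average.
    """
    if rate_per_s < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    seed = seed if isinstance(seed, (int, np.integer)) else None
    n_events = rng.poisson(rate_per_s * duration_s)
    n_samples = int(round(duration_s * sample_rate_hz))
    times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    indices = np.unique(np.minimum((times * sample_rate_hz).astype(np.int64), n_samples - 1)) if n_events else np.empty(0, dtype=np.int64)
    n = indices.size
    n_neg = n // 2 + (1 if (n % 2 == 1 and rng.random() < 0.5) else 0)
    polarities = np.ones(n, dtype=np.int8)
    polarities[:n_neg] = -1
    rng.shuffle(polarities)
    return ImpulseTrain(
        indices=indices,
        polarities=polarities,
        rate_per_s=rate_per_s,
        duration_s=duration_s,
        sample_rate_hz=sample_rate_hz,
        seed=seed,
    )


def _convolve_train(train: ImpulseTrain, toneburst: np.ndarray) -> np.ndarray:
    out = np.zeros(train.n_samples)
    impulses = np.zeros(train.n_samples)
    np.add.at(impulses, train.indices, train.polarities.astype(float))
    if train.n:
        out = sps.fftconvolve(impulses, toneburst)[: train.n_samples]
    return out


def assemble_stimulus(
    trains: dict[float, ImpulseTrain],
    tonebursts: dict[float, np.ndarray],
    paradigm: str = "parallel",
    test_frequency_hz: float | None = None,
) -> np.ndarray:
    """Convolve each impulse train with its toneburst and combine.

    ``parallel`` sums the trains of every frequency; ``serial`` keeps only
    ``test_frequency_hz`` in isolation (the train itself is identical to
    the one embedded in the parallel ensemble).
    """
    if paradigm not in ("parallel", "serial"):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    fss = {t.sample_rate_hz for t in trains.values()}
    durs = {t.duration_s for t in trains.values()}
    if len(fss) > 1 or len(durs) > 1:
        raise ValueError("all impulse trains must share sample rate and duration")
    if paradigm == "serial":
        if test_frequency_hz is None or test_frequency_hz not in trains:
            raise ValueError("serial paradigm requires a test frequency present in trains")
        freqs = [test_frequency_hz]
    else:
        freqs = list(trains)
    n_samples = next(iter(trains.values())).n_samples
    token = np.zeros(n_samples)
    for f in freqs:
        token += _convolve_train(trains[f], tonebursts[f])
    return token


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance pink (1/f power) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def make_hpn_masker(
    spec: MaskerSpec, duration_s: float = 1.0, seed: int | None = None
) -> np.ndarray:
    """Generate one high-pass pink-noise masker token.

    The pink noise is scaled to ``level_db_spl`` (RMS convention) before
    filtering, so the passband spectrum level is the same at every cutoff.
    The high-pass is an 8th-order Butterworth applied forward-backward
    (zero phase), giving > 60 dB attenuation one octave below the cutoff.
    """
    fs = spec.sample_rate_hz
    if spec.cutoff_hz is not None and spec.cutoff_hz >= fs / 2.0:
        raise ValueError("masker cutoff at or above Nyquist")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    x = _pink_noise(n, rng) * db_spl_rms(spec.level_db_spl)
    if spec.cutoff_hz is not None:
        sos = sps.butter(8, spec.cutoff_hz, btype="highpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    return x


def make_masker_tokens(
    spec: MaskerSpec, n_tokens: int = 60, duration_s: float = 1.0, seed: int | None = None
) -> list[np.ndarray]:
    """Generate independent masker tokens from one parent seed."""
    children = np.random.SeedSequence(seed).spawn(n_tokens)
    return [make_hpn_masker(spec, duration_s, np.random.default_rng(c)) for c in children]


def enumerate_conditions(
    paradigm: str,
    test_frequency_hz: float | None = None,
    rates: tuple[int, ...] = STANDARD_RATES_PER_S,
) -> ConditionGrid:
    """Enumerate the half-octave masker-cutoff grid for one paradigm.

    Parallel: cutoffs span 250-16,000 Hz (13 conditions).  Serial: cutoffs
    span one octave below to two octaves above the test frequency
    (7 conditions).
    """
    if paradigm == "parallel":
        cutoffs = half_octave_steps(250.0, 13)
        return ConditionGrid(paradigm, tuple(cutoffs), tuple(rates))
    if paradigm == "serial":
        if test_frequency_hz is None:
            raise ValueError("serial paradigm requires a test frequency")
        if test_frequency_hz not in STANDARD_FREQUENCIES_HZ:
            raise ValueError(f"test frequency must be one of {STANDARD_FREQUENCIES_HZ}")
        cutoffs = half_octave_steps(test_frequency_hz / 2.0, 7)
        return ConditionGrid(paradigm, tuple(cutoffs), tuple(rates), test_frequency_hz)
    raise ValueError(f"unknown paradigm {paradigm!r}")


def derived_band_center(cutoff_low_hz: float, cutoff_high_hz: float) -> int:
    """Nominal center frequency of a derived band, by geometric mean.

    The octave-wide region between two masker cutoffs is labeled by the
    geometric mean of the cutoffs, snapped to the nominal half-octave grid
    (e.g. the 707-1414 Hz band is denoted 1000 Hz).
    """
    if cutoff_low_hz <= 0 or cutoff_high_hz <= 0:
        raise ValueError("cutoffs must be positive")
    ratio = cutoff_high_hz / cutoff_low_hz
    if not (0.99 <= ratio / 2.0 <= 1.01):
        raise ValueError("derived bands require cutoffs one octave apart")
    return nominal_frequency(math.sqrt(cutoff_low_hz * cutoff_high_hz))
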