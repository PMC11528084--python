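"""Stimulus construction: tonebursts, Poisson trains, maskers, condition grids."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from pabr.stimulus import (
    ConditionGrid,
    ImpulseTrain,
    MaskerSpec,
    ToneburstSpec,
    assemble_stimulus,
    db_spl_peak,
    derived_band_center,
    draw_impulse_train,
    enumerate_conditions,
    make_hpn_masker,
    make_toneburst,
    nominal_frequency,
)

FS = 48_000.0


class TestToneburst:
    def test_length_and_spectral_peak(self):
        w = make_toneburst(ToneburstSpec(2000.0, n_cycles=5, sample_rate_hz=FS))
        assert w.size == 120  # 5 cycles / 2000 Hz at 48 kHz
        f = np.fft.rfftfreq(w.size * 16, 1 / FS)
        peak_hz = f[np.argmax(np.abs(np.fft.rfft(w, w.size * 16)))]
        assert abs(peak_hz - 2000.0) < 200.0
        assert abs(w.mean()) < 1e-12  # zero DC
        assert np.all(np.isfinite(w))

    def test_peak_matches_pespl_reference(self):
        # peak equals the peak of a 75 dB peSPL reference sinusoid within 0.1 dB
        w = make_toneburst(ToneburstSpec(4000.0, level_db_pespl=75.0))
        ref_peak = db_spl_peak(75.0)
        assert abs(20 * np.log10(np.max(np.abs(w)) / ref_peak)) < 0.1

    def test_zero_scale_gives_silence(self):
        assert not np.any(make_toneburst(ToneburstSpec(1000.0), scale=0.0))

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError, match="unrepresentable"):
            make_toneburst(ToneburstSpec(24_000.0, sample_rate_hz=FS))

    @pytest.mark.parametrize("envelope", ["blackman", "hann", "cosine-squared"])
    def test_envelopes_start_and_end_quiet(self, envelope):
        w = make_toneburst(ToneburstSpec(500.0, envelope=envelope))
        edge = max(abs(w[0]), abs(w[-1]))
        assert edge < 0.01 * np.max(np.abs(w))


class TestImpulseTrain:
    def test_zero_rate_is_empty(self):
        t = draw_impulse_train(0.0, 1.0, seed=0)
        assert t.n == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            draw_impulse_train(-1.0, 1.0)

    def test_indices_strictly_increasing(self):
        t = draw_impulse_train(100.0, 10.0, seed=3)
        assert np.all(np.diff(t.indices) > 0)

    def test_polarity_split_exact_half(self):
        for seed in range(20):
            t = draw_impulse_train(40.0, 2.0, seed=seed)
            assert int(t.polarities.sum()) in (-1, 0, 1)
            if t.n % 2 == 0:
                assert t.polarities.sum() == 0

    def test_poisson_count_tail_bound(self):
        # count within rate*T +/- 3*sqrt(rate*T) in >= 99% of seeds
        mu = 40.0 * 60.0
        ok = sum(
            abs(draw_impulse_train(40.0, 60.0, seed=s).n - mu) <= 3 * np.sqrt(mu)
            for s in range(500)
        )
        assert ok / 500 >= 0.99

    def test_mean_count_converges(self):
        counts = [draw_impulse_train(20.0, 1.0, seed=s).n for s in range(400)]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 20.0) <= 3 * se


class TestAssemble:
    def _trains_and_bursts(self, seed0=0, duration=1.0):
        freqs = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)
        trains = {
            f: draw_impulse_train(40.0, duration, seed=seed0 + i, sample_rate_hz=FS)
            for i, f in enumerate(freqs)
        }
        bursts = {f: make_toneburst(ToneburstSpec(f, sample_rate_hz=FS)) for f in freqs}
        return trains, bursts

    def test_single_impulse_identity(self):
        burst = make_toneburst(ToneburstSpec(2000.0, sample_rate_hz=FS))
        train = ImpulseTrain(
            indices=np.array([1000]), polarities=np.array([1]),
            rate_per_s=1.0, duration_s=1.0, sample_rate_hz=FS,
        )
        token = assemble_stimulus({2000.0: train}, {2000.0: burst}, "serial", 2000.0)
        assert np.allclose(token[1000 : 1000 + burst.size], burst)
        assert np.allclose(token[:1000], 0.0, atol=1e-12)

    def test_parallel_with_one_train_equals_serial(self):
        trains, bursts = self._trains_and_bursts()
        empty = ImpulseTrain(
            indices=np.empty(0, dtype=int), polarities=np.empty(0, dtype=int),
            rate_per_s=0.0, duration_s=1.0, sample_rate_hz=FS,
        )
        only_2k = {f: (t if f == 2000.0 else empty) for f, t in trains.items()}
        par = assemble_stimulus(only_2k, bursts, "parallel")
        ser = assemble_stimulus(trains, bursts, "serial", 2000.0)
        np.testing.assert_array_equal(par, ser)

    def test_serial_train_identical_to_parallel_member(self):
        # the serial stimulus is the single train extracted from the ensemble
        trains, bursts = self._trains_and_bursts(seed0=7)
        ser = assemble_stimulus(trains, bursts, "serial", 500.0)
        alone = assemble_stimulus(
            {500.0: trains[500.0]}, {500.0: bursts[500.0]}, "parallel"
        )
        np.testing.assert_array_equal(ser, alone)

    def test_rms_grows_with_active_frequencies(self):
        trains, bursts = self._trains_and_bursts(seed0=11)
        par = assemble_stimulus(trains, bursts, "parallel")
        ser = assemble_stimulus(trains, bursts, "serial", 1000.0)
        assert np.sqrt(np.mean(par**2)) > np.sqrt(np.mean(ser**2))

    def test_mismatched_rates_rejected(self):
        trains, bursts = self._trains_and_bursts()
        bad = draw_impulse_train(40.0, 1.0, seed=9, sample_rate_hz=44_100.0)
        trains[500.0] = bad
        with pytest.raises(ValueError, match="sample rate"):
            assemble_stimulus(trains, bursts, "parallel")


class TestMasker:
    def test_highpass_attenuation_at_half_cutoff(self):
        x = make_hpn_masker(MaskerSpec(cutoff_hz=250.0), duration_s=4.0, seed=0)
        f, psd = sps.welch(x, fs=48_000.0, nperseg=16384)
        below = np.mean(psd[(f > 100) & (f < 150)])
        passband = np.mean(psd[(f > 900) & (f < 1100)])
        assert 10 * np.log10(passband / below) >= 60.0

    def test_fullband_pink_slope(self):
        x = make_hpn_masker(MaskerSpec(cutoff_hz=None), duration_s=8.0, seed=1)
        f, psd = sps.welch(x, fs=48_000.0, nperseg=8192)
        sel = (f >= 100) & (f <= 10_000)
        slope = np.polyfit(np.log2(f[sel]), 10 * np.log10(psd[sel]), 1)[0]
        assert -3.5 < slope < -2.5  # -3 dB per octave

    def test_levels_differ_by_exactly_3_db(self):
        lo = make_hpn_masker(MaskerSpec(cutoff_hz=None, level_db_spl=69.0), seed=2)
        hi = make_hpn_masker(MaskerSpec(cutoff_hz=None, level_db_spl=72.0), seed=2)
        ratio = np.linalg.norm(hi) / np.linalg.norm(lo)
        assert ratio == pytest.approx(10 ** (3 / 20), rel=1e-12)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_hpn_masker(MaskerSpec(cutoff_hz=24_000.0), seed=0)


class TestConditionGrids:
    def test_parallel_grid(self):
        grid = enumerate_conditions("parallel")
        assert grid.n_conditions == 13
        assert grid.hpn_cutoffs_hz[0] == 250 and grid.hpn_cutoffs_hz[-1] == 16_000

    def test_serial_500(self):
        grid = enumerate_conditions("serial", 500.0)
        assert grid.n_conditions == 7
        assert grid.hpn_cutoffs_hz == (250, 354, 500, 707, 1000, 1414, 2000)

    def test_serial_2000(self):
        grid = enumerate_conditions("serial", 2000.0)
        assert grid.hpn_cutoffs_hz == (1000, 1414, 2000, 2828, 4000, 5657, 8000)

    def test_serial_requires_test_frequency(self):
        with pytest.raises(ValueError):
            enumerate_conditions("serial")

    def test_default_session_layout(self):
        grid = enumerate_conditions("parallel")
        assert grid.tokens == 60 and grid.token_duration_s == 1.0


class TestDerivedBandCenter:
    def test_worked_examples(self):
        assert derived_band_center(707, 1414) == 1000
        assert derived_band_center(250, 500) == 354

    @settings(derandomize=True, max_examples=30)
    @given(st.sampled_from([250, 354, 500, 707, 1000, 1414, 2000, 2828, 4000, 5657, 8000]))
    def test_geometric_mean_closed_form(self, f):
        # center of (f, 2f) is f*sqrt(2) before snapping to the nominal grid
        assert derived_band_center(f, 2 * f) == nominal_frequency(f * np.sqrt(2.0))

    def test_non_octave_pair_rejected(self):
        with pytest.raises(ValueError, match="octave"):
            derived_band_center(500, 1414)
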