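"""Forward model: kernels, excitation structure, masking, linearity."""

import numpy as np
import pytest

from pabr.derived_band import estimate_size
from pabr.response_extraction import downsample_impulses, extract_condition
from pabr.stimulus import draw_impulse_train
from pabr.synthetic_eeg import (
    CochlearBandModel,
    NoiseModel,
    simulate_condition,
    wave_v_kernel,
)

FS = 10_000.0
FREQS = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)


def _trains(duration=10.0, rate=40.0, seed0=0):
    return {
        f: draw_impulse_train(rate, duration, seed=seed0 + i)
        for i, f in enumerate(FREQS)
    }


class TestWaveVKernel:
    def test_zero_amplitude(self):
        assert not np.any(wave_v_kernel(8.0, 0.0, FS))

    def test_peak_at_latency(self):
        k = wave_v_kernel(9.0, 2.5e-7, FS)
        assert abs(np.argmax(k) - 9.0e-3 * FS) <= 1
        assert k.max() == pytest.approx(2.5e-7, rel=1e-9)

    def test_latency_shift_moves_crosscorrelation_peak(self):
        a, b = wave_v_kernel(8.0, 1.0, FS), wave_v_kernel(9.0, 1.0, FS)
        n = max(a.size, b.size)
        a, b = np.pad(a, (0, n - a.size)), np.pad(b, (0, n - b.size))
        lag = np.argmax(np.correlate(b, a, mode="full")) - (n - 1)
        assert lag == int(1.0e-3 * FS)

    def test_biphasic(self):
        k = wave_v_kernel(9.0, 1.0, FS)
        assert k.min() < -0.05 * k.max()


class TestCochlearBandModel:
    def test_latency_strictly_decreasing_in_cf(self):
        m = CochlearBandModel()
        lats = [m.latency_ms(c) for c in m.band_centers_hz]
        assert np.all(np.diff(lats) < 0)

    def test_excitation_nonnegative_and_peaks_at_stimulus(self):
        m = CochlearBandModel()
        a = m.excitation(2000.0)
        assert np.all(a >= 0)
        assert m.band_centers_hz[int(np.argmax(a))] == 2000

    def test_basal_spread_is_asymmetric(self):
        m = CochlearBandModel(basal_skew=1.0)
        a = m.excitation(1000.0)
        centers = np.asarray(m.band_centers_hz)
        up = a[centers == 2000][0]
        down = a[centers == 500][0]
        assert up > down

    def test_masking_residual_scales_bands_above_cutoff(self):
        m = CochlearBandModel(masking_residual=0.0)
        a = m.effective_excitation(2000.0, 20.0, "serial", 2000.0)
        centers = np.asarray(m.band_centers_hz)
        assert not np.any(a[centers >= 2000])
        assert np.all(a[centers < 2000] > 0)

    def test_adaptation_shrinks_response_with_rate(self):
        m = CochlearBandModel()
        a20 = m.effective_excitation(1000.0, 20.0, "serial", None)
        a100 = m.effective_excitation(1000.0, 100.0, "serial", None)
        assert np.all(a100 < a20)

    def test_parallel_suppression_targets_off_frequency_bands(self):
        m = CochlearBandModel(parallel_suppression=0.5)
        ser = m.effective_excitation(1000.0, 100.0, "serial", None)
        par = m.effective_excitation(1000.0, 100.0, "parallel", None)
        centers = np.asarray(m.band_centers_hz)
        on = centers == 1000
        np.testing.assert_allclose(par[on], ser[on])
        assert np.all(par[~on] < ser[~on])


class TestSimulateCondition:
    def test_noiseless_single_band_is_shifted_kernel(self):
        m = CochlearBandModel(band_centers_hz=(1000,), masking_residual=0.0)
        nm = NoiseModel(base_std_v=0.0)
        train = draw_impulse_train(2.0, 2.0, seed=1)
        rec = simulate_condition(
            "serial", 20.0, None, {1000.0: train}, m, nm, seed=0,
            test_frequency_hz=1000.0,
        )
        k = wave_v_kernel(m.latency_ms(1000.0), m.peak_amplitude_v, FS)
        idx = downsample_impulses(train, FS)
        expected = np.zeros(rec.samples.size)
        for i in idx:
            end = min(i + k.size, expected.size)
            expected[i:end] += k[: end - i]
        np.testing.assert_allclose(rec.samples, expected, atol=1e-15)

    def test_linearity_without_suppression(self):
        # parallel recording == sum of serial recordings minus the
        # multiply-counted shared noise (noise is seeded independently of
        # the stimulus ensemble)
        m = CochlearBandModel(parallel_suppression=0.0)
        nm = NoiseModel(base_std_v=1e-6)
        trains = _trains(duration=4.0)
        par = simulate_condition("parallel", 40.0, 1000.0, trains, m, nm, seed=5)
        serial_sum = np.zeros_like(par.samples)
        noise = simulate_condition(
            "serial", 40.0, 1000.0, trains, CochlearBandModel(peak_amplitude_v=0.0),
            nm, seed=5, test_frequency_hz=500.0,
        ).samples
        for f in FREQS:
            s = simulate_condition(
                "serial", 40.0, 1000.0, trains, m, nm, seed=5, test_frequency_hz=f
            )
            serial_sum += s.samples - noise
        np.testing.assert_allclose(par.samples - noise, serial_sum, atol=1e-12)

    def test_complete_masking_at_lowest_cutoff(self):
        # cutoff 250 Hz with zero masking residual: extraction yields a
        # response size consistent with the noise floor
        m = CochlearBandModel(masking_residual=0.0)
        nm = NoiseModel(base_std_v=2e-6)
        v2 = []
        for seed in range(6):
            trains = _trains(duration=20.0, seed0=100 * seed)
            rec = simulate_condition(
                "serial", 40.0, 250.0, trains, m, nm, seed=seed, test_frequency_hz=500.0
            )
            idx = downsample_impulses(trains[500.0], FS)
            r = extract_condition(rec.samples, FS, idx, rec.trial_boundaries)
            v2.append(estimate_size(r, window_center_ms=10.0).sigma_r_squared_v2)
        se = np.std(v2, ddof=1) / np.sqrt(len(v2))
        assert abs(np.mean(v2)) < 3 * se

    def test_unknown_stimulus_frequency_rejected(self):
        m = CochlearBandModel()
        with pytest.raises(ValueError, match="bands"):
            simulate_condition(
                "serial", 40.0, None,
                {50.0: draw_impulse_train(40.0, 1.0, seed=0)},
                m, NoiseModel(), test_frequency_hz=50.0,
            )

    def test_trial_variance_heterogeneity_recorded(self):
        nm = NoiseModel(base_std_v=1e-6, sigma_log=0.5)
        rec = simulate_condition(
            "serial", 40.0, None, _trains(duration=20.0), None, nm, seed=2,
            test_frequency_hz=500.0,
        )
        scales = np.asarray(rec.ground_truth["trial_noise_scales"])
        assert scales.size == rec.trial_boundaries.size
        assert scales.std() > 0.1

    def test_same_seed_shares_noise_across_paradigms(self):
        m = CochlearBandModel(peak_amplitude_v=0.0)
        trains = _trains(duration=2.0)
        a = simulate_condition("parallel", 40.0, None, trains, m, None, seed=4)
        b = simulate_condition(
            "serial", 40.0, None, trains, m, None, seed=4, test_frequency_hz=2000.0
        )
        np.testing.assert_array_equal(a.samples, b.samples)
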