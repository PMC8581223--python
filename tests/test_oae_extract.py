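"""Gammatone bank, delay windowing and band-magnitude reduction."""

import numpy as np
import pytest

from clickmocr.oae_extract import (
    DelayModel,
    GammatoneBank,
    band_magnitude,
    delay_window_and_recombine,
    erb_hz,
    noise_floor_snr,
    oae_window_mask,
    window_oae,
)
from clickmocr.paradigm import ParameterError
from clickmocr.synthsession import synth_oae_kernel

FS = 32000.0


class TestOaeWindow:
    def test_mask_values_at_key_times(self):
        n = int(0.02 * FS)
        w = oae_window_mask(n, FS)
        t = np.arange(n) / FS
        assert w[np.argmin(np.abs(t - 2e-3))] == 0.0           # outside window
        assert w[np.argmin(np.abs(t - 5e-3))] == pytest.approx(0.5)  # ramp midpoint
        assert w[np.argmin(np.abs(t - 10e-3))] == 1.0          # flat top

    def test_short_epoch_raises(self):
        with pytest.raises(ParameterError):
            window_oae(np.zeros(int(0.010 * FS)), FS)


class TestGammatoneBank:
    def test_erb_formula(self):
        assert erb_hz(1000.0) == pytest.approx(132.6, abs=0.1)

    def test_on_frequency_unity_gain(self, bank32):
        """A pure tone at a channel cf emerges at ~unit amplitude."""
        cf = bank32.cfs[bank32.n_channels // 2]
        t = np.arange(int(0.2 * FS)) / FS
        x = np.sin(2 * np.pi * cf * t)
        y = bank32.filter(x[None, :])[bank32.n_channels // 2, 0]
        mid = slice(int(0.05 * FS), int(0.15 * FS))
        gain_db = 20 * np.log10(np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2)))
        assert abs(gain_db) <= 1.0

    def test_summed_response_flat_over_analysis_range(self, bank32):
        freqs, total = bank32.summed_response()
        sel = (freqs >= 1000.0) & (freqs <= 4000.0)
        rel_db = 20 * np.log10(total[sel] / bank32.sum_gain)
        assert rel_db.max() <= 3.0 and rel_db.min() >= -3.0

    def test_channel_spacing_at_most_one_erb(self, bank32):
        cfs = bank32.cfs
        gaps = np.diff(cfs) / erb_hz(cfs[:-1])
        assert np.all(gaps <= 1.0 + 1e-9)

    def test_envelope_delay_compensation(self, bank32):
        """Band envelopes stay time-aligned with an impulsive input."""
        n = int(0.05 * FS)
        x = np.zeros(n)
        t0 = int(0.02 * FS)
        x[t0] = 1.0
        bands = bank32.filter(x[None, :])
        from scipy.signal import hilbert

        for c in range(0, bank32.n_channels, 7):
            env = np.abs(hilbert(bands[c, 0]))
            assert abs(int(np.argmax(env)) - t0) <= int(0.5e-3 * FS)


class TestDelayModel:
    def test_default_keep_window_at_1khz(self):
        lo, hi = DelayModel().keep_window(1000.0)
        assert lo == pytest.approx(8.8e-3)
        assert hi == pytest.approx(13.2e-3)

    def test_delay_decreases_with_frequency(self):
        f = np.array([1000.0, 2000.0, 4000.0])
        tau = DelayModel().tau(f)
        assert np.all(np.diff(tau) < 0)


class TestDelayWindowing:
    def test_early_noise_impulse_removed_everywhere(self, bank32):
        """Energy at 2 ms lies outside every band's delay window."""
        n = int(0.02 * FS)
        x = np.zeros(n)
        x[int(2e-3 * FS)] = 1.0
        n_fft = bands_shape = None
        bands = bank32.filter(x[None, :])
        comp = delay_window_and_recombine(
            bands, bank32.cfs, FS, DelayModel(),
            equalizer=bank32.equalizer(bands.shape[-1]),
        )
        assert np.max(np.abs(comp)) < 1e-3 * np.max(np.abs(x))

    @pytest.mark.parametrize("cf", [1000.0, 2000.0, 4000.0])
    def test_kernel_at_model_delay_survives(self, bank32, cf):
        model = DelayModel()
        # tightly concentrated probe kernel (its own +-20% energy ~99.6%)
        k = synth_oae_kernel(cf, 1e-3, float(model.tau(cf)), FS,
                             int(0.016 * FS), concentration=25.0)
        bands = bank32.filter(k[None, :])
        comp = delay_window_and_recombine(
            bands, bank32.cfs, FS, model,
            equalizer=bank32.equalizer(bands.shape[-1]),
        )[0]
        assert np.sum(comp**2) / np.sum(k**2) >= 0.95


class TestBandReduction:
    def test_energy_weighted_mean(self):
        assert band_magnitude(np.array([1.0, 2.0]), np.array([1.0, 4.0])) == (
            pytest.approx(1.8)
        )

    def test_uniform_magnitude_is_identity(self):
        m = band_magnitude(np.full(5, 0.37), np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert m == pytest.approx(0.37)

    def test_snr_gate_excludes_only_gated_bins(self):
        mags = np.array([1.0, 2.0, 3.0])
        w = np.array([1.0, 1.0, 1.0])
        snr = np.array([20.0, 5.0, 20.0])
        gated = band_magnitude(mags, w, snr, 12.0)
        assert gated == pytest.approx(2.0)  # middle bin dropped
        assert band_magnitude(mags, w) == pytest.approx(2.0)  # ungated mean

    def test_all_bins_gated_gives_nan(self):
        out = band_magnitude(np.ones(3), np.ones(3), np.full(3, -5.0), 12.0)
        assert np.isnan(out)


class TestNoiseFloor:
    def test_identical_repetitions_give_infinite_snr(self):
        reps = np.tile(np.array([1 + 1j, 2 + 0j]), (8, 1))
        mean, sem, snr = noise_floor_snr(reps)
        assert np.allclose(sem, 0.0)
        assert np.all(np.isinf(snr))

    def test_pure_noise_snr_near_zero_db(self):
        """Coherent mean and SEM of iid noise shrink together: SNR ~ 0 dB.

        Both scale as 1/sqrt(N); their Monte-Carlo-averaged linear
        magnitudes differ only by a Rayleigh-vs-RMS shape factor (~-1 dB).
        """
        rng = np.random.default_rng(9)
        means, sems = [], []
        for _ in range(200):
            reps = rng.normal(size=(50, 8)) + 1j * rng.normal(size=(50, 8))
            mean, sem, _ = noise_floor_snr(reps)
            means.append(np.abs(mean).mean())
            sems.append(sem.mean())
        snr_db = 20 * np.log10(np.mean(means) / np.mean(sems))
        assert abs(snr_db) < 2.0

    def test_quadrupling_repetitions_halves_sem(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(4000, 4)) + 1j * rng.normal(size=(4000, 4))
        _, sem_n, _ = noise_floor_snr(base[:1000])
        _, sem_4n, _ = noise_floor_snr(base)
        assert np.mean(sem_n) / np.mean(sem_4n) == pytest.approx(2.0, rel=0.1)

    def test_needs_two_repetitions(self):
        with pytest.raises(ParameterError):
            noise_floor_snr(np.ones((1, 4)))
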