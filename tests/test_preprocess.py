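"""Band-pass filtering, epoching, artifact rejection and sub-averaging."""

import numpy as np
import pytest

from clickmocr.paradigm import ConstructionError, build_block_timeline
from clickmocr.preprocess import (
    AllEpochsRejectedError,
    EpochMatrix,
    bandpass_recording,
    reject_artifacts,
    segment_epochs,
    subaverage_adjacent,
)

FS = 32000.0


def _tone_gain_db(freq, fs=FS, dur=1.0):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    y = bandpass_recording(x, fs)
    sl = slice(int(0.2 * fs), int(0.8 * fs))  # avoid edges
    return 20 * np.log10(np.sqrt(np.mean(y[sl] ** 2)) / np.sqrt(np.mean(x[sl] ** 2)))


class TestBandpass:
    def test_in_band_tone_passes(self):
        assert abs(_tone_gain_db(2000.0)) <= 0.5

    def test_tone_one_octave_below_band_attenuated(self):
        assert _tone_gain_db(400.0) <= -30.0

    def test_zero_phase_time_reversal_symmetry(self):
        """Away from edge transients, filtering commutes with time reversal."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=8192)
        fwd = bandpass_recording(x, FS)
        rev = bandpass_recording(x[::-1], FS)[::-1]
        core = slice(1024, -1024)
        assert np.allclose(fwd[core], rev[core], atol=1e-9)


class TestSegmentEpochs:
    def test_activation_epoch_shape(self, null_session):
        em = segment_epochs(null_session.waveform, null_session.timeline)
        assert em["activation"].data.shape == (4, 125, 512)  # 32 kHz / 62.5 Hz
        assert em["baseline"].data.shape == (4, 6, 1600)
        assert "silence" not in em

    def test_truncated_recording_reports_complete_blocks(self, null_session):
        tl = null_session.timeline
        clipped = null_session.waveform[: 2 * tl.block_samples + 100]
        with pytest.raises(ConstructionError, match="2 complete blocks"):
            segment_epochs(clipped, tl)


def _make_epochs(rms_per_epoch, n_samples=256, seed=0):
    """Epoch matrix of white-noise epochs with prescribed RMS values."""
    rng = np.random.default_rng(seed)
    rms = np.asarray(rms_per_epoch, dtype=float)
    data = rng.normal(size=(1, len(rms), n_samples))
    data /= np.sqrt(np.mean(data**2, axis=2, keepdims=True))
    data *= rms[None, :, None]
    tl = build_block_timeline(n_blocks=1, sample_rate=FS)
    w = tl.window("activation")
    n = len(rms)
    return EpochMatrix(
        data=data, sample_rate=FS, window=w,
        epoch_times=np.arange(n) / w.click_rate,
    )


class TestRejectArtifacts:
    def test_constructed_outliers_exactly_rejected(self):
        rng = np.random.default_rng(8)
        rms = 1.0 + 0.02 * rng.normal(size=100)
        rms[[7, 21, 40, 77, 93]] = 10.0
        em = _make_epochs(rms)
        mask = reject_artifacts(em, centered=False)
        assert set(np.nonzero(~mask[0])[0]) == {7, 21, 40, 77, 93}

    def test_identical_epochs_none_rejected(self):
        em = _make_epochs(np.ones(32))
        em.data[0] = em.data[0, 0]  # make all epochs literally identical
        for rule in ("tukey", "literal"):
            assert reject_artifacts(em, rule=rule).all()

    def test_mask_invariant_under_common_scaling(self):
        rng = np.random.default_rng(1)
        em = _make_epochs(1.0 + 0.1 * rng.normal(size=64))
        scaled = EpochMatrix(
            data=em.data * 37.2, sample_rate=em.sample_rate,
            window=em.window, epoch_times=em.epoch_times,
        )
        for centered in (True, False):
            assert np.array_equal(
                reject_artifacts(em, centered=centered),
                reject_artifacts(scaled, centered=centered),
            )

    def test_all_rejected_raises(self):
        rng = np.random.default_rng(2)
        em = _make_epochs(1.0 + 0.1 * rng.normal(size=16))
        with pytest.raises(AllEpochsRejectedError):
            # absurd negative threshold forces empty retention
            reject_artifacts(em, rule="tukey", k=-100.0, centered=False)


class TestSubaverage:
    def test_activation_timepoint_count_and_resolution(self, null_session):
        em = segment_epochs(null_session.waveform, null_session.timeline)
        sub = subaverage_adjacent(em["activation"])
        assert sub.n_timepoints == 62           # floor(125 / 2), leftover dropped
        assert sub.time_resolution == pytest.approx(0.032)
        rec = subaverage_adjacent(em["recovery"])
        assert rec.n_timepoints == 10
        assert rec.time_resolution == pytest.approx(0.100)

    def test_identical_pair_average_returns_member(self):
        em = _make_epochs(np.ones(10))
        em.data[0, 1] = em.data[0, 0]
        sub = subaverage_adjacent(em)
        assert np.allclose(sub.data[0, 0], em.data[0, 0])

    def test_single_surviving_member_used_verbatim(self):
        em = _make_epochs(np.ones(10))
        mask = np.ones((1, 10), dtype=bool)
        mask[0, 0] = False
        sub = subaverage_adjacent(em.with_retention(mask))
        assert sub.counts[0, 0] == 1
        assert np.allclose(sub.data[0, 0], em.data[0, 1])

    def test_fully_rejected_pair_is_missing(self):
        em = _make_epochs(np.ones(10))
        mask = np.ones((1, 10), dtype=bool)
        mask[0, 2:4] = False
        sub = subaverage_adjacent(em.with_retention(mask))
        assert sub.counts[0, 1] == 0
        assert np.isnan(sub.data[0, 1]).all()

    def test_averaging_contracts_rms(self):
        rng = np.random.default_rng(5)
        em = _make_epochs(1.0 + 0.2 * np.abs(rng.normal(size=40)))
        sub = subaverage_adjacent(em)
        for j in range(sub.n_timepoints):
            pair = em.data[0, 2 * j : 2 * j + 2]
            member_rms = np.sqrt(np.mean(pair**2, axis=1)).max()
            assert np.sqrt(np.mean(sub.data[0, j] ** 2)) <= member_rms + 1e-12
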