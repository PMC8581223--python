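"""Shared fixtures: small scaled sessions and an independent HHG oracle."""

import numpy as np
import pytest

from clickmocr import preprocess as pre
from clickmocr.oae_extract import GammatoneBank
from clickmocr.paradigm import build_block_timeline
from clickmocr.synthsession import GroundTruth, simulate_session

FS = 32000.0  # scaled-down session rate used throughout the test suite


@pytest.fixture(scope="session")
def bank32():
    return GammatoneBank(FS)


@pytest.fixture(scope="session")
def timeline_small():
    return build_block_timeline(n_blocks=4, sample_rate=FS)


@pytest.fixture(scope="session")
def null_session(timeline_small):
    """Noiseless session with zero MOCR/MEMR: every epoch identical."""
    truth = GroundTruth.null(noise_rms=0.0)
    return simulate_session(timeline_small, truth, seed=7)


@pytest.fixture(scope="session")
def quiet_mocr_session(timeline_small):
    """Noiseless session with the default (graded) MOCR inhibition."""
    truth = GroundTruth.default(noise_rms=0.0, artifact_fraction=0.0)
    return simulate_session(timeline_small, truth, seed=7)


@pytest.fixture(scope="session")
def quiet_activation_subavg(quiet_mocr_session):
    rec = quiet_mocr_session
    filtered = pre.bandpass_recording(rec.waveform, rec.sample_rate)
    epochs = pre.segment_epochs(filtered, rec.timeline)
    return pre.subaverage_adjacent(epochs["activation"])


def hhg_bruteforce(x, y):
    """Exhaustive HHG sum-chi-square tabulation over all (i, j, k) triples.

    Independent of the vectorized implementation: builds each 2x2 table by
    explicit loops with the inclusive (<=) tie convention and accumulates
    the Pearson chi-square, skipping tables with a zero margin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a11 = a12 = a21 = a22 = 0
            for k in range(n):
                if k in (i, j):
                    continue
                ax = abs(x[k] - x[i]) <= abs(x[j] - x[i])
                ay = abs(y[k] - y[i]) <= abs(y[j] - y[i])
                if ax and ay:
                    a11 += 1
                elif ax:
                    a12 += 1
                elif ay:
                    a21 += 1
                else:
                    a22 += 1
            den = (a11 + a12) * (a21 + a22) * (a11 + a21) * (a12 + a22)
            if den > 0:
                total += (n - 2) * (a11 * a22 - a12 * a21) ** 2 / den
    return total
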