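"""Click stimulus design and block-timeline construction.

The measurement paradigm repurposes a single click train both to evoke
click-evoked otoacoustic emissions (CEOAEs) and to elicit the medial
olivocochlear reflex (MOCR).  Each *block* consists of four windows:

* ``silence``    -- 0.25 s of no stimulation, letting the reflex return to rest
* ``baseline``   -- 0.3 s of 55 dB peSPL clicks at 20 Hz (no reflex activation)
* ``activation`` -- 2 s of 80 dB peSPL clicks at 62.5 Hz (elicits the MOCR)
* ``recovery``   -- 1 s of 55 dB peSPL clicks at 20 Hz (tracks the decay)

A click presentation plus the silent interval until the next click is an
*epoch*; epoch duration is the reciprocal of the click rate.  Blocks are
repeated (500 times by default) and epochs are coherently averaged across
blocks downstream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterError",
    "ConstructionError",
    "ClickStimulus",
    "WindowSpec",
    "BlockTimeline",
    "REF_PRESSURE_PA",
    "design_click",
    "scale_to_pespl",
    "recursive_exponential_window",
    "main_lobe_width",
    "default_windows",
    "build_block_timeline",
]

#: Reference pressure for SPL (Pa).
REF_PRESSURE_PA = 20e-6

WINDOW_NAMES = ("silence", "baseline", "activation", "recovery")


class ParameterError(ValueError):
    """Raised for invalid user-supplied parameters."""


class ConstructionError(ValueError):
    """Raised when a timeline/window specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Click stimulus
# ---------------------------------------------------------------------------

@dataclass
class ClickStimulus:
    """A zero-phase band-limited click.

    ``waveform`` holds pressure samples in Pa.  ``peak_index`` is the sample
    offset of the maximum absolute pressure and defines time zero for all
    epoch-based analyses.  ``level`` is the peak-to-peak equivalent SPL
    (dB peSPL): the SPL of a 1 kHz tone whose peak-to-peak pressure matches
    the click's.  ``level is None`` for an unscaled (unit-peak) click.
    """

    sample_rate: float
    passband_lo: float
    passband_hi: float
    waveform: np.ndarray
    peak_index: int
    level: float | None = None

    @property
    def peak_to_peak(self) -> float:
        return float(np.ptp(self.waveform))

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sample_rate


def _recexp_scale(order: int) -> float:
    """Scale factor so the order-n recursive-exponential window is 1/2 at x=1.

    The window is w_n(x) = 1 / L_n(lam * x) with L_1(u) = exp(u^2) and
    L_{k+1}(u) = exp(L_k(u) - 1).  ``lam`` solves L_n(lam) = 2, obtained by
    running the recursion backwards (numerically stable at any order).
    """
    c = 2.0
    for _ in range(order - 1):
        c = 1.0 + math.log(c)
    return math.sqrt(math.log(c))


def recursive_exponential_window(x: np.ndarray, order: int = 12) -> np.ndarray:
    """Flat-topped window with doubly-exponential skirts, half amplitude at |x|=1.

    Used in the frequency domain to band-limit clicks: the top is maximally
    flat (all derivatives vanish at x=0) and the skirts fall off faster than
    any polynomial, so out-of-band rejection is essentially complete a few
    percent past the edge at moderate orders.
    """
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    lam = _recexp_scale(order)
    x = np.asarray(x, dtype=float)
    log_l = (lam * x) ** 2  # log of L_1
    for _ in range(order - 1):
        log_l = np.expm1(np.minimum(log_l, 700.0))
        log_l = np.minimum(log_l, 745.0)
    return np.exp(-np.minimum(log_l, 745.0))


def design_click(
    sample_rate: float,
    f_lo: float,
    f_hi: float,
    *,
    order: int = 12,
    duration: float = 0.01,
) -> ClickStimulus:
    """Design a zero-phase band-limited click via a recursive-exponential filter.

    The spectrum is a flat-topped recursive-exponential window spanning
    ``f_lo``..``f_hi`` (half amplitude at the edges); the zero-phase inverse
    transform yields an even-symmetric impulse whose peak defines time zero.
    The waveform has unit peak amplitude; scale it with
    :func:`scale_to_pespl`.

    Parameters
    ----------
    sample_rate : Hz
    f_lo, f_hi : Hz
        Passband edges (0 < f_lo < f_hi < Nyquist).
    order:
        Recursive-exponential order; controls skirt steepness.
    duration : s
        Length of the synthesized waveform.
    """
    if not (0.0 < f_lo < f_hi < sample_rate / 2.0):
        raise ParameterError(
            f"band edges must satisfy 0 < f_lo < f_hi < fs/2; got "
            f"f_lo={f_lo}, f_hi={f_hi}, fs={sample_rate}"
        )
    n = int(round(duration * sample_rate))
    if n < 16:
        raise ParameterError("click duration too short for the sample rate")
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    fc = 0.5 * (f_lo + f_hi)
    hw = 0.5 * (f_hi - f_lo)
    spectrum = recursive_exponential_window((freqs - fc) / hw, order=order)
    spectrum[0] = 0.0  # no DC: the click is exactly zero-mean
    wave = np.fft.irfft(spectrum, n=n)
    wave = np.roll(wave, n // 2)  # centre the (acausal) zero-phase peak
    peak = int(np.argmax(np.abs(wave)))
    wave = wave / wave[peak]
    return ClickStimulus(
        sample_rate=float(sample_rate),
        passband_lo=float(f_lo),
        passband_hi=float(f_hi),
        waveform=wave,
        peak_index=peak,
        level=None,
    )


def scale_to_pespl(click: ClickStimulus, level: float) -> ClickStimulus:
    """Scale a click to a peak-to-peak equivalent SPL (dB peSPL).

    The peak-to-peak pressure is matched to that of a 1 kHz sine at ``level``
    dB SPL: ``2 * sqrt(2) * 20e-6 * 10**(level / 20)`` Pa.  Levels here are a
    digital convention (the stored samples are in Pa); no hardware coupler
    calibration is modelled.
    """
    if not (0.0 <= level <= 120.0):
        raise ParameterError(f"level must lie in [0, 120] dB peSPL, got {level}")
    target = 2.0 * math.sqrt(2.0) * REF_PRESSURE_PA * 10.0 ** (level / 20.0)
    scale = target / np.ptp(click.waveform)
    return dataclasses.replace(click, waveform=click.waveform * scale, level=float(level))


def main_lobe_width(click: ClickStimulus) -> float:
    """Full width at half maximum (s) of the waveform around its peak.

    For an ideal 0.8-6 kHz band-limited impulse this evaluates to ~108 us.
    Crossings are located by linear interpolation between samples.
    """
    w = click.waveform
    p = click.peak_index
    half = w[p] / 2.0

    def _cross(direction: int) -> float:
        i = p
        while 0 < i < len(w) - 1:
            j = i + direction
            if w[j] < half <= w[i]:
                frac = (w[i] - half) / (w[i] - w[j])
                return abs(i - p) + frac
            i = j
        raise ConstructionError("no half-maximum crossing found")

    return (_cross(+1) + _cross(-1)) / click.sample_rate


# ---------------------------------------------------------------------------
# Windows and timeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """One window of the block paradigm.

    ``click_rate`` is 0 for the silence window.  For click windows the
    duration must be an integer number of epochs (epoch = 1/rate).
    """

    name: str
    duration: float
    click_rate: float
    click_level: float

    def __post_init__(self) -> None:
        if self.name not in WINDOW_NAMES:
            raise ConstructionError(
                f"window name must be one of {WINDOW_NAMES}, got {self.name!r}"
            )
        if self.duration <= 0:
            raise ConstructionError("window duration must be positive")
        if self.click_rate < 0:
            raise ConstructionError("click rate must be >= 0")
        if self.click_rate > 0:
            n = self.duration * self.click_rate
            if abs(n - round(n)) > 1e-6:
                raise ConstructionError(
                    f"window {self.name!r}: duration {self.duration} s is not an "
                    f"integer multiple of the epoch duration {1.0 / self.click_rate} s"
                )

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration * self.click_rate)) if self.click_rate > 0 else 0

    @property
    def epoch_duration(self) -> float:
        if self.click_rate <= 0:
            raise ConstructionError("silence window has no epochs")
        return 1.0 / self.click_rate


def default_windows() -> list[WindowSpec]:
    """The published four-window paradigm."""
    return [
        WindowSpec("silence", 0.25, 0.0, 0.0),
        WindowSpec("baseline", 0.3, 20.0, 55.0),
        WindowSpec("activation", 2.0, 62.5, 80.0),
        WindowSpec("recovery", 1.0, 20.0, 55.0),
    ]


@dataclass
class BlockTimeline:
    """Per-click onsets and epoch boundaries for all blocks of a session.

    Click onsets are rounded to the nearest sample; with the default paradigm
    (62.5/20 Hz at 96 kHz) every epoch is an integer number of samples, so no
    rounding drift accumulates.
    """

    windows: list[WindowSpec]
    n_blocks: int
    sample_rate: float
    _offsets: dict[str, float] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConstructionError("n_blocks must be >= 1")
        names = [w.name for w in self.windows]
        if len(set(names)) != len(names):
            raise ConstructionError("window names must be unique within a block")
        offsets, t = {}, 0.0
        for w in self.windows:
            offsets[w.name] = t
            t += w.duration
        self._offsets = offsets

    @property
    def block_duration(self) -> float:
        return float(sum(w.duration for w in self.windows))

    @property
    def block_samples(self) -> int:
        return int(round(self.block_duration * self.sample_rate))

    @property
    def total_samples(self) -> int:
        return self.n_blocks * self.block_samples

    def window(self, name: str) -> WindowSpec:
        for w in self.windows:
            if w.name == name:
                return w
        raise KeyError(name)

    def window_offset(self, name: str) -> float:
        """Start time (s) of a window relative to block onset."""
        return self._offsets[name]

    def epoch_samples(self, name: str) -> int:
        w = self.window(name)
        return int(round(self.sample_rate / w.click_rate))

    def click_onset_samples(self, name: str) -> np.ndarray:
        """Click-peak sample indices, shape ``(n_blocks, n_epochs)``."""
        w = self.window(name)
        if w.click_rate <= 0:
            return np.zeros((self.n_blocks, 0), dtype=np.int64)
        k = np.arange(w.n_epochs)
        within = np.round(
            self.sample_rate * (self._offsets[name] + k / w.click_rate)
        ).astype(np.int64)
        blocks = np.arange(self.n_blocks, dtype=np.int64) * self.block_samples
        return blocks[:, None] + within[None, :]

    def click_onset_times(self) -> np.ndarray:
        """All click onsets in the session (s), strictly increasing."""
        onsets = [
            self.click_onset_samples(w.name).ravel()
            for w in self.windows
            if w.click_rate > 0
        ]
        return np.sort(np.concatenate(onsets)) / self.sample_rate

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sample_rate": self.sample_rate,
            "n_blocks": self.n_blocks,
            "windows": [
                {
                    "name": w.name,
                    "duration": w.duration,
                    "click_rate": w.click_rate,
                    "click_level": w.click_level,
                }
                for w in self.windows
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "BlockTimeline":
        windows = [WindowSpec(**w) for w in d["windows"]]
        return cls(windows=windows, n_blocks=int(d["n_blocks"]),
                   sample_rate=float(d["sample_rate"]))

    @classmethod
    def from_json(cls, s: str) -> "BlockTimeline":
        return cls.from_dict(json.loads(s))


def build_block_timeline(
    windows: list[WindowSpec] | None = None,
    n_blocks: int = 500,
    sample_rate: float = 96000.0,
) -> BlockTimeline:
    """Construct the block timeline for a session (defaults: published paradigm)."""
    if windows is None:
        windows = default_windows()
    return BlockTimeline(windows=list(windows), n_blocks=n_blocks,
                         sample_rate=float(sample_rate))
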