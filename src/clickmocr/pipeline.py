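"""End-to-end analysis pipeline and result persistence.

``run_pipeline`` executes preprocess -> CEOAE extraction -> kinetics ->
detection -> MEMR on a (recorded or simulated) session and writes a stable
results layout::

    results/
      bandseries.csv   per-band, per-time-point magnitudes / noise / SNR
      kinetics.csv     per-band delta_max, time constants, baseline trend
      detection.csv    per-band HHG statistics and p-values
      memr.csv         per-band stimulus-window MEMR outcomes
      summary.json     per-band summary + config hash
      run.log          processing log

All randomness (simulation noise, permutation order) flows from the single
top-level seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detection as det
from . import kinetics as kin
from . import oae_extract as oae
from . import preprocess as pre
from .paradigm import BlockTimeline, WindowSpec, build_block_timeline, default_windows
from .synthsession import GroundTruth, SessionRecording, simulate_session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SessionResult", "analyze_session", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully serializable run configuration; hashed into every output."""

    sample_rate: float = 96000.0
    n_blocks: int = 500
    subaverage_factor: int = 2
    snr_criterion_db: float = 12.0
    delay_a_ms: float = 11.0
    delay_p: float = 0.4
    bank_spacing_erb: float = 0.5
    artifact_rule: str = "tukey"
    artifact_k: float = 2.25
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    detect: bool = True
    analyze_windows: tuple = ("baseline", "activation", "recovery")
    windows: list | None = None  # list of WindowSpec dicts; None = defaults
    truth: dict = field(default_factory=dict)  # GroundTruth.default overrides

    def timeline(self) -> BlockTimeline:
        windows = (
            [WindowSpec(**w) for w in self.windows]
            if self.windows is not None
            else default_windows()
        )
        return build_block_timeline(windows, self.n_blocks, self.sample_rate)

    def delay_model(self) -> oae.DelayModel:
        return oae.DelayModel(a_ms=self.delay_a_ms, p=self.delay_p)

    def ground_truth(self) -> GroundTruth:
        kwargs = dict(self.truth)
        for key in ("delta_max_db", "memr_gain_db"):
            if key in kwargs:
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        return GroundTruth.default(delay_model=self.delay_model(), **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyze_windows"] = list(d["analyze_windows"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "analyze_windows" in d:
            d["analyze_windows"] = tuple(d["analyze_windows"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SessionResult:
    """Everything the pipeline computed for one session."""

    config: RunConfig
    band_series: dict          # window -> BandMagnitudeSeries (CEOAE)
    stimulus_series: object    # BandMagnitudeSeries (activation stimulus)
    mocr: list                 # KineticsResult per band (activation)
    recovery: list             # KineticsResult per band (recovery)
    baseline: list             # KineticsResult per band (baseline trend)
    memr: list                 # MemrResult per band

    # -- tabular exports ---------------------------------------------------

    def bandseries_frame(self) -> pd.DataFrame:
        frames = [s.to_frame() for s in self.band_series.values()]
        if self.stimulus_series is not None:
            frames.append(self.stimulus_series.to_frame())
        return pd.concat(frames, ignore_index=True)

    def kinetics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.mocr + self.recovery:
            fit = r.fit
            rows.append(
                {
                    "band_hz": r.band_hz,
                    "window": r.window,
                    "delta_max_db": r.delta_max_db,
                    "tau_f_s": fit.tau_f if fit else np.nan,
                    "tau_s_s": fit.tau_s if fit else np.nan,
                    "at_bound": bool(fit.at_bound) if fit else False,
                    "p_hhg": r.p_hhg,
                    "significant": bool(r.significant),
                    "baseline_slope": r.baseline_slope,
                    "baseline_p": r.baseline_p,
                }
            )
        for r in self.baseline:
            rows.append(
                {
                    "band_hz": r.band_hz, "window": r.window,
                    "delta_max_db": np.nan, "tau_f_s": np.nan,
                    "tau_s_s": np.nan, "at_bound": False,
                    "p_hhg": np.nan, "significant": False,
                    "baseline_slope": r.baseline_slope,
                    "baseline_p": r.baseline_p,
                }
            )
        return pd.DataFrame(rows)

    def detection_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.mocr:
            rows.append(
                {
                    "band_hz": r.band_hz, "test": "mocr_hhg",
                    "p_raw": r.p_hhg,
                    "p_corrected": min(r.p_hhg * det.N_BANDS, 1.0)
                    if np.isfinite(r.p_hhg) else np.nan,
                    "significant": bool(r.significant),
                    "seed": self.config.seed, "n_perm": self.config.n_perm,
                }
            )
        for m in self.memr:
            rows.append(
                {
                    "band_hz": m.band_hz, "test": "memr_hhg",
                    "p_raw": m.p,
                    "p_corrected": min(m.p * det.N_BANDS, 1.0),
                    "significant": bool(m.significant),
                    "seed": self.config.seed, "n_perm": self.config.n_perm,
                }
            )
        return pd.DataFrame(rows)

    def memr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "band_hz": m.band_hz,
                    "delta_max_db": m.delta_max_db,
                    "tau_f_s": m.fit.tau_f if m.fit else np.nan,
                    "p_hhg": m.p,
                    "significant": bool(m.significant),
                    "direction": m.direction,
                }
                for m in self.memr
            ]
        )

    def summary(self) -> dict:
        bands = {}
        for r in self.mocr:
            b = {
                "mocr_delta_max_db": r.delta_max_db,
                "mocr_tau_f_s": r.fit.tau_f if r.fit else None,
                "mocr_tau_s_s": r.fit.tau_s if r.fit else None,
                "mocr_p_hhg": r.p_hhg,
                "mocr_significant": bool(r.significant),
            }
            bands[f"{r.band_hz:.0f}"] = b
        for r in self.baseline:
            bands.setdefault(f"{r.band_hz:.0f}", {}).update(
                baseline_slope_db_per_s=r.baseline_slope,
                baseline_p=r.baseline_p,
            )
        for m in self.memr:
            bands.setdefault(f"{m.band_hz:.0f}", {}).update(
                memr_delta_max_db=m.delta_max_db,
                memr_p=m.p,
                memr_significant=bool(m.significant),
            )
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "bands_hz": [float(b) for b in oae.BAND_CENTERS_HZ],
            "bands": bands,
        }


def _kinetics_for_window(
    series: oae.BandMagnitudeSeries,
    window: str,
    config: RunConfig,
    t_end: float,
) -> list[kin.KineticsResult]:
    out = []
    for d in kin.compute_delta_series(series):
        try:
            fit = kin.fit_two_term_exp(d)
            dmax = kin.delta_max(fit, t_end) if fit.converged else np.nan
        except Exception as exc:  # insufficient points etc.
            out.append(
                kin.KineticsResult(
                    band_hz=d.band_hz, window=window, fit=None,
                    delta_max_db=np.nan, notes=str(exc),
                )
            )
            continue
        p, sig = np.nan, False
        if config.detect:
            hhg = det.detect_timecourse(
                d, n_perm=config.n_perm, seed=config.seed, alpha=config.alpha
            )
            p, sig = hhg.p, hhg.significant
        out.append(
            kin.KineticsResult(
                band_hz=d.band_hz, window=window, fit=fit,
                delta_max_db=dmax if sig or not config.detect else dmax,
                p_hhg=p, significant=sig,
            )
        )
    return out


def analyze_session(recording: SessionRecording, config: RunConfig) -> SessionResult:
    """Run the complete analysis chain on one session recording."""
    timeline = recording.timeline
    fs = recording.sample_rate
    logger.info("bandpass filtering %.1f s of recording", len(recording.waveform) / fs)
    filtered = pre.bandpass_recording(recording.waveform, fs)
    epochs = pre.segment_epochs(filtered, timeline)

    bank = oae.GammatoneBank(fs, spacing_erb=config.bank_spacing_erb)
    delay_model = config.delay_model()

    band_series: dict[str, oae.BandMagnitudeSeries] = {}
    subavgs: dict[str, pre.SubAveragedEpochs] = {}
    for name in config.analyze_windows:
        if name not in epochs:
            continue
        em = epochs[name]
        mask = pre.reject_artifacts(em, rule=config.artifact_rule, k=config.artifact_k)
        n_rej = mask.size - mask.sum()
        logger.info("window %s: rejected %d/%d epochs", name, n_rej, mask.size)
        sub = pre.subaverage_adjacent(em.with_retention(mask), config.subaverage_factor)
        subavgs[name] = sub
        band_series[name] = oae.extract_band_series(
            sub, bank, delay_model, snr_criterion_db=config.snr_criterion_db
        )

    activation_end = (
        timeline.window("activation").duration
        if "activation" in [w.name for w in timeline.windows]
        else 2.0
    )

    mocr = (
        _kinetics_for_window(band_series["activation"], "activation", config,
                             t_end=activation_end)
        if "activation" in band_series
        else []
    )
    recovery = []
    if "recovery" in band_series:
        rec_end = timeline.window("recovery").duration
        recovery = _kinetics_for_window(
            band_series["recovery"], "recovery", config, t_end=rec_end
        )

    baseline = []
    if "baseline" in band_series:
        for d in kin.compute_delta_series(band_series["baseline"]):
            try:
                trend = kin.baseline_trend(d)
                baseline.append(
                    kin.KineticsResult(
                        band_hz=d.band_hz, window="baseline", fit=None,
                        delta_max_db=np.nan,
                        baseline_slope=trend.slope_db_per_s,
                        baseline_p=trend.p_value,
                    )
                )
            except Exception as exc:
                baseline.append(
                    kin.KineticsResult(
                        band_hz=d.band_hz, window="baseline", fit=None,
                        delta_max_db=np.nan, notes=str(exc),
                    )
                )

    stimulus_series, memr = None, []
    if "activation" in subavgs:
        stimulus_series = oae.extract_stimulus_band_series(
            subavgs["activation"], snr_criterion_db=config.snr_criterion_db
        )
        if config.detect:
            memr = det.memr_timecourse(
                stimulus_series, n_perm=config.n_perm, seed=config.seed,
                alpha=config.alpha, t_end=activation_end,
            )

    return SessionResult(
        config=config, band_series=band_series, stimulus_series=stimulus_series,
        mocr=mocr, recovery=recovery, baseline=baseline, memr=memr,
    )


_CSV_FMT = "%.10g"


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    recording: SessionRecording | None = None,
) -> SessionResult:
    """Simulate (if no recording is given) and analyze a session; write results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("clickmocr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if recording is None:
            logger.info("simulating session (seed=%d)", config.seed)
            recording = simulate_session(
                config.timeline(), config.ground_truth(), seed=config.seed
            )
        result = analyze_session(recording, config)
        result.bandseries_frame().to_csv(
            out / "bandseries.csv", index=False, float_format=_CSV_FMT
        )
        result.kinetics_frame().to_csv(
            out / "kinetics.csv", index=False, float_format=_CSV_FMT
        )
        result.detection_frame().to_csv(
            out / "detection.csv", index=False, float_format=_CSV_FMT
        )
        result.memr_frame().to_csv(
            out / "memr.csv", index=False, float_format=_CSV_FMT
        )
        (out / "summary.json").write_text(
            json.dumps(result.summary(), indent=2, sort_keys=True, default=float)
        )
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
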