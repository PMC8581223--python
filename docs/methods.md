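# Methods

This note documents the models, parameter choices and numerical decisions
behind `clickmocr`, and what the synthetic-data validation does and does
not establish about real recordings.

## Stimulus and paradigm

Clicks are designed in the frequency domain as a flat-topped window with
recursive-exponential skirts spanning 0.8–6 kHz (half amplitude at the
edges), inverse-transformed at zero phase. The window order controls skirt
steepness; the default order 12 is the smallest even order for which every
frequency below half the lower edge or above 1.5× the upper edge sits more
than 40 dB below the passband mean (order 10 reaches only ~36 dB at
0.4 kHz). The resulting impulse is even-symmetric about its peak — which
defines time zero for all epoch-based analyses — with a main-lobe FWHM of
~92–104 µs depending on the sampling grid.

Click levels follow a peak-equivalent SPL convention: the waveform is
scaled so its peak-to-peak pressure equals that of a 1 kHz tone at the
nominal SPL, `2√2 · 20 µPa · 10^(L/20)`. Levels are digital (samples are
in Pa); no transducer or coupler calibration is modelled.

The block paradigm is silence 0.25 s → baseline 0.3 s (20 Hz, 55 dB
peSPL) → activation 2 s (62.5 Hz, 80 dB peSPL) → recovery 1 s (20 Hz,
55 dB peSPL). Click onsets are rounded to the nearest sample; at the
default rates every epoch is an integer number of samples, so no rounding
drift accumulates.

## Synthetic sessions

The generator produces ear-canal pressure recordings whose correct
analysis outcome is known exactly:

- **Clicks** are added as full acausal waveforms centred at their onsets;
  the left tail of a window's first click spills into the preceding
  window, as a physical click train's would.
- **Emissions** are gammatone-enveloped tone bursts at the seven band
  centers, each centred at its model latency `τ(f) = 11·(f/1 kHz)^−0.4`
  ms. The envelope decay rate scales as `25/τ` by default (the generator
  uses 16/τ for a slightly narrower spectral footprint), keeping ≥95 % of
  kernel energy inside τ ± 20 %. Kernel level is −40 dB re the 80 dB
  click peak, growing compressively at 0.34 dB/dB with click level so that
  the recovery-window SNR sits ~8.5 dB below the activation window, the
  relationship observed between the two windows in vivo.
- **MOCR inhibition** multiplies the kernel magnitudes by
  `10^(Δ_b(t)/20)` with
  `Δ_b(t) = m_f(1 − e^(−t/τ_f)) + m_s(1 − e^(−t/τ_s))` during activation
  (algebraically the analysis model with `C = −(m_f + m_s)`, so
  Δ(0) = 0 by construction) and exponential return with `fall_tau` during
  recovery. Defaults: per-band 2 s inhibition graded −2.2 … −1.3 dB
  (mean 1.69 dB, largest at low frequencies), τ_f = 0.22 s,
  τ_s = 16.8 s, fall 0.22 s — the bilateral-stimulation group means
  reported for this paradigm, split 85 %/15 % between fast and slow terms.
- **MEMR** is a slowly varying per-band gain applied to the stimulus only
  (onset τ 0.3 s, release 0.2 s), interpolated smoothly across band
  centers on a log-frequency axis: middle-ear reflectance changes are
  broadband, and a spectrally sharp gain would ring in time beyond the
  stimulus analysis window. Because a 4 ms stimulus segment cannot resolve
  structure finer than the analysis bands, single-band gain spikes are
  physically and numerically meaningless; round-trip validation therefore
  uses regionally constant gains (e.g. −1 dB across 1–1.6 kHz), whose
  plateau-interior bands recover the nominal value.
- **Noise** is white Gaussian at 7.5 mPa RMS by default, chosen once so a
  scaled 50-block session lands at ~30–32 dB activation-window band SNR —
  the upper part of the ≥26 dB regime in which single-session kinetic
  parameters are identifiable (a Fisher-information estimate puts the
  τ_f sampling error near the ±25 % acceptance band at exactly 26 dB).
  A configurable fraction of epochs (1 %) receives 10× noise to emulate
  movement artifacts; realized artifact positions are stored with the
  session.

All generator randomness flows from one mandatory seed; sessions are
bit-reproducible and carry their ground truth in a JSON sidecar next to
the float32 WAV.

What the generator does **not** emulate: cochlear compressive
nonlinearity and suppression, spontaneous OAEs, probe drift, 1/f or
physiological (heartbeat, swallowing) noise structure, and middle-ear
transfer interactions between MEMR and the emissions themselves. Passing
round-trip tests therefore demonstrates that the analysis chain is
internally consistent and unbiased under its own assumptions — not that
those assumptions hold in any particular ear.

## Preprocessing

Recordings are band-pass filtered 0.8–4.2 kHz with a 4th-order zero-phase
Butterworth (forward–backward), segmented into epochs with sample 0 at the
click peak, screened for artifacts, and sub-averaged pairwise.

Artifact rejection screens per-epoch RMS within each window. Two
decisions needed care:

- The printed rule "RMS > 2.25 × IQR" is degenerate as IQR → 0; the
  default is the Tukey-style fence `RMS > Q3 + 2.25·IQR` (the literal rule
  is available as an option and falls back to no rejection at zero IQR).
- The RMS is computed by default on the residual after subtracting each
  epoch index's across-block **median** waveform. Raw epoch RMS is
  dominated by the deterministic click, and the slow reflex-driven drift
  of the emission would register as spurious "outliers" whenever the
  noise floor is low; the median template (robust to the artifact epochs
  themselves) isolates the noise. Raw-RMS screening remains available.

Sub-averaging by 2 halves the time base (32 ms activation, 100 ms
recovery resolution); an unpaired trailing epoch is dropped, a pair with
one rejected member keeps the survivor, and a fully rejected pair becomes
a missing time point that propagates as NaN.

## Emission extraction

Per sub-averaged epoch: the 4.5–15 ms window (1 ms raised-cosine ramps)
isolates the emission; a 4th-order gammatone FIR bank (ERB bandwidths
`24.7·(4.37 f_kHz + 1)` Hz, channels every 0.5 ERB over 0.8–4.2 kHz,
unity on-frequency gain, envelope-delay compensated) decomposes it; each
channel is zeroed outside its expected latency ±20 % (0.5 ms ramps); the
channels are summed and the summed-bank response is equalized by its
complex inverse (zeroed where the response falls below 10 % of its
in-band level). The equalization makes the decompose–window–recombine
chain transparent to a properly placed kernel (≥95 % energy survival at
every band center) rather than only flat to within the bank's ±3 dB
ripple.

Per time point, spectra are averaged coherently across blocks; the noise
floor is the standard error of the complex mean per bin, and band values
are energy-weighted means (weights = squared magnitude of the mean
spectrum) over third-octave bins, excluding bins below the 12 dB SNR
criterion. Band-level SNR (median over time points) gates band inclusion
at the same 12 dB.

The MEMR analysis applies the identical averaging and band weighting to a
plain DFT of the stimulus portion. The 0–4 ms window is augmented by the
final 1 ms of the epoch, which at steady state holds the acausal left
half of the zero-phase click: truncating a zero-phase click exactly at
its peak mixes distant frequencies in the spectral estimate
(Hilbert-kernel leakage) and was found to dilute narrow-band stimulus
changes by ~27 %. One millisecond covers the compact click while staying
clear of the emission latencies near the epoch end. (In a physical
recording the ear-canal click is causal and 0–4 ms captures all of it;
the gather is the zero-phase equivalent.)

## Kinetics

Δ series are referenced to the first time point (baseline, activation) or
last (recovery) and fit by bounded trust-region least squares from a
deterministic 4 × 4 multi-start grid (τ_f ∈ {0.05, 0.1, 0.2, 0.4} s,
τ_s ∈ {1, 5, 20, 45} s), magnitudes initialized from the endpoint
difference. Bounds: τ_f ≤ 0.5 s < τ_s ≤ 50 s (upper bounds from
physiology; the shared 0.5 s boundary enforces τ_f < τ_s). The τ_f
*lower* bound is raised to the series' sampling interval: dynamics faster
than the grid are unidentifiable, and admitting them lets a vanishing-τ
term chase single-point noise and destabilize the extrapolation of the
fit to t = 0 used by `Δmax = f(t_end) − f(0)`. Fits whose τ lands within
1 % of a bound are flagged. Noiseless series are recovered to 0.1 %
relative; translation of Δ by a constant moves only C.

Δmax is defined from the fitted curve (not the raw 2 s point) as
`f(t_end) − f(0)`; with the Δ(0) = 0 reference convention this equals the
accrued inhibition including the small amount already present at the
first observed time point (~8 ms into the window). Evaluation at
intermediate `t_end` (1, 1.25, 1.5 s) is supported for steady-state
comparisons. Baseline windows are tested for systematic drift with
ordinary least squares (slope and two-sided p; an exactly flat series
returns p = 1).

## Detection

The HHG statistic sums, over all ordered pairs (i, j), the Pearson
chi-square of the 2×2 table classifying the remaining points by their x-
and y-distances to point i relative to point j (inclusive ties;
zero-margin tables contribute 0). A constant vector gives T = 0, and T is
invariant under affine maps of either vector. (It is *not* invariant
under general monotone transforms — distances from a centre point are
reordered by nonlinear maps — so only the affine property is asserted.)

Significance is a permutation test of the Δ time order with
`p = (1 + #{T_perm ≥ T_obs}) / (n_perm + 1)`. For every permutation the
two-term-exponential fit is **recomputed** via a deterministic separable
projection (linear solve for C, m_f, m_s on the fixed τ grid, best
residual kept), so the statistic is a pure function of the Δ sequence and
the test is exact under time-exchangeability — the fixed-fit variant,
also exposed, is anti-conservative because the observed fit is derived
from the same Δ it is compared against. Reported parameter estimates come
from the refined bounded least-squares fit; the grid projection is used
only inside the test. Empirically the rejection rate on white-noise Δ
stays within the binomial band of the nominal α. P-values are
Bonferroni-corrected across the seven bands (α/7 ≈ 0.00714); at least 140
permutations are therefore needed for any band to reach significance, and
the default is 1,000.

MEMR detection applies the same Δ → fit → HHG machinery to the stimulus
band magnitudes; the sign of its Δmax distinguishes increased from
decreased stimulus reflectance. Across-participant MOCR–MEMR association
is summarized as the 7×7 Pearson correlation matrix of absolute Δmax
values with Benjamini–Hochberg adjustment over all cells; zero-variance
columns yield flagged NaN cells.

## Problem sizes

The package defaults reproduce the full recording session (96 kHz, 500
blocks, 1,000 epochs per time point). Validation and the acceptance
script run a scaled configuration — 32 kHz sampling and 50 blocks (100
epochs per time point), with the generator noise set so band SNR matches
the ≥26 dB regime — which exercises every code path identically at ~6 %
of the data volume. The methods are rate- and block-count-agnostic; only
SNR and the permutation floor depend on them.

## Known limitations

- Adjacent analysis bands (1 and 1.2 kHz are 0.26 octave apart) overlap
  spectrally with the emission kernels' skirts, so per-band Δ estimates
  mix a few percent of their neighbours; frequency-averaged magnitudes
  are unbiased to ~0.01 dB, single-band values to ~0.12 dB under the
  graded default truth.
- τ_s is weakly identified from a 2 s activation window and frequently
  lands at a bound (flagged); this mirrors its behaviour on real data and
  is why only τ_f carries a recovery guarantee.
- The recovery window (10 time points at 100 ms, lower click level) gives
  sparse, low-SNR fall-time estimates.
- The fixed-fit HHG variant and the literal IQR rejection rule are
  provided for completeness but are not the validated defaults.
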