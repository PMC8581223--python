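# clickmocr

Click-train, time-course-based estimation of the human **medial
olivocochlear reflex (MOCR)** from click-evoked otoacoustic emissions
(CEOAEs), with concurrent **middle-ear-muscle-reflex (MEMR)** detection.

## The problem

The MOCR is a brainstem feedback loop that inhibits outer-hair-cell
amplification in the cochlea. Conventional assays play broadband noise in
the opposite ear and compare OAE levels with and without the elicitor —
which can only probe the contralateral pathway, is vulnerable to probe
drift between conditions, and collapses the reflex to a single number.

`clickmocr` implements an alternative paradigm in which the *same* click
train both evokes the CEOAEs and elicits the reflex bilaterally. Each
3.55 s block consists of four windows:

| window     | duration | click rate | click level |
|------------|----------|------------|-------------|
| silence    | 0.25 s   | —          | —           |
| baseline   | 0.3 s    | 20 Hz      | 55 dB peSPL |
| activation | 2 s      | 62.5 Hz    | 80 dB peSPL |
| recovery   | 1 s      | 20 Hz      | 55 dB peSPL |

Blocks are repeated (500 by default) and averaged coherently, preserving
the *time course* of the reflex: the CEOAE level change

```
Δ(t) = 20 log10( M(t) / M_ref )    [dB]
```

(referenced to the first time point of the activation window, last point
of recovery) is fit with a two-term exponential

```
f(t) = C + m_f e^(−t/τ_f) + m_s e^(−t/τ_s),
0.001 s ≤ τ_f ≤ 0.5 s < τ_s ≤ 50 s,
```

whose fast/slow time constants are the reflex kinetics and whose fitted
change at the 2 s activation endpoint, `Δmax = f(2) − f(0)`, is the reflex
magnitude. Whether a Δ series reflects genuine reflex activity is decided
by a permutation implementation of the Heller–Heller–Gorfine (HHG)
distance-based association test between the fit and Δ, Bonferroni-corrected
across the seven third-octave analysis bands (1, 1.2, 1.6, 2, 2.5, 3.2,
4 kHz). The MEMR is monitored concurrently from the *stimulus* portion of
the very same epochs (0–4 ms, vs 4.5–15 ms for the emission).

The package is aimed at auditory-neuroscience and audiology researchers
prototyping efferent-reflex analyses: every processing stage is exercised
end-to-end against a synthetic ear-canal session generator with exactly
known ground truth, so no human recordings are needed to validate the
chain.

## What is inside

- `clickmocr.paradigm` — recursive-exponential band-limited click design
  (0.8–6 kHz), peak-equivalent SPL scaling, block timeline construction.
- `clickmocr.synthsession` — synthetic sessions: gammatone-enveloped CEOAE
  kernels at stimulus-frequency-OAE latencies, two-term-exponential MOCR
  inhibition, per-band MEMR stimulus gain, Gaussian noise, artifact epochs;
  WAV + JSON persistence.
- `clickmocr.preprocess` — zero-phase 0.8–4.2 kHz band-pass, epoch
  segmentation (time zero = click peak), interquartile-range artifact
  rejection, adjacent-epoch sub-averaging (factor 2).
- `clickmocr.oae_extract` — 4.5–15 ms analysis window with 1 ms Hann
  ramps, 4th-order gammatone filterbank on an ERB grid, per-band delay
  windows (SFOAE latency ± 20 %), energy-weighted third-octave band
  magnitudes with SEM noise floor and 12 dB SNR criterion.
- `clickmocr.kinetics` — Δ series, bounded multi-start two-term
  exponential fits, Δmax, baseline linear-trend test.
- `clickmocr.detection` — HHG statistic and permutation p-values, MEMR
  time courses, MOCR–MEMR Pearson correlation matrix with
  Benjamini–Hochberg adjustment.
- `clickmocr.pipeline` / `clickmocr.cli` — end-to-end runs and the
  `clickmocr` command-line tool (`simulate`, `analyze`, `detect`,
  `report`).

## Worked example

Simulate a scaled session (20 blocks at 32 kHz, known ground truth with a
graded 2.2→1.3 dB inhibition across bands, τ_f = 0.22 s) and analyze it:

```sh
cat > cfg.json <<'JSON'
{"sample_rate": 32000.0, "n_blocks": 20, "n_perm": 200, "seed": 7}
JSON
clickmocr simulate --config cfg.json --seed 7 --out demo_session
clickmocr analyze  --session demo_session --config cfg.json --out demo_results
clickmocr report   --results demo_results
```

prints

```
7/7 bands with significant MOCR activation
config hash: e7c9617d6bbbd23e  seed: 7
  band   dmax dB  tau_f s  tau_s s        p  sig   MEMR dB MEMR sig
  1000     -2.07    0.279     0.50   0.0050 True   -0.0965    False
  1200     -2.05    0.293     0.50   0.0050 True    0.0319    False
  1600     -1.89    0.210     0.50   0.0050 True    0.0375    False
  2000     -1.56    0.271    50.00   0.0050 True    0.1114    False
  2500     -1.57    0.179    50.00   0.0050 True   -0.0273    False
  3200     -1.35    0.302     0.50   0.0050 True   -0.0100    False
  4000     -1.52    0.200    50.00   0.0050 True   -0.0089    False
```

Reading the table: `dmax dB` is the fitted CEOAE inhibition at the 2 s
activation endpoint per band — close to the generator's graded truth
(−2.2 … −1.3 dB) with larger inhibition at low frequencies; `tau_f` is the
fast activation time constant (truth 0.22 s); `p` is the HHG permutation
p-value (floor 1/201 at 200 permutations), significant after Bonferroni in
all seven bands; the MEMR column shows the stimulus-level change, correctly
not significant because the simulated session had no MEMR. The slow
constant `tau_s` is weakly identified from a 2 s window and often lands at
a bound (flagged in `kinetics.csv`), matching its behaviour on real
recordings. The analysis writes `bandseries.csv`, `kinetics.csv`,
`detection.csv`, `memr.csv` and `summary.json` under `demo_results/`.

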