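# gridsync

Analysis pipeline for pairwise synchrony of spatially tuned neurons:
gridness and head-direction scoring of spatially binned firing, pairwise
temporal and spatial correlations of simultaneously recorded cells,
cyclic-shift shuffle significance, time-windowed spike-centric relative
maps, and a cohort-selection / summary procedure — plus a synthetic
session generator so the whole pipeline is testable without any recorded
data.

## What it computes

- **Rate maps and autocorrelograms** (`gridsync.maps`): 50×50 occupancy
  and firing-rate maps with NaN-marked unvisited bins, masked (NaN-aware)
  Pearson correlation, masked normalized 2D spatial autocorrelograms and
  masked Gaussian smoothing.
- **Scoring** (`gridsync.scoring`): grid score = annulus correlation at a
  60° rotation minus the correlation at 30° (range [−2, 2], default 0 when
  the smoothed autocorrelogram lacks six distinct non-central fields);
  head-direction Rayleigh score (mean resultant vector of the
  occupancy-normalized tuning curve, 60 bins of 6°).
- **Pair correlations** (`gridsync.paircorr`): lag-0 Pearson of 1 ms
  binned spike trains after a centered 25 ms moving average; spatial
  cross-correlograms with the zero-offset readout and nearest-peak angle;
  time-windowed relative maps at ±1/2/3/5/10 s.
- **Significance** (`gridsync.shuffletest`): deterministic cyclic-shift
  null (1000 evenly spaced shifts of one train), nearest-rank percentile
  criterion, two-sided split or one-sided-high tails; the all-shifts FFT
  fast path is exact for the default statistic.
- **Cohort pipeline** (`gridsync.cohort_pipeline`): session directory
  I/O, 15–45 min during-window clipping, duplicate-cell removal (>5%
  spike overlap within a 1 ms window), grid-score selection thresholds
  (≥0.5 pre, ≤0.2 during), HD clustering at Rayleigh 0.4, cross-session
  control pairs, and the correlation-of-correlations summary with
  threshold sweeps.
- **Synthetic sessions** (`gridsync.synthgen`): foraging random walk,
  three-cosine hexagonal tuning, inhomogeneous Poisson spikes by
  thinning, shared log-normal gain coupling, and an inactivation model in
  which a session-wide phase drift abolishes each cell's spatial tuning
  while preserving pairwise phase offsets; optional grid-turned
  head-direction cells.

## CLI

```sh
# generate a synthetic session directory
gridsync simulate --n-cells 5 --seed 1 --out sessions/s1

# per-cell grid and head-direction scores
gridsync score sessions/s1

# pairwise correlations with shuffle verdicts
gridsync pairs sessions/s1 --n-shuffles 1000 --alpha 0.01

# full selection + summary across sessions
gridsync pipeline sessions/s1 sessions/s2 --thresholds 0.5,0.2 --out report/
```

Session directories are plain text: `manifest.json` (ids, arena side,
condition spans, cell list), `position_<cond>.csv` (t,x,y,hd) and
`spikes_<cell>_<cond>.txt` (one spike time per line), for the conditions
`pre`, `during`, `post`.

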