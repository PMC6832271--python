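# Methods

This note documents the models, numerical choices and limitations behind
`sensorbench`: what each stage assumes, which parameters matter, and what
the synthetic cohort does and does not emulate.

## Alignment model

Raw streams are per-(platform, parameter) sample sequences with millisecond
timestamps. A packed dialect (one row per second holding k delimited
sub-second values) is unpacked by assigning sample *i* the timestamp
`t0 + i·1000/rate` ms. All channels are transposed onto a regular grid of
half-open cells `[t, t + res)`; cells are anchored at t = 0 (absolute
multiples of the resolution) so that the 10 ms ECG grid, the 100 ms channel
grid and the 1 s metric grid stay in phase. A cell holding several samples
stores their arithmetic mean; an empty cell is missing. Defaults: 100 ms
for every channel except ECG (10 ms — coarser cells would smear R-peak
timing); both are configurable per run. The session start is the earliest
timestamp across a participant's streams (device clocks are assumed
synchronized).

## Channel preparation

- **Gap filling** uses a natural cubic spline through the observed samples
  (low-oscillation interpolant; observed cells are kept bit-identical,
  leading/trailing gaps are trimmed). At least 4 support points are
  required.
- **Moving average**: mean over a ±5 s time-defined window. Only full
  windows are emitted, so the smoothed series is 5 s shorter at each end.
  Truncated edge windows would average half the data and bias the boundary
  level; the discrete Fréchet distance anchors its coupling at the series
  endpoints, so that bias alone — not the signals — would set the distance
  for many smoothed pairs. The window is time-defined (±5 s), not
  sample-count-defined, so it is grid-independent.
- **Rescaling** maps min→0, max→1 and is applied only for the similarity
  battery; the correlation battery always consumes original units so that
  systematic offsets remain visible. A constant series rescales to all-zero
  with a warning.
- **Band filtering** (the "filt." GSR variants): first-order Butterworth
  high-pass at 0.05 Hz followed by first-order low-pass at 0.5 Hz, applied
  forward–backward. Zero-phase filtering is chosen so the filtered variant
  is not artificially lagged before cross-correlation; the doubled
  effective order is recorded in the provenance list every series carries.

## Cardiac derivation

- **R-peak detection**: band-pass 5–15 Hz, derivative, square, 150 ms
  moving integration, then candidate peaks at ≥ 250 ms spacing accepted
  against adaptive signal/noise levels (exponentially updated running
  estimates, threshold at noise + 0.25·(signal − noise)). Accepted peaks
  are refined to the local raw-signal maximum with parabolic sub-sample
  interpolation. The adaptive threshold makes detection invariant to
  overall amplitude; a flatline yields an empty train with a warning.
- **IBI**: `IBI(t_i) = t_i − t_{i−1}`, stamped at the later peak. Intervals
  outside [250, 3000] ms (240–20 bpm) are dropped as artifacts before the
  series is spline-resampled onto the analysis grid. The conversion
  `IBI ms = 60000 / HR bpm` is an exact involution.
- **HRV complex demodulation**: the evenly resampled IBI series (4 Hz,
  i.e. ≥ 2× the HF upper edge) is multiplied by `exp(−i2πf_c t)` with the
  carrier at the band centre; the product is low-passed at half the band
  width and the envelope is `2·|·|`. The low-pass is an 8th-order
  zero-phase Butterworth: a tone just outside a band sits barely beyond the
  half-width cutoff (e.g. an LF tone is at 1.19× the HF demodulator's
  cutoff), and a shallower filter demonstrably leaks such tones into the
  envelope at several milliseconds. IBI (not instantaneous HR) is
  demodulated. Series must span at least two carrier periods of the band's
  lower edge; the first/last few tens of seconds of an envelope carry the
  filter's edge transient.

## Correlation battery

R² is the squared Pearson correlation (identically the OLS coefficient of
determination); zero-variance input yields a missing value with a warning.

Cross-correlation requires stationarity: both series are differenced
(order 1, at most twice) until the augmented Dickey–Fuller test (AIC lag
selection, 5% level) accepts both; if order-2 differences are still
non-stationary the coefficients are computed anyway and flagged in a log
warning. Lags run over ±15 s in 1 s steps regardless of grid resolution;
a lag whose overlap falls below 30 samples is recorded missing. With the
reference series first, a positive best lag means the wearable reports
late. Physiological caveat: series dominated by narrow-band oscillation
(HRV-modulated IBI) have near-periodic correlograms, so the argmax lag of
such pairs can alias by one modulation period — the benchmark matrices
therefore report the whole per-lag profile, not only the argmax.

MIC follows the MINE characteristic-matrix construction with B(n) = n^0.6
and clump factor c = 15. For a fixed row partition the optimal column
partition is found exactly by dynamic programming over clump boundaries,
maximising `Σ_col (−m log m + Σ_row m_q log m_q)` (equal to
n·(H(cols) − H(cols,rows)); adding H(rows) gives the grid's mutual
information). What remains approximate in the classic algorithm is the row
partition. Here, samples with n ≤ 40 enumerate *every* row partition, so
the estimator equals the defined MIC exactly on small instances (verified
against an independent exhaustive-grid oracle); above that the rows are
mass-equipartitioned and the characteristic matrices of both orientations
are combined, which is the standard approximation and a lower bound. Note
the null bias of MIC: on independent pairs it is ≈ 0.16 at n = 500 and
≈ 0.06 at n = 10⁴, which is why the nonlinearity classification
(ε = 0.1 around MIC − R² = 0) is only meaningful at large sample sizes.

k-means clustering of pair profiles (per-pair MIC across participants) uses
25 restarts at a fixed seed, Euclidean distance on the raw profiles (MIC is
already in [0, 1], so no standardisation), missing cells imputed with the
pair mean, and clusters relabelled low/moderate/high by ascending centroid
mean.

## Similarity battery

Both measures use |a − b| as the pointwise cost on rescaled series sharing
a grid, so they live on one cost scale; the time coordinate is omitted from
the point distance (a value-only leash), since at coupled indices of a
common normalised time axis it contributes nothing useful. DTW is the
boundary-anchored sum-cost dynamic program with steps (i−1,j), (i,j−1),
(i−1,j−1), unconstrained by default (an optional Sakoe–Chiba-style band is
not enabled anywhere in the shipped configuration); no path-length
normalisation is applied, so values compare only between equal-length
pairs. The discrete Fréchet distance is the Eiter–Mannila coupling dynamic
program (max-cost instead of sum-cost). Both recurrences are evaluated
along anti-diagonals so the inner loop is vectorised; both are verified
against exhaustive path enumeration on short sequences. The local Fréchet
profile applies the global distance to aligned 60 s windows every 10 s.

## Benchmark assembly

The default roster holds the study's 15 analysis parameters: 7 direct
channels (HR: VP/BH, IBI: VP/BH/E4, GSR: VP/E4) and 8 ECG-derived ones
(IBI, VLF, LF, HF from the VP and BH ECGs); the ECG waveform itself is a
source, not an analysis channel. Every channel also exists as a moving-
averaged variant, GSR additionally as filtered and filtered+smoothed.
Same-parameter pairs (every cross-source combination within a parameter,
variants paired separately; 32 with the default roster) receive the full
battery; cross-parameter pairs (all combinations of the 17 moving-averaged
channels with different parameters; 116 by default) receive the correlation
battery. The original study reports 22 and 136 pairs; its exact roster
decomposition is not recoverable from the text, so the counts here are
config-driven and logged, not hard-coded.

Metrics are computed on a common 1 s grid (block means of the 100 ms grid).
This matches the integer-second lag convention and keeps the O(n²) dynamic
programs and the MINE search fast at full session length (n ≈ 1200);
channel pairs are trimmed to their overlapping span first, and similarity
inputs are rescaled on that span.

Matrices follow the study's sorting convention: rows grouped by parameter,
sorted within the group by cross-participant mean; columns sorted by the
participant's mean over all pairs; descending for correlation statistics,
ascending for distances (smaller = more similar = "top"). Sorts are stable
with ties broken by enumeration order (rows) and participant id (columns).
Missing cells are never imputed and are excluded from every average; the
per-pair average is appended as a last column and each group's participant
average as the group's last row.

## Synthetic cohort

The generator emulates the ergometer study: 5 min rest, five 2-minute load
steps at 35/65/100/133/165 W, 5 min cool-down; 18 participants, one
deliberately degraded.

Latent truth per participant (all randomness from one master seed via a
seed sequence; per-participant parameters drawn once):

- HR relaxes toward a load-affine target (baseline ~U(65, 75) bpm, gain
  ~N(0.5, 0.04) bpm/W, onset τ = 30 s, recovery τ = 60 s — plausible
  on/off kinetics for moderate exercise; the gain keeps peak HR under the
  200 bpm bound even with modulation).
- IBI = 60000/HR plus sinusoidal LF (50 ms at 0.105 Hz) and HF (25 ms at
  0.32 Hz) modulation at the band carriers, so demodulation has a known
  amplitude to recover. R-peaks are placed so successive gaps equal the
  instantaneous IBI with 2 ms Gaussian jitter.
- GSR = slow tonic drift toward a load-dependent level (baseline
  U(2, 10) µS, rise U(1, 3) µS at peak load, τ = 60 s) plus phasic
  responses: Poisson events (0.05 Hz at rest, 0.15 Hz under load) convolved
  with a 0.75 s-rise / 4 s-decay kernel, amplitudes ~Exp(0.3 µS).

Observation models per (platform, parameter): device sampling rates (VP
GSR 25 Hz, E4 GSR 4 Hz, E4 IBI 64 Hz, ECG 250 Hz, BH summary channels
1 Hz), constant reporting lags (BH 1 s, E4 2 s, VP leading), a
range-dependent offset `a/v + b` for BH HR (maximal at low heart rates,
vanishing at high ones), Gaussian noise, ~1% sample dropout, a
platform-specific phasic GSR gain (E4 1.8× — the wrist band responds more
strongly to sweating than the gel-electrode reference), and ECG rendered as
a Gaussian R-wave train (σ = 8 ms) — no full PQRST morphology, which is
sufficient for the detector contract but not for morphology studies. The
degraded participant mimics weak electrode contact: 20% dropout, 10× noise,
15% ECG amplitude, 0.3× phasic gain.

What passing the recovery tests shows: the pipeline recovers configured
lags, injected HRV amplitudes and the planted anomaly under realistic
rates, offsets, noise and dropout. What it does not show: performance
under real-device failure modes not modelled here — motion artifacts,
optical-IBI beat misses, electrode drift, nonstationary noise, clock skew
over time, or true beat-to-beat (per-beat, sensor-independent) IBI error.
One consequence of the smooth shared HRV modulation: smoothing removes
*common* signal rather than independent noise on IBI pairs, so the
"smoothed pairs are more similar" tendency is weaker here than on real
data; it is asserted statistically (≥ 80% of clean-participant pairs), not
per pair.

## Degenerate inputs and tie-breaks

Constant series: stationary by ADF convention, MIC 0 and R² missing with
warnings, rescale to all-zero. Duplicate timestamps are a hard read error
naming the line. Grid cells average multiple samples (permutation
invariant). k-means on identical profiles may collapse clusters; labels
then follow centroid rank order with stable ties. All floating-point CSV
output uses fixed formats so identical runs are byte-identical.
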