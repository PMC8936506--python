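# Methods

`recamp` estimates how much energy a signal carries in *recurrent* activity
as a function of the recurrence period, without assuming any waveform
shape.  This note documents the model, the numerical choices, and what the
synthetic validation does and does not show.

## Model and procedure

**Phase-space reconstruction.**  A scalar series `x_t` sampled at `fs` is
lifted to d-dimensional states by delay embedding,
`s_i = [x_i, x_{i+τ}, …, x_{i+(d−1)τ}]` (oldest-lag-first; state index `i`
anchored to raw index `i`).  The delay τ is taken from the auto-mutual
information (AMI) of the series, the dimension d from the
false-nearest-neighbors (FNN) criterion; both can be fixed by the user
instead.

**Recurrence structure.**  Two states are recurrent when their distance
(maximum norm by default, Euclidean optional) is at most
`ε = en/100 · STD(window)`.  The binary recurrence matrix is symmetric with
a unit diagonal; a distance exactly equal to ε counts as recurrent, so
constant or duplicated states remain recurrent.  For each reference state,
forward time offsets are scanned: recurrence points delimit white runs, and
every run of length `T ≥ 2` bounded by recurrence points on both sides is
one recurrence event of period `T` (time spent outside the neighborhood —
the "second type" recurrence period).  Runs of length 1 are tangential
motion and excluded; runs cut off by the window edge are unbounded and
dropped.

**Spectrum.**  Events are histogrammed into `R(T)` and normalized over the
requested period range to `P(T)`.  Each event's amplitude is its loop's
maximum phase-space diameter (largest pairwise distance over the spanned
states, bounding points included); the mean over the `q` events of a period
gives `ā(T)`, and the probability-weighted spectrum is `A(T) = P(T)·ā(T)`
at frequency `f = fs/T`.  Weighting by `P` damps rare, noise-inflated
loops.  Sliding the estimator over overlapping windows (embedding
re-optimized per window by default) yields a time-resolved spectrum with
rows at window centers.

**Waveform template (optional).**  Each event's raw-signal segment is
correlated against a template waveform resampled so one cycle spans the
loop's cycle length (`T+1` samples; the two bounding recurrence points sit
one full cycle apart), maximizing the Pearson correlation over all cyclic
offsets.  The correlation, clamped at 0 and raised to the exponent α,
multiplies the event amplitude before averaging.  α = 0 restores the
unfiltered spectrum exactly; negative correlations clamp to zero because an
anti-correlated waveform should be attenuated, not sign-flipped.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `tau`, `dim` | embedding delay (samples) / dimension | 0 = automatic | AMI first minimum / FNN |
| `en` | neighborhood radius, % of window STD | 5 | validation experiments here use 10; for measured data 50–100 % is a practical start |
| `metric` | phase-space norm | maximum | Euclidean optional |
| `window` | sliding window, ms | 1/10 of data length | lowest resolvable frequency is `fs/window` |
| `overlap` | window overlap fraction | 0.5 | |
| `min_period, max_period` | period range | (0, 0) = all | maps to `2 … window−1` |
| `amplitudes` | estimate `ā(T)` | on | off → probabilities only |
| `outp`, `db` | magnitude/power, decibel | amp, dB on | zero amplitudes floor at −120 dB |
| `template`, α | waveform filter | none | α = 5 in the shape-filter experiments |
| `r_tol`, `a_tol`, `fnn_threshold`, `d_max` | FNN settings | 10, 2, 0.01, 10 | Kennel-style tolerances |

AMI defaults: equal-width histogram over the observed range with
`⌈√N⌉` bins capped at 64; lags up to `min(N/2, fs)` (one second).  These
give stable joint histograms at the window sizes used here; none of them is
prescribed by the method itself.

## Numerical choices

- **Delay selection.**  The "first AMI minimum" rule is applied to a
  5-lag-smoothed curve, requires the minimum to hold over ±2 lags, ignores
  the smoothing edge zone, and accepts only minima within 10 % of the
  curve's floor (relative to the drop from lag 0).  Equal-width-binned MI of
  periodic signals shows shallow commensurability ripples well before the
  true basin; an exact-MI study on a noise-free sine shows these ripples are
  estimator structure, not sampling noise, so a literal first-local-minimum
  rule would return a uselessly small delay.  Fallbacks: first crossing of
  `MI(0)/e`, then 1.
- **FNN.**  A neighbor is false when the appended coordinate grows the
  distance by more than `r_tol`-fold or the grown distance exceeds `a_tol`
  standard deviations.  Growth below `1e−10·STD` is ignored — exactly
  periodic signals contain duplicate states whose round-off-sized distances
  would otherwise make the ratio criterion fire on noise.
- **Period bias.**  With isolated recurrence points spaced one period `P`
  apart, the white run between them has length `P−1`, so detected periods
  sit ~1 sample below the true period at small ε, and drop a further ~2
  samples per state-to-state distance added to ε (the SREPS ridge slope).
  All frequency checks therefore use one reciprocal-period-bin tolerance.
- **Small-ε period multiples.**  When the sampling grid is incommensurate
  with the period (e.g. 41 Hz at 1 kHz, period 24.39 samples), single-cycle
  recurrences can miss a small ε-ball for a fraction of reference phases
  while multi-cycle recurrences (whose accumulated phase error wraps closer
  to the grid) are always caught; the spectrum then peaks at an integer
  multiple of the period.  Growing ε (≥ 20 % STD for that example) restores
  the fundamental.  The same mechanism produces the noise-induced
  subharmonics.
- **Degenerate windows** (constant signal, or too few states) produce a
  zero spectrum row and are flagged in the output metadata rather than
  failing the run.
- **Overlap averaging.**  Output bins are window centers; if several
  windows map to one bin they are averaged with equal weight (with the
  standard hop this does not occur).
- **dB floor.**  Zero amplitudes map to −120 dB so logs never see 0.
- **Amplitude convention.**  The reported amplitude is the phase-space
  *diameter* (peak-to-trough for a sinusoid under the maximum norm); an
  optional `peak_rescale` halves it for peak-amplitude units.

## Synthetic validation: what it shows

The generators produce the study conditions used throughout tests and the
acceptance script, all at fs = 1 kHz: the 15-s waveform compound (5 s each
of sine/sawtooth/rectangle, 33 Hz, amplitude 2), the five-step staircase
(14/33/41/52/67 Hz sines, 3 s each, sharp transitions intentional), seeded
uniform noise referenced to the signal's peak amplitude (bound
`L = level/100·max|x|`, STD `L/√3`) or to its STD, a slow 3-Hz + 8 %-STD
noise signal for the ε scan, and a fixed-step RK4 Lorenz trajectory
(σ = 10, ρ = 28, β = 8/3, transient discarded) as the chaotic, recurrent
but non-periodic reference.  Validation runs use 600–2,000-sample windows
on ≤ 15,000-sample signals — sizes at which every experiment reproduces the
qualitative phenomena (waveform independence, missing harmonic stacks,
subharmonics instead of a noise floor, template selectivity) with stable
peak locations.

These signals are noise-free or carry white uniform noise only.  They do
not emulate 1/f background, drifts, amplitude modulation, or
non-stationary waveform shape of physiological recordings, so passing
tests demonstrate estimator correctness on known ground truth, not
field-data performance; for measured data the ε scan and transparent
parameter reporting remain essential.

## Known limitations

- Superpositions of rhythms are not decomposed: recurrence requires the
  *joint* state to return, so a sum of two sines is not two peaks.
- The recurrence matrix is O(n²) in window length (SREPS keeps one
  distance matrix: ~n² doubles of memory).
- The white-run convention biases periods ~1 sample low; frequencies
  derived from small integer periods are correspondingly coarse.
- Binned AMI delay selection is approximate for slow rhythms (broad
  shallow basins); supplying τ explicitly is supported and recommended
  when the timescale is known.
- The Belousov–Zhabotinsky benchmark requires an external download and is
  exercised only when the file is present.
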