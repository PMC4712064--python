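# Methods

`affectemg` implements a complete facial-EMG affective-state analysis: a
synthetic generator that emulates a block-design picture-viewing protocol,
a signal-conditioning chain, baseline/evoked window extraction, a
16-feature descriptor per muscle channel, six-class SVM classification
under repeated cross-validation, and the group statistics computed on
published-style accuracy grids.  This note records the model assumptions,
the parameter choices that matter, and the design decisions taken where
the problem leaves the design genuinely open.

## The synthetic protocol and signal model

The generator reproduces the *statistical* structure of a standard affect
induction experiment, not muscle physiology.  A session is ten 20 s
stimulus blocks — two per category: neutral (0VLA), positive/high-arousal
(PVHA), negative/high-arousal (NVHA), positive/low-arousal (PVLA) and
negative/low-arousal (NVLA) — in seeded random order, each preceded by a
20 s rest pause (400 s total).  Each block contains ten 2 s picture slots.
Two channels are generated at 512 Hz: corrugator supercilii and
zygomaticus major.

Each channel is

    x(t) = A * g(t) * c(t) + L * sin(2*pi*f0*t + phi)

where `c(t)` is unit-RMS Gaussian noise shaped in the frequency domain to a
trapezoid — zero outside 20–250 Hz, flat on 50–150 Hz with linear
transition ramps — matching the canonical surface-EMG spectrum and making
the spectral-containment property exact by construction; `A` is the base
amplitude (default 20 µV); `L`/`f0` are power-line interference (default
5 µV at 50 Hz, random phase); and `g(t)` is a piecewise-linear envelope
that rests at 1 during pauses and, inside each picture slot, ramps (onset
latency 0.2 s, rise 0.2 s) to `gain[channel][category] * jitter`, with a
mean-one lognormal jitter (sigma 0.1) drawn per slot.  The jitter creates
within-block nonstationarity so early and late evoked windows genuinely
differ.

The default gain matrix encodes the classical directional effects —
corrugator activity ordered NVHA > NVLA > 0VLA > PVHA, PVLA; zygomaticus
ordered PVHA > PVLA > 0VLA ≈ NVLA with a mild arousal boost for NVHA:

| channel     | NVHA | NVLA | 0VLA | PVLA | PVHA |
|-------------|------|------|------|------|------|
| corrugator  | 6.0  | 2.5  | 1.2  | 0.65 | 0.85 |
| zygomaticus | 1.4  | 1.0  | 1.0  | 2.0  | 5.0  |

The spacing follows an explicit calibration rule: in the two-channel
log-gain plane, every pair of (category × age-group) clusters is at least
~3× the within-category log-amplitude spread apart (jitter plus
RMS-estimator noise, about 0.11 nats).  This makes the defaults a
*strong-separation* configuration: category structure is recoverable by
the pipeline, and weakening the gains toward 1 degrades recovery smoothly
to chance.  The age effect is a single multiplicative amplitude factor
(default 0.7 for the senior group), the simplest form consistent with
reports of globally lower facial-EMG amplitude in older adults; the
calibration rule deliberately accounts for it, because a whole-amplitude
scaling slides every senior category cluster along the diagonal of the
log-gain plane and is the main source of cross-group confusions.

What the generator does **not** model: motor-unit recruitment, electrode
cross-talk between muscle sites, blink/EOG and movement artifacts,
habituation across blocks, and inter-subject amplitude variability beyond
the age factor.  Passing recovery tests on this generator therefore shows
that the pipeline recovers amplitude-coded category structure under
realistic spectra, interference and nonstationarity — not that real
recordings would classify at these rates.

## Signal conditioning

* **Band-pass**: Butterworth 20–250 Hz, order 4, applied forward–backward
  (zero phase) so burst onsets are not delayed relative to the stimulus
  schedule.  Offline processing permits the non-causal filter.
* **Line cancellation**: a two-weight LMS canceller with unit-amplitude
  sine/cosine references at the line frequency; step size 0.005
  (dimensionless, per-sample).  It behaves as a narrow adaptive notch
  (bandwidth ~ mu*fs/pi ≈ 0.8 Hz): an isolated 50 Hz tone is driven below
  1% of its power within ~2 s while broadband EMG passes essentially
  unchanged.  The step size trades convergence speed against notch width
  and is configurable.
* **EMD**: classic sifting with cubic-spline envelopes over the extrema,
  mirror extension of two extrema at each end, and a two-part stopping
  rule per mode: a Cauchy criterion (relative squared change < 0.2) *and*
  IMF admissibility (extrema and zero-crossing counts differ by at most
  one), capped at 10 sifts per mode and 12 modes.  The decomposition is
  exact by construction (modes plus residual sum to the input at float
  precision).
* **Hilbert spectrum**: analytic signal per IMF; instantaneous frequency
  from the gradient of the unwrapped phase.  The first and last 5% of
  samples are excluded from summary statistics because the analytic
  signal is unreliable at the edges.
* **EMD denoising** (the `enhanced` profile): a mode is retained when its
  median instantaneous frequency lies within the EMG band (20–250 Hz);
  the monotone residual is always dropped.  The `standard` profile
  (band-pass + line cancellation only) is the default, since nothing in
  the feature definitions requires mode-domain processing; both profiles
  feed the identical downstream chain.

A note on stop-band expectations: an order-4 band-pass edge at 250 Hz
attenuates a 300 Hz tone (0.26 octave above the edge) to only ~8% RMS even
when applied twice; rejection of ≥95% RMS that close to the edge would
require roughly a 9th-order edge.  The filter order is kept at 4, the
value appropriate for this recording setup, and the residual is what it
is.

## Windowing

Seven conditions pair a baseline window (1 or 2 s) with an evoked window
(1, 2 or 10 s, the 10 s ones aligned to the first or last part of the
block): 1-1, 1-2, 1-10-f, 1-10-l, 2-2, 2-10-f, 2-10-l.  The baseline
window is cut from the start of the pause preceding each block — the only
unstimulated epoch in the protocol — which is a documented convention, not
something the protocol itself fixes.  All windows are half-open
`[t0, t0+len)` seconds, converted to 0-based sample indices by
`floor(t*fs)`.  Every block contributes one evoked and one baseline
segment per channel, so the baseline class is ~5× the size of each affect
class; this imbalance is kept (it mirrors the published tables' near-100%
baseline rates) and documented rather than re-balanced.

## Features

16 features per segment and channel; both channels give a 32-dimensional
vector with `corr_`/`zyg_` prefixes.

* amplitude: `mav`, `mavfd`, `mavsd` (mean absolute value of the signal
  and its first/second differences, µV), `peak` (max, µV), `rms` (µV);
* frequency: `zc` (zero crossings; exact zeros carry the previous sign),
  `fmed` (frequency bisecting the cumulative *power* spectrum), `fmode`
  (magnitude-spectrum argmax, lowest frequency on ties), `fmean`
  (magnitude-weighted mean frequency), `cf` (half the width between the
  −3 dB band edges around the spectral peak), all in Hz;
* predictability: `ap_en` (approximate entropy, self-matches included),
  `fuzzy_en` (fuzzy entropy: mean-removed templates, membership
  `exp(-(d/r)^n)`, self-matches excluded, equal template counts for both
  lengths);
* variability: `var` (N−1 denominator), `std`, `range`,
  `intrange` ((Q3−Q1)/2, linear-interpolation quartiles).

Entropy parameters default to m = 2, r = 0.2 × the segment's population
SD, fuzzy exponent n = 2 — the standard settings in the sEMG literature.
Conventions fixed where definitions are ambiguous: `cf` uses the printed
half-difference form (fh−fl)/2 (the midpoint (fh+fl)/2 is available via
`frequency_features`' building blocks); `fmed` operates on power while
`fmode`/`fmean` operate on magnitude; a constant segment yields zero for
both entropies.  Every feature is verified against an independent
brute-force oracle (naive O(N²) double loops for the entropies) in the
test suite.

## Classification

Rows are the labelled windows of all subjects (row-wise partitioning; a
subject's windows may appear on both sides of a fold split, as when a
single feature table is cross-validated without subject grouping).
Pipeline: standardization → Gaussian-kernel SVM, one-vs-one multiclass →
stratified 10-fold CV, repeated 10× with fresh seeded fold assignments →
per-class success rates from the held-out predictions pooled over a
repeat's folds → mean/SD across repeats, in percent.

Standardization is per-fold by default (scaler fit on training rows only;
held-out rows never leak into the scaling), with a `global` mode that
z-scores the full table up front.  Box constraint C = 1.  The kernel
scale defaults to the dimension-aware heuristic `sqrt(n_features*var(X))`
rather than a fixed 1: with 32 standardized features, a unit kernel scale
makes every off-diagonal kernel entry ~exp(−64) and the one-vs-one vote
degenerates to the majority class — a failure mode we observed directly —
so the fixed scale survives only as an explicit option.

## Group statistics

An accuracy grid is the 7 × 6 table of per-class mean success rates.  The
age and gender comparisons are pooled-variance two-sample t-tests over the
42 cells of each grid (Welch available by flag).  The electrode-
configuration comparison is a one-way repeated-measures ANOVA across the
two-channel, corrugator-only and zygomaticus-only grids, with the 42 cells
as repeated-measures units; F is reported with uncorrected df (2, 82) and
with the lower-bound sphericity correction (1, 41), plus the three
Bonferroni-corrected (×3) paired comparisons.

Cells are paired across grids *positionally, in each grid's stored row
order* by default.  The shipped fixtures preserve the row order of their
sources, which differs between them (the two-channel grid lists condition
2-2 in the fifth row block, the single-channel grids list it last); the
positional pairing therefore mis-aligns the 2-2 rows, and exactly this
reading reproduces the published F to two decimals, so it is the default.
Label-matched pairing (`pairing="condition"`) is provided and gives a
larger F (≈105), since aligning 2-2 — the weakest condition in all three
grids — with itself moves its shared dip into the subject effect instead
of the error term.

## Problem sizes and numerical choices

The recovery experiments use a 12-subject cohort (6 young, 6 senior, 120
windows per subject-condition table, 24 windows per affect class) under
window condition 1-2 — large enough for stable 10-fold stratification and
chosen as the package's standard demonstration size.  Entropy features on
10 s windows (5120 samples) build an O(N²) distance matrix (~200 MB
transiently); the shorter conditions are recommended for exploratory
sweeps.  Quantile interpolation is linear; ties in `fmode` resolve to the
lowest frequency; all RNG flows from explicit seeds
(`numpy.random.SeedSequence` fan-out per subject and stage), and every
stage is bit-reproducible under a fixed configuration.

## Known limitations

* The generator codes affect purely as amplitude modulation; spectral or
  phase-coded effects would exercise the frequency features more than the
  synthetic tests do.
* Accuracy levels obtained on synthetic cohorts are not comparable to
  values obtained on human recordings; only structural statements
  (orderings, chance-level behaviour, determinism) transfer.
* The repeated-measures ANOVA treats grid cells, not subjects, as units —
  the only analysis available when per-subject accuracies are not
  published — and its default pairing is a faithful-reproduction choice,
  as discussed above.
* Row-wise CV partitioning is the default; subject-disjoint folds would
  give more conservative (lower) rates on cohorts with strong
  subject-level amplitude structure.
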