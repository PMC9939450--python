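# Methods

This note documents the models, conventions and numerical choices behind
`usvmeal`, in the order data flows through the pipeline.

## Study design being modelled

One session is one rat in one 10 min phase of an experimental meal:
*anticipation* (food present in a perforated container, inaccessible) or
*consumption*. Audio is mono PCM at 384 kHz from an ultrasonic microphone
above the cage; behaviour is scan-sampled at 1 s from synchronized video
against a ten-state ethogram (Up explore, Down explore, Sniff food, Move,
Grooming, Dig litter, Rearing, Lying down, Immobile, Feeding — Feeding
existing only in the consumption phase). Ultrasonic vocalisations (USVs)
are discrete events of peak frequency 20–100 kHz lasting 10–150 ms, with at
least 20 ms between two distinct events; each is assigned a subtype from the
14-type taxonomy used for amphetamine-elicited 50 kHz calls and a median
frequency on a 5 kHz grid.

## Synthetic data generator (`synthdata`)

The generator is first-class code: it defines the conditions under which
the statistical machinery is validated.

**Behaviour** is a continuous-time semi-Markov chain: exponential bout
durations with per-state means (e.g. Feeding 25 s, Move 3 s), embedded
transition matrix built from preference weights, scan-sampled at 1 s. Bouts
give realistic run-lengths — the time-shuffling test must be exercised
against autocorrelated behaviour, which per-second i.i.d. draws would not
provide. In the anticipation phase Feeding is removed from every transition
row and rows are renormalised. The initial state is dwell-weighted.

**USV events** follow an inhomogeneous Poisson process whose rate is set by
the behaviour of the current 1 s bin (defaults 1–7 events/min per
behaviour, giving 40–60 calls per 10 min session — the observed order of
magnitude; no per-behaviour rates are published, so these are chosen for
test power). The subtype of an event is drawn from
`(1 − a)·global + a·behaviour-specific` mixtures, with
`a = association_strength`: at `a = 0` subtype is independent of behaviour
(the null of the shuffling test), at `a = 1` the planted associations are
fully expressed (flats boosted ×6 under Feeding, trills under Lying down,
frequency-modulated calls under Up explore, multi-steps under Immobile).
Durations are uniform within subtype-specific bounds inside [10, 150] ms;
consecutive events keep a ≥ 20 ms offset-to-onset gap (onsets resampled
within their bin, the event dropped after 10 failures). The rate attaches
to the behaviour at event *onset*, matching the co-occurrence convention.

**Audio**: each call is a phase-continuous tone following its subtype's
frequency trajectory (flat: constant; ramps: linear; steps: piecewise
constant with 15 kHz jumps; trill: sinusoidal FM, 15 ms period, 5 kHz
depth; split: brief +15 kHz excursion; inverted U: parabolic;
complex: piecewise linear through random control points) with 2 ms cosine
on/off ramps, amplitude 0.3 full scale. Pellet-crack clicks are 0.5 ms
white bursts at 3 clicks/s inside Feeding bins. The noise floor is Gaussian
with σ = 10^(−60/20) full scale, i.e. well above 20 dB SNR per call. All
trajectory parameters are configuration, not constants: the source taxonomy
is visual and publishes no numeric shapes.

**Reproducibility**: one `numpy` generator per (scenario seed, rat, phase),
derived via `SeedSequence([seed, crc32(rat|phase)])`; identical seeds give
byte-identical scans, events and waveforms, independent of generation order.

What the generator does **not** emulate: room acoustics and microphone
directivity, cage-mate cross-talk, amplitude modulation within calls,
harmonics, overlapping calls from two animals, and non-stationary noise.
Passing detector tests therefore show correctness of the segmentation and
classification logic under clean, well-separated calls — not performance on
degraded field recordings.

## Detection and classification (`spectro`)

STFT with a 1024-sample Hanning window at 384 kHz. The hop is 512 (50%
overlap): the window size is fixed by the recording protocol, and a 1.33 ms
time step resolves the 10 ms minimum call duration comfortably. Power is in
dB full scale. The detection threshold is the per-frequency-row median plus
12 dB — an adaptive floor robust to spectral tilt.

Detection segments above-threshold cells inside 20–100 kHz into
8-connected components; components narrower than 3 frames are discarded
(a minimum-duration call spans ~7 frames; the survivors are noise specks
which would otherwise merge into neighbouring calls). Broadband frames
(≥ 40% of all bins lit, dilated by one frame) are blanked first so
pellet-crack skirts neither masquerade as calls nor corrupt trajectories.
Endpoints are interpolated where the per-frame peak power crosses 12 dB
below the component maximum, then pushed outward by a quarter window — a
threshold crossing on a tapered onset sits inward by about that much; the
measured duration bias on synthetic calls is −0.1 ± 0.15 ms.

Candidates closer than 20 ms are **merged** (the inclusion rule defines
distinctness of two events, not validity of one), then duration and band
filters apply. Rejected events longer than 150 ms with median below 30 kHz
are logged: the duration cap conflicts with typical 22 kHz long calls, and
the log surfaces them rather than silently discarding.

The per-frame trajectory is the argmax frequency within the component. The
median frequency is the median over *all* frame samples, rounded to the
nearest 5 kHz with ties rounding half-up (the convention at 2.5 kHz
midpoints is arbitrary; half-up is fixed for reproducibility).

Subtype classification is a decision cascade with configurable thresholds
(defaults: short < 12 ms; flat bandwidth ≤ 5 kHz; jump ≥ 10 kHz over a
2-frame lag; trill ≥ 2 FM cycles whose extrema spacing has CV ≤ 0.4):
duration → jump family (step up/down by single jump sign; split if the
trajectory returns to its starting level after a short excursion;
multi-step otherwise; trill-with-jumps if a segment oscillates) → flat →
trill (with a flat-trill combination carve-out when a flat head precedes
the oscillation) → inverted U (one interior prominent maximum with rise and
fall) → ramps by net monotone change (composite when a long plateau
precedes the ramp) → complex. On clean synthetic audio the five classes
used in downstream statistics (flat, short, both ramps, trill) classify at
≥ 0.98; the residual confusions sit inside the frequency-modulated family
(trill-with-jumps ↔ trill, complex ↔ anything wiggly), which mirrors how
ambiguous those categories are for human raters.

Chew clicks are runs of ≤ 3 consecutive frames whose above-threshold bins
cover ≥ 80% of 0–Nyquist. A 0.5 ms transient overlaps up to
⌈(0.5 + 2.67)/1.33⌉ = 3 half-overlapped windows, so 3 is geometry, not
slack; the reported click duration is the frame support (1.3–2.7 ms) because
nothing shorter is resolvable at this hop — the physical transient is < 1 ms.
A call's `chew_overlap` flag is true iff at least one click time falls
within its span.

## Co-occurrence conventions (`ethogram`)

Scan bins are half-open `[k, k+1)` seconds, 0-based, on the video clock;
audio events are moved onto the video clock by subtracting the per-session
audio-minus-video offset (events leaving the phase window are excluded with
a warning). An event co-occurs with the behaviour of the bin containing its
**onset**: anticipatory calls begin within the behaviour that elicits them,
and the convention makes co-occurrence independent of call duration. A
midpoint convention is available as a sensitivity switch. A call spanning
two bins is counted once (onset bin) — never in both.

## Shuffling test (`mcshuffle`)

Per session, every replicate reassigns each event an independent uniform
time in `[0, T)` (continuous, then binned exactly as observed events are)
and recounts the matrix; subtype labels never change. z uses the sample sd
(ddof 1) over replicates — negligible at 10,000 replicates but fixed for
bit-reproducibility. Cells with zero null sd (subtype absent, or a
behaviour occupying all bins) are undefined, and sessions with undefined z
are dropped from that cell's cross-rat average rather than imputed 0: a rat
that never produced the subtype carries no evidence either way. The number
of contributing sessions is reported per cell. Flags: positive if
mean z ≥ 2, negative if ≤ −2; the two-sided normal tail at 2 is p = 0.0455,
and an exact permutation p per cell (fraction of replicates at least as far
from the null mean as the observation) is emitted alongside.

Rows/columns are excluded when their total co-occurrence count across all
sessions is ≤ 5 (configurable; 0 disables). No multiple-testing correction
is applied across the grid, by design.

Calibration and power are established empirically in the test suite: on
null data (association 0) the per-cell flag rate over 200 16-rat cohorts is
far below 5% (averaging 16 per-rat z-scores shrinks the sd of the mean to
~1/4, making the fixed |z̄| ≥ 2 threshold conservative — the same
conservatism applies to any real multi-animal analysis); with fully
behaviour-specific mixtures the planted flat×Feeding cell is flagged in
≥ 95% of replicates at 4 rats and 1,000 shuffles.

## Phase statistics (`phasestats`)

*Delta USV* is consumption count − anticipation count per rat and subtype;
subtypes produced by a single individual are excluded with a report (one
emitter makes a between-subtype comparison of per-rat deltas meaningless).
Kruskal–Wallis uses the tie-corrected H; all-identical inputs return H = 0,
p = 1. Dunn's pairwise z uses the rank variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`
with two-sided normal p, Bonferroni-adjusted over all pairs (configurable to
unadjusted); it is implemented in-package and verified against a hand-rank
oracle.

*Band summaries* use bounds inclusive on both ends — frequencies live on a
5 kHz grid, so 35–45 means {35, 40, 45} — and whole-percent shares with
half-up rounding.

*Chewing chi-square*: the default layout is the 2×2 of the four headline
totals `[[all, all-chewing], [flat, flat-chewing]]` without continuity
correction, which reproduces the published statistic and its N exactly, even
though flats are counted inside the totals (the cells are not disjoint). A
`subset_corrected` mode on disjoint flat/non-flat × chewing/non-chewing
cells is always available and co-reported by the pipeline; on the headline
totals it gives χ² ≈ 39.9, a much stronger association — the faithful
layout understates the effect.

*Frequency model*: ordinary least squares of median frequency (kHz) on
behaviour + individual, both categorical. The analysis this reproduces was
described as a "logistic regression", but its published coefficient table
is in kHz with t-values, and the factor tests are F statistics — outputs a
logistic model cannot produce — so the linear model is implemented and
documented here prominently. F tests are sequential (behaviour entered
first); behaviours with fewer than 2 events are dropped and logged; the
reference level defaults to Down explore, the only ethogram behaviour
absent from the published table rows (inferred, flagged here). Predictions
are intercept + estimate (0 for the reference), rounded to nearest kHz.

*Subtype × diet ANOVA*: two-way OLS ANOVA on per-rat subtype counts,
used to justify pooling the two test-meal diets when the diet main effect
and interaction are non-significant. The subtype factor has 13 df for the
14-type taxonomy.

## Problem sizes used in the test suite

Worked-example reproductions run on the printed inputs in milliseconds.
The oracle comparison uses 20 random 600 s sessions at 10,000 shuffles;
null calibration uses 200 cohorts × 16 rats at 1,000 shuffles; power uses
100 replicates × 4 rats at 1,000 shuffles; the detector benchmark uses
three ~25 s 384 kHz recordings containing two calls of every subtype. The
whole suite completes in about a minute on one core.

## Known limitations

- The detector assumes one animal per channel; overlapping calls merge.
- Subtype boundaries (short/flat duration, flat bandwidth) are not
  published numerically anywhere; the defaults here are explicit but other
  choices are defensible, and results near boundaries shift accordingly.
- The chi-square "faithful" layout double-counts flats; use
  `subset_corrected` for inference and the default only for comparison with
  the published value.
- No mixed-effects variant of the frequency model (the individual enters as
  a fixed factor), and no reproduction of distributions that would require
  the original recordings.
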