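# Methods

This note documents the models and procedures `sleepso` implements, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions taken where a published procedure
leaves room.

## Candidate events and morphology

A candidate SO is the stretch of band-pass-filtered signal between two
consecutive positive-to-negative zero-crossings (sample `i` with
`x[i] > 0` and `x[i+1] <= 0`).  Intervals are half-open `[start, end)` and
0-based, so durations are exactly `(end - start) / fs`.  Crossings snap to
integer samples; sub-sample interpolation is deliberately omitted because a
±1-sample position error is three orders of magnitude below the 0.8-s
minimum event duration.

Filtering is a 2nd-order Butterworth band-pass (labeling band 0.1–1.25 Hz)
applied forward-backward (`sosfiltfilt`).  Zero-phase filtering is the
default because causal filtering would shift event timing by a
band-dependent group delay and corrupt the 50%-overlap evaluation; the
consequence — the effective magnitude order doubles — is accepted and a
causal flag is kept for experiments.

Morphology per event: total duration (d₁), first-crossing→negative-peak
(d₂), negative→positive peak (d₃), positive-peak→second-crossing (d₄; the
three parts sum to d₁ exactly), positive-peak count, negative-peak voltage
(segment minimum), positive-peak voltage (maximum *after* the negative
peak — the up-state follows the down-state), and their difference, the
negative-to-positive peak-to-peak amplitude.

**Peak counting.** "Number of positive wave peaks" is counted over the
whole event as local maxima with positive voltage and a prominence of at
least 10% of the event's peak-to-peak range (plateaus count once).  A pure
strict-local-maximum rule is available (`prominence_fraction=0`) but is not
the default: on band-limited data with residual noise it counts sub-µV
ripples no rater would call a wave peak, which turns the peak-count
pre-filter criterion into a noise detector and needlessly discards well-
formed SOs.  The prominence floor matches what a rater resolves at the
scale of the event.

## Pre-filtering

Manual labeling of every candidate in an overnight or nap recording is
infeasible, so thresholds are derived from a labeled sample on one channel:

1. For each of the five parameters (d₁–d₄, positive-peak count), compute
   mean and SD over the labeled SOs (population SD, `ddof=0`; the estimator
   is configurable) and lay a nine-value grid over mean ± 2 SD (values for
   the peak count are rounded to integers).
2. Starting from the grid maximum (the permissive end under the upper-bound
   reading), repeatedly compare the current value with the next smaller
   one: if the TPR lost exceeds the FPR lost, stop and keep the current
   value; otherwise step down.  TPR/FPR are evaluated per criterion
   independently, with the other criteria disabled (marginal evaluation;
   a joint walk is a possible variant but the per-parameter procedure is
   the one implemented).
3. The two amplitude thresholds are scale factors: minimum over average of
   the labeled SOs' peak-to-peak amplitude, and of the negative-peak
   voltage.  For the negative peak, "minimum" is taken in magnitude (the
   least negative labeled SO), so both factors land in (0, 1] and — applied
   to the derivation channel — retain every labeled SO by construction.
   The negative-peak comparison is on the voltage axis: an event passes if
   its negative peak is *at or below* `scale × channel average`.
4. The minimum duration stays fixed at 0.8 s.

Degenerate cases: with an empty negative class the FPR is defined as 0
(with a warning) so the walk remains total; it then stops at the first grid
step that loses any TP.

## Classical detectors

All three operate on candidates from a 2nd-order Butterworth band-pass and
report **full candidate spans** (crossing to crossing) so that overlap
evaluation treats them uniformly — the absolute detector's criteria are
evaluated on the down-state half-wave, but a half-wave span would be
structurally shorter than the other detectors' events and bias matching.

| detector   | band (Hz)  | duration gate      | amplitude rule |
|------------|-----------|---------------------|----------------|
| absolute   | 0.1–4     | half-wave 0.3–1 s   | neg peak < −40 µV and p2p > 70 µV |
| relative   | 0.1–2     | event 0.9–2 s       | p2p > ⅔·avg and neg peak < ⅓·avg neg peak |
| percentile | 0.16–1.25 | event 0.8–2 s       | largest 25% by p2p |

The absolute thresholds are the aging-adjusted values (−40 µV / 70 µV); the
classic −80 µV / 140 µV pair suits young adults and can be set through
`DetectorConfig`.  The relative detector's averages are computed per
channel over all duration-eligible candidates; its negative-peak rule is
compared on the voltage axis (both sides negative, more negative passes),
with a magnitude reading behind a flag.  The percentile detector returns
exactly `floor(0.25 · n)` events per channel, ties broken by earlier onset
(rounding and tie rules are not fixed by convention; floor + earliest onset
is deterministic).  `DetectorConfig.assume_filtered` skips the internal
filter for inputs that are already band-limited (used heavily in tests,
where noise-free templates carry exact crossing structure).

## DTW, LB-Keogh, DBA, and the index tree

The DTW local cost is the squared sample difference and the accumulated
path cost is returned without a square root — monotone in the rooted
distance, hence equivalent for nearest-neighbour ranking — under a
Sakoe-Chiba band of half-width `window` (default 10% of the longest
training series).  A window smaller than the length difference of the two
series admits no path and is rejected.

LB-Keogh compares one series against the windowed min/max envelope of the
other with the same local cost; it is an exact lower bound for equal-length
series.  Unequal lengths are handled by linearly resampling the shorter
series to the longer one's length, which makes the bound heuristic; the
index search therefore only prunes with it where lengths match, keeping
the exhaustive-budget search exactly equal to brute-force 1-NN.

DBA (DTW Barycenter Averaging) starts from the first series, aligns every
member to the centroid along an optimal path, and replaces each centroid
sample by the mean of aligned samples.  The objective (within-set sum of
DTW distances) is non-increasing; an update that would increase it (a
numerical-edge case) is rejected, so monotonicity holds by construction.

The time-series index is a hierarchical k-means tree: up to 10 clusters
per level (DBA centroids, DTW assignment, at most 10 Lloyd iterations,
empty clusters repaired by donating the farthest member of the largest
cluster), recursing until clusters hold ≤ 30 series.  Identical-series
degeneracies split by chunking to guarantee termination.  Queries descend
best-first by centroid DTW distance; at leaves, surviving members are fully
compared, each consuming one unit of the search budget ("examples seen",
default 1,000).  Ties in nearest-neighbour distance resolve to the lowest
training-series index, making results reproducible bit-for-bit.

## Classifiers

The 17-feature registry (durations d₁–d₄, positive/negative peak counts,
negative/positive peak voltages, peak-to-peak amplitude, segment mean, SD,
skewness, excess kurtosis, negative half-wave area, negative-to-positive
slope, within-event zero-crossing count, energy) is a documented stand-in
with the canonical cardinality — the exact published list is not machine-
readable — and is pluggable: swapping the registry changes nothing
downstream.  Distributional features use the effective sampling rate
`len(waveform)/d_total`, so resampled waveforms stay consistent.

Classical models come from scikit-learn (logistic regression, decision
tree, random forest, SVM, MLP) behind a grid-searched, standardized
pipeline; feature selection offers univariate ANOVA scoring, random-forest
importances, RFE, and PCA.  DTW feature construction clusters the training
waveforms with average-linkage hierarchical clustering on the pairwise DTW
matrix, cuts at the requested prototype count (500 at study scale; tests
use tens), takes each cluster's medoid, and uses DTW distances to the
prototypes as features.

The sequence classifier is a compact numpy BiLSTM: stacked bidirectional
LSTM layers (default hidden sizes 16 and 8), masked mean-pooling over time,
logistic output, Adam on binary cross-entropy (learning rate 0.01, batch
256, up to 80 epochs, early stop after 30 epochs without loss improvement
beyond 1e-5 — Adam plateaus and escapes, so short patience systematically
underfits).  Padded steps are copy-through in both directions and excluded
from pooling, making predictions invariant to trailing padding; the
hand-derived BPTT gradients are verified against finite differences in the
test suite.  Inputs are globally standardized by the training set's scalar
mean/SD so the amplitude information (in µV) survives as a feature.

Evaluation uses repeated stratified 70/30 shuffle splits (10 by default)
scoring balanced accuracy, and a learning-curve helper that subsamples the
training pool at requested sizes.

## Evaluation

Detected and reference events rarely share boundaries (different bands), so
matching is by overlap: a detected event is a true positive if it overlaps
some reference SO by ≥ 50% of the *detected* event's duration; matching is
one-to-one, greedy by overlap size.  A reference non-SO untouched by any
detection covering ≥ 50% of the *reference* duration is a true negative; an
unmatched reference SO is a false negative.  The denominator convention
(the event whose status is being decided) is not the only defensible one;
an intersection-over-union variant is available via `denominator="iou"`.
Balanced accuracy is implemented in its expanded form,
½·(TP/(TP+FN) + TN/(TN+FP)), i.e. mean of sensitivity and specificity.

Stage densities assign each event to the hypnogram epoch containing its
negative peak (events straddling epoch boundaries are not split); artifact
epochs are excluded from the denominators.  Average waveforms align events
at their negative peaks over ±1.25 s, zero-padding at recording edges.

## Synthetic generator

The generator emulates the *structure* of a labeled sleep-EEG study, not
its physiology: a 90-minute nap hypnogram (Wa 10, N1 10, N2 40, N3 30
minutes), Poisson-thinned SO event times with stage-graded densities
(0.5 / 1.5 / 4 / 7 events·min⁻¹ for Wa/N1/N2/N3) and amplitudes
(peak-to-peak means 70/80/90/105 µV, SD 10–15, truncated below 60 µV —
an SO is by definition a large-amplitude event, and raters do not tag
smaller ones), low-amplitude distractor slow events at 40% of the stage
mean (3 min⁻¹), and 1/f^1.5-shaped Gaussian background at 10 µV RMS.

The SO template is a raised-cosine biphasic wave whose lobe durations are
chosen so the areas cancel (the deeper down-state is shorter, the broader
up-state shallower): a zero-area template both matches the physiological
asymmetry and avoids rebound artifacts under the 0.1-Hz high-pass.  The
first sample carries a +0.5 µV epsilon so the leading positive-to-negative
crossing exists even on a silent baseline.

The synthetic *rater* (`label_candidates`) tags an extracted candidate as
SO only if it mutually overlaps an implanted SO by ≥ 50% **and** its total
duration is ≤ 2 s — mirroring how raters are instructed to mark only
events that look like SOs.  A candidate stretched far beyond the implanted
template by surrounding slow activity, or a fragment clipping only part of
it, is not the event a rater would see.

What the generator does **not** emulate: spindles, K-complexes, artifacts,
inter-channel correlation, non-stationary noise, or realistic SO waveform
variability beyond amplitude/duration draws.  Passing tests therefore
demonstrate procedural correctness and qualitative behavior (stage
orderings, detector rankings, pre-filter retention), not clinical-grade
accuracy; the high classifier accuracies reflect the generator's clean
class separation and will not transfer numerically to real recordings.

## Problem sizes

The test suite and `scripts/acceptance.py` run on one CPU in a few
minutes.  Chosen sizes: 200 random pairs for the DTW oracle, 300 training
series / 100 queries for the index-vs-brute-force check, 2,000-event
corpora (60% SO) for classifier evaluation, 2,900 events for the learning
curve (so a 2,000-event training set leaves a held-out 30%), and one
90-minute simulated recording for detector and pre-filter checks.  Corpus
recordings are simulated at 100 Hz (the labeling band ends at 1.25 Hz, so
this is comfortably oversampled) with denser stages so a target event count
is reachable quickly; full-rate 500-Hz recordings are used everywhere
event timing matters.

## Known limitations

- The pre-filter's grid walk evaluates criteria marginally; a joint walk
  could stop elsewhere on strongly correlated parameters.
- LB-Keogh on unequal-length series is a heuristic bound (documented
  above); pruning is restricted to the exact case.
- The percentile detector's per-channel floor rule yields zero detections
  on channels with fewer than four candidates.
- The BiLSTM is a minimal reference implementation: no dropout, no
  gradient clipping, single-threaded; it is adequate at corpus scale but
  not a production deep-learning stack.
- Serialized TSI trees store raw series as JSON and grow linearly with the
  training set; they are meant for fixture-scale reuse.
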