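# Methods

`vocalclust` groups discrete vocal elements — zebra finch song syllables or
mouse ultrasonic vocalizations (USVs) — into acoustic types from their
pairwise similarity structure, then quantifies phonology, cross-session
identity, syntax, and repertoire composition. This note records the models,
the tunable parameters with their defaults, the numerical choices, and the
limits of what the synthetic test bed demonstrates.

## Signal layer

Recordings are mono WAV (finch song at 44.1 kHz/16-bit, USV sessions at
250 kHz). Samples are scaled to [-1, 1] by the full-scale magnitude of the
integer format. Spectrograms are short-time Hann-windowed magnitude
matrices; the *spectral derivative* option is defined here as the first
difference of log magnitude along time (first frame zeroed), which is near
zero for stationary sound and highlights onsets and frequency modulation.

**Pitch contours (USVs).** A call is cut into non-overlapping 44-sample
windows; each window's spectrum is masked to the 40–120 kHz analysis band
(spectral masking rather than time-domain filtering); a per-window dominant
frequency is estimated; and the median over every 5 consecutive windows
yields one contour value per ~0.88 ms (44·5/250000 s). Trailing samples
that do not fill a window, and windows that do not fill a 5-block, are
dropped, so the contour length is exactly `floor(floor(n/44)/5)`. The
per-window estimator is the power-weighted mean frequency of the masked
spectrum (robust for narrowband calls); a peak-bin alternative is available
via `estimator="peak"`. Neither variant is claimed to reproduce any
particular external tool's estimator. The frequency resolution of a
44-sample window at 250 kHz is ~5.7 kHz per bin; the weighted mean
interpolates well below that for clean tones.

## Segmentation

**USVs** are detected on the RMS amplitude envelope (1 ms sliding window —
kept below the 2 ms minimum-sound rule so smoothing cannot mask it). A call
is a maximal supra-threshold region whose internal sub-threshold gaps are
each shorter than 10 ms (`gap_close`); a sound must stay above threshold
for more than 2 ms (`min_above`, applied to the longest contiguous run);
anything longer than 150 ms after gap closure (`max_duration`) is discarded
whole as noise. The completion gap is not clipped: a call ends at its last
supra-threshold sample. The threshold is user-set; the default is 5× the
median envelope of the recording, a robust noise-floor multiple. The
interactive "discard noise clips" step of a manual workflow is replaced by
a review manifest (per-element peak in-band energy) the user can filter.

**Birdsong** is clipped from the raw recording using an external
segmenter's onset/duration table (columns `element_id, onset_s,
duration_s`); each syllable is the exact half-open sample slice
`[round(onset·rate), round((onset+duration)·rate))`.

## Similarity backends

**Broadband (finch) backend.** Each syllable is summarized
millisecond-by-millisecond (9.3 ms windows, 1 ms steps) by four features:
Wiener entropy (log of geometric over arithmetic mean of the power
spectrum; 0 for white noise, strongly negative for tones), power-weighted
mean frequency, frequency modulation (the angle of spectral change over
time versus over frequency), and pitch goodness (peak of the real cepstrum
in the 300 Hz–8 kHz pitch range). A pair of syllables is compared in this
feature space after per-pair pooled-SD standardization: *similarity* is the
percent of steps whose feature distance to the best globally-aligned region
of the other syllable (±10-step shift search) falls below 0.75 pooled-SD
units; *accuracy* is `100·(1 − mean distance/2)` over the matched overlap;
*temporal overlap* is `100·min/max` duration; and the global similarity
GS = similarity·accuracy·overlap/10000 on a 0–100 scale. The two
calibration constants were fixed so that self-comparison scores exactly 100
while unrelated white-noise pairs average below 20 GS. The comparator keeps
the classic output contract (two percent terms, overlap, GS product) but is
not bit-compatible with any external similarity batch.

**Narrowband (USV) backend.** Contour pairs are onset-aligned (calls are
clipped at detected onset, so index 0 is the natural register; a
shift-optimized alignment is deliberately not the default) and compared
over the leading `min(len_a, len_b)` windows: Pearson correlation of raw
pitch; pitch-difference score `1 − mean|Δpitch|/80 kHz` (the 40–120 kHz
band width); temporal overlap `min/max` length. The product lies in
[-1, 1]. Degenerate correlations are defined explicitly: two flat contours
correlate 1 (identical shape), a flat against a modulated contour 0. "Flat"
means contour SD below 2 kHz — above the ~1 kHz wiggle of the pitch
estimator at moderate SNR and well below the ≥3 kHz contour SD of genuinely
modulated calls.

**Dissimilarity.** Finch: Euclidean distances between rows of the GS matrix
(two syllables are close when they relate to the whole repertoire the same
way). Mouse: `1 − score` elementwise.

## Clustering

Average-linkage (UPGMA) hierarchical clustering, followed by an adaptive
tree cut in the spirit of dynamic hybrid dendrogram pruning, implemented
in-package: descending from the root, a branch becomes a cluster at the
first node whose merge gap to its parent, relative to the parent's height,
reaches a sensitivity-dependent minimum (0.15/0.35/0.55/0.75/0.95 for
`deep_split` 0–4). Leaves trivially qualify, so the recursion always
terminates; branches merging at height zero (exact duplicates) are never
split; higher `deep_split` demands larger gaps, descends deeper, and never
yields fewer clusters; clusters below `min_cluster_size` are absorbed into
the nearest cluster by average distance. Defaults are the most divisive
settings: `min_cluster_size=1`, `deep_split=4` — deliberate over-splitting
that the merge step then undoes.

**Eigen summaries.** Each cluster is summarized by its eigensyllable /
eigencall: member similarity profiles (rows of the M×M matrix) are
standardized and decomposed by SVD; the first principal direction over
elements is the eigen-profile, `s₁²/Σs²` its explained variance, and each
member's Pearson correlation with it the membership strength. Singletons
and clusters of identical members have explained variance 1 and
correlations 1 by construction; all-flat profiles are defined the same way.

**Iterative merging.** For rho = 0.99 down to 0.00 in steps of 0.01, the
pair of clusters whose eigen-profiles correlate highest is merged whenever
that correlation ≥ rho (highest pair first — deterministic and
order-independent for well-separated data), eigens are recomputed, and the
process repeats. Per rho the cluster count and mean cohesion are recorded —
IGS (mean intracluster pairwise similarity; singletons score the backend
maximum) when within-session scores exist, mean explained variance
otherwise. Counts stable over ≥2 consecutive thresholds are *plateaus*; the
default selection policy takes the largest-span plateau (ties: more
clusters), and `expected_n` lets the user impose a repertoire-size prior —
an irreducibly human judgement that is exposed as configuration, not
inferred. Because mutually anticorrelated cluster profiles never merge even
at rho = 0, the floor of the sweep typically sits at the true type count
for well-separated repertoires.

**Quality control.** Clusters whose mean member-to-eigen correlation is
≥ 0.8 (configurable) are represented by their best-correlated member for
one-shot classification; clusters below it are dissolved and classified
member-by-member. The classification vocabulary is the ten canonical
retrieval-call types plus `double`, `triple` (multi-call clips), and
`miscellaneous`. Classification itself stays human-in-the-loop; a
plain-text relabeling table (`apply_relabeling`) supports manual error
correction.

## Cross-session assignment

Each cluster contributes its top `ceil(0.10·size)` members by eigen
correlation (at least one) as representatives. A later-session element is
scored against all representatives; clusters with mean score ≥ the
user-set floor are candidates (the floor is an experiment-level choice:
high for stable adult song, lowered when degradation is expected). Zero
candidates → novel; one → assigned; several → one-way ANOVA over the
per-representative score groups, then Welch pairwise comparisons of the
top-mean cluster against each other candidate, Bonferroni-corrected over
those k−1 tests; only a top cluster significantly above all others is
assigned, otherwise the element enters the tie queue. ANOVA groups are the
representative scores only (consistent with the top-10% workflow); a
single-representative group enters the post-hoc via a one-sample test
against its lone score, and two singletons can never separate (p = 1).
Tie policies: `interactive` (decisions file; undecided elements stay tied),
`best_mean`, or `unassigned`. Novel elements are clustered among themselves
via the Pearson correlation of their rows in the element×representative
score matrix (1 − r as dissimilarity), with explained variance as the
merge-trace cohesion since no within-session scores exist; new ids extend
the established set. In longitudinal designs each session is assigned
against the most recently clustered session.

## Syntax

First-order transition probabilities over consecutive label pairs,
self-transitions included; rows of types that never lead remain zero; the
vocabulary is sorted alphabetically for reproducibility. Session
comparisons correlate corresponding rows over the union vocabulary and
average: unpenalized variants average over shared types that lead in both
sessions; penalized variants average over the union with absent types as
all-zero rows. Weighted variants multiply each row correlation by
`1 − |f_a − f_b|` (frequency agreement). Degenerate rows: identical rows —
including two all-zero rows — correlate 1 (so self-comparison is exactly 1
for all four scores); an all-zero or otherwise zero-variance row against a
different row correlates 0, which is precisely the novel-type penalty. The
penalty therefore pulls scores toward zero; it strictly lowers them in the
positively-correlated regime of real session comparisons.

Syntax entropy is a normalized conditional entropy:
`Σ_t f_t · H(tp_t) / log₂(n)`, in [0, 1] — 0 for deterministic sequencing,
1 for uniform transitions. The normalization by `log₂(n)` is this package's
fixed interpretation of "string-based" sequence entropy; only its
qualitative contract (low = stereotyped) should be compared across tools.

## Resampling statistics

All tests default to 10,000 draws and are bit-reproducible given a seed.
Two-sided p-values count `#{|null| ≥ |observed|}/n_draws`; a `(k+1)/(n+1)`
smoothing option avoids p = 0. Independent mean differences: pooled
redrawing with replacement at the observed group sizes. Paired differences:
random sign flips. One-way resampling ANOVA: the classical F statistic
under label permutation, with Bonferroni-corrected pairwise post-hocs over
all group pairs.

**Repertoire difference.** The reference genotype's per-type median counts
define a resampling pool; each draw samples the test genotype's total call
count with replacement and tallies per type. Because the comparison is
against per-animal means, each tally is divided by the number of test
animals so both sides share a scale. A type is flagged over-/under-
represented when the test mean ± SEM (SD/√n animals) lies entirely outside
the 95% percentile interval of the draws. **Repertoire correlation** is the
mean pairwise Pearson correlation of per-animal count vectors within and
between genotypes (constant vectors excluded with a warning); within-group
correlation sets are compared with the independent resampling test when
both groups yield at least two pairs.

## Synthetic test bed

The generator emulates two regimes with known ground truth: narrowband
USV-like sessions (flat / upsweep / downsweep / chevron / complex-trill
contour archetypes as phase-integrated FM tones with 1 ms cosine ramps,
sequenced by a first-order Markov chain, Gaussian inter-call gaps, additive
white Gaussian noise) and broadband birdsong-like syllables (the same
machinery at 44.1 kHz with a 3-partial harmonic stack, giving the feature
backend non-trivial entropy and periodicity structure). Default conditions:
40 ms calls, 100 ± 20 ms gaps, noise SD 0.002 against amplitude 0.5
(≈48 dB SNR), per-rendition frequency jitter 1 kHz and duration jitter 5%,
≥15 renditions per archetype. The canonical archetype sets place shapes in
distinct band positions, as the real retrieval-call categories do.

What passing tests show — and do not show: the synthetic bed exercises
thresholds, alignment, clustering geometry, and statistical calibration,
and end-to-end recovery (archetype ARI ≥ 0.9, exact cross-session
relabeling, novelty detection) holds under these clean conditions. Real
recordings add reverberation, broadband transients, overlapping callers,
amplitude drift, and call-shape continua between categories; none of these
are modeled, so real-data performance depends on recording quality and
threshold choices in ways the test bed cannot certify.

## Problem sizes and numerical notes

Test and acceptance runs use 45–75-call sessions (3–5 archetypes ×
15 renditions), 12-element oracle matrices, 1000-trial type-I calibrations
at ~1000 draws per trial, and 300 null repertoire simulations at 2000
draws — sizes chosen so the full suite runs in well under a minute on one
CPU while keeping every statistical band meaningful. Ties in the merge step
are broken by lowest cluster id; UPGMA input symmetry is checked to 1e-8;
correlations guard zero-variance inputs explicitly everywhere rather than
relying on NaN propagation.

## Known limitations

- The broadband comparator is contract-compatible, not bit-compatible,
  with legacy similarity batches; absolute GS values are comparable only
  within this package.
- Onset-aligned contour overlap under-scores calls whose similarity is
  shift-dependent (e.g. truncated onsets); the shift-optimized mode exists
  but changes the score scale subtly (more pairs reach high correlation).
- The adaptive tree cut reproduces the dynamic-hybrid *contract*
  (shape-derived cluster count, minimum size, monotone sensitivity), not
  its exact partitions; downstream results are insensitive to this because
  the merge sweep re-derives the final count.
- The repertoire-difference rule inherits the family-wise behavior of the
  published procedure: with many call types its null flag rate approaches
  ~5% in aggregate, not per type.
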