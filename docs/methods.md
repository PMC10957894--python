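# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, the synthetic-data generator's
calibration, and the limits of what desk-scale validation establishes.

## Word-level predictors

The lexical model treats each content word as a point in a 12-dimensional
property space: number of letters, number of phonemes, phonological and
orthographic neighbourhood sizes, word frequency, concreteness, semantic
neighbourhood density, semantic diversity, valence, arousal, dominance,
and socialness (1–5).  Assembly excludes closed-class words, words above
a configurable frequency quantile (default 0.95 — the exclusion of
"high-frequency" words is inherently a judgement call, and a quantile is
a reproducible one), and words missing more than 10 of the 12 properties.

**Imputation.**  Missing norms are imputed by chained equations with
predictive mean matching (statsmodels `MICEData`), m = 5 completed
datasets, 10 cycles by default (5 in the desk-scale drivers).  PMM keeps
every imputed value inside the observed range of its property, which
matters for bounded scales such as socialness.  The imputation never
alters observed cells and is deterministic given a seed.

**Factor model.**  Each completed dataset is standardized per property
(correlation-metric PCA — covariance-metric PCA would let the wider
scales dominate) and the first four components are varimax-rotated.  The
factor count is fixed at k = 4 rather than chosen by an eigenvalue rule:
the model targets the four named factors (Word Length, Semantic
Flexibility, Emotional Strength, Social Impact).  Factor sign is
arbitrary, so each factor is flipped to make its largest-magnitude
loading positive, factors are ordered by rotated variance, and models
from different imputations are aligned to the first by maximal absolute
congruence before element-wise averaging of loadings.

**Scores.**  Factor scores use the regression method, `Z R⁻¹ L`, with
`R` the pooled correlation matrix — the conventional default when no
scoring method is specified.  Scores are averaged over imputations; the
Emotional Strength column is then replaced by its absolute value so it
indexes emotional versus neutral content rather than valence polarity.
A consequence worth noting: the validity of regression scores is bounded
by the loading strength.  With the variance-calibrated loadings below,
the maximum attainable correlation between Semantic Flexibility scores
and the generating latent is ≈ 0.88, and ≈ 0.74 for Social Impact (two
indicators).  Score-recovery tests therefore use a dedicated
strong-loading generator; the calibrated lexicon is validated through
loading congruence and the variance split instead.

**Socialness extrapolation.**  A word without a normed rating but with
an embedding receives the similarity-weighted mean rating of its k = 10
most cosine-similar normed words, ties broken alphabetically.  Negative
similarities are clipped to zero before weight normalization — negative
weights could push the result outside the neighbours' rating range — and
if every retained similarity is non-positive the unweighted mean is used
with a warning.

## Event-level data

Events carry integer 1–10 semantic and social ratings.  Machine-checkable
rubric constraints (rating range, positive duration, ordering,
non-overlap, and the rule that no event scores 9–10 on both dimensions)
are validated report-style.  Inter-rater reliability uses Krippendorff's
alpha in its coincidence-matrix form; the measurement level defaults to
interval (ratings treated as numeric), with ordinal available, since the
level is a modelling choice.  Alpha below 0.75 flags ratings for
consensus revision — the revision itself is a human act, represented
only by the flag plus a rating-override table.

Events shorter than 3 s are merged into their *successor* (onset of the
earlier, summed duration, arithmetic-mean ratings).  Two boundary cases
need a policy: a trailing short event merges backward, and chains of
consecutive shorts iterate until every event is at least 3 s (or one
event remains).  Merged ratings are kept real-valued rather than
re-rounded to the integer scale.  Total rated time is conserved exactly.

Words are assigned to events by onset using half-open intervals
`[onset, onset + duration)`, which prevents double counting at
boundaries; transcript word durations are ignored as noisy.

## Window series

Per-word values are summed inside a window (default 5 s) sliding in
1 s steps.  The window grid restarts at each event's onset and is
clipped at the event's end, so no window ever mixes words from two
events; a final fragment shorter than the step still yields a (shorter)
window rather than being discarded.  Factor series are residualized —
per movie, since word-rate regimes differ across films — on the total
word count per window (OLS with intercept), leaving residuals exactly
uncorrelated with the counts.  Windows containing no rated words are
*dropped* for factor predictors: after mean-centering, a zero would
denote average-scoring words, not silence.  The content-word count
predictor keeps zero-count windows, because a zero count is meaningful.

## First-level GLM

Modulator values are mean-centered, placed as impulses at window starts
(starts rather than centers — a choice the data cannot adjudicate) on a
0.1 s grid, convolved with a canonical double-gamma HRF (5 s peak, 15 s
undershoot, unit peak, truncated at 32 s, configurable), and sampled at
the TR grid (default TR 1 s).  Event models use three regressors:
unmodulated boxcars over each event's span (baseline), boxcars scaled by
the mean-centered rating of interest, and boxcars scaled by the
mean-centered other rating (nuisance).  Mean-centering plus the explicit
baseline decorrelates "stimulus on" from "stimulus intensity"; with
random ratings the modulated/baseline correlation stays below 0.2.

The voxelwise fit is OLS with polynomial drift columns (order 0 —
intercept only — by default, as the input BOLD is assumed detrended and
motion-censored upstream; a censor vector drops flagged volumes).
Residual spatial smoothness per axis comes from the variance of spatial
first differences of the per-voxel-standardized residuals:
`σ² = d² · var(z) / (2 · var_diff)`, the gradient-based Gaussian-kernel
equivalent.  For white noise this returns ≈ 1.18 voxels; for smooth
fields it recovers the width of the kernel that would generate them.

## Group level and cluster inference

Each subject contributes one map and watched one movie, so "random
intercepts of subject and movie" is not separately identifiable: the
subject intercept is absorbed into the residual, leaving a one-way
random-movie model fit voxelwise by REML (variance ratio profiled on a
log grid including zero).  The fixed-effect statistic is referenced
against a t distribution with a Satterthwaite-style effective df that
blends the movie-level df (J−1) and the residual df (S−J) by the movie
component's share of the intercept variance — a hard switch to J−1
whenever the movie variance is positive would make desk-scale analyses
(2–4 movies) needlessly erratic.  The statistic is converted to z
preserving the two-sided p, capped at ±40 for degenerate voxels.

Cluster correction simulates Gaussian null fields smoothed at the
(median-across-subjects) estimated FWHM inside the mask, standardizes
within the mask, thresholds two-sided at the cluster-forming quantile
(p < .01), labels components with faces-only (NN = 1) connectivity
separately per sign, and returns the smallest extent k with
P(max cluster ≥ k) ≤ p_FWE.  Both the pre-registered (p < .05) and
strict (p < .01) FWE variants are computed.  The null fields use a pure
Gaussian kernel rather than a long-tailed autocorrelation model; this is
a simplification stated openly, and its self-consistency is what the
calibration tests check.

## Overlap

Subject-level maps are thresholded with *subject-specific* cluster
extents derived from each subject's own residual smoothness.  Binary
overlap gives Dice and voxel counts, with fewer than 10 overlapping
voxels treated as functionally zero.  For cross-subject analysis,
thresholded maps are normalized by their maximum statistic and the two
conditions' normalized maps multiplied voxelwise; the products feed the
same random-effects group model.  Because the products are non-negative
and mostly zero, this test is anti-conservative, and the output metadata
carries that caveat verbatim.  The rejected binary-overlap alternative
(aggregate any-overlap masks) is available but non-default.

## Synthetic data generator

The generator emulates the study conditions, with every artifact a pure
function of (parameters, seed):

- **Lexicon** — properties arise from four latent factors via a
  single-parent loading plan whose magnitudes (0.917 / 0.731 / 0.682 /
  0.619) were solved once so that the *fitted* varimax-PCA variance split
  lands on ≈ 29/17/16/11% (PCA absorbs some unique variance, so the plan
  is slightly weaker than the targets); z-scores map affinely to
  realistic norm scales, socialness bounded in [1, 5], counts rounded and
  non-negative; MCAR missingness at a configurable rate (< 0.5).
- **Embeddings** — vectors interpolate between two orthogonal anchors by
  socialness plus isotropic noise, so cosine neighbourhoods carry
  socialness; hold-out extrapolation recovers ratings with MAE < 0.8.
- **Events** — log-normal durations (post-merge median ≈ 16 s, clipped
  to [4, 131] s), ≈ 4% of pre-merge events under 3 s; integer ratings
  from correlated Gaussians (r ≈ 0.25) mildly coupled to log duration
  (coupling 0.30), dual-9/10 rule enforced by demoting the weaker latent.
- **Transcripts** — Poisson word counts with rate ∝ duration ×
  exp(0.42·z_sem + 0.27·z_soc + 0.10·noise), calibrated once so the
  empirical correlations of word count with duration, semantic and social
  ratings fall inside 0.55–0.86, 0.40–0.76 and 0.32–0.56; onsets uniform
  within events; tokens mix lexicon draws (55% open-class) with a small
  closed-class vocabulary.
- **BOLD** — the pipeline's own forward model: known betas (spheres of
  configurable radius) times the analysis regressors, plus AR(1) noise
  (φ = 0.3) smoothed spatially at 4 mm FWHM.  Word-level forward
  regressors use the lexicon's *true* latent factors, so recovery via the
  estimated factor scores is a genuine end-to-end test.

## Problem sizes and what the tests show

Desk-scale runs use 10³–16³ grids, 2 mm voxels, 150–400-word lexica,
35–300 events per movie, 6–20 subjects over 2–4 movies, and reduced
Monte-Carlo counts (150–2000 null fields) — sizes chosen so the full
suite exercises every stage end to end while remaining routine to run.
Two scale effects are worth knowing.  First, with few movies the
movie-level df is tiny; the Satterthwaite blending above keeps group
inference usable, but group z values at desk scale are not comparable to
a 10-movie study.  Second, the scrambled-ratings null is only clean when
the event count is realistic: with ~40 events a scrambled rating vector
retains a chance correlation of ~0.16 with the truth, enough for a
strong planted effect to leak through; at ~300 events per movie (the
realistic count) the null behaves as intended, and the null-calibration
test runs at that size.

Passing tests establish that the machinery is correct and calibrated
under the generator's assumptions (Gaussian latents, AR(1)+Gaussian
noise, known HRF, MCAR missingness).  They do not establish robustness
to real-data violations: HRF variability across regions, non-Gaussian
noise and motion artefacts, systematically (not randomly) missing norms,
or annotation idiosyncrasies.  Real-data anatomical results (cluster
coordinates, atlas labels, observed Dice distributions) are outside what
synthetic validation can reproduce.
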