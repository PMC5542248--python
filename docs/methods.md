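# Methods

## The peaks transformation

A case is a multiset of per-cell DNA-index (DI) values.  Its feature vector
is built in three steps.

**Density.**  A Gaussian kernel density estimate is evaluated on an equally
spaced grid of 512 points spanning `[min − 3h, max + 3h]`.  The default
bandwidth is Silverman's rule in its nrd0 form,

    h = 0.9 · min(s, IQR/1.34) · n^(−1/5),

with the standard deviation substituted when the IQR is zero and a
degenerate-sample error (advising a fixed bandwidth) when the sample has no
spread at all.  These are the conventional defaults for one-dimensional
density plots and are all exposed in `DensityConfig` (fixed bandwidth, grid
size, tail extension).  With the default 3-bandwidth tail extension the
trapezoid integral of the curve is within 1% of 1; shrinking the extension
clips kernel tails and is allowed but not recommended.

**Peaks.**  The lagged differences of the gridded density mimic its first
derivative.  A peak is a grid point where the curve was rising and starts
falling — a positive-to-negative sign change of the differences.  Two
conventions deserve note because the gridded curve can contain exact ties:

* a plateau (run of zero differences) preceded by a rise and followed by a
  fall contributes exactly one peak, at the first point of the run;
* the first and last grid points are never peaks.

The detector is equivalent to a brute-force scan of all grid points for
local maxima with plateau collapsing; the test suite asserts exact
agreement on 1,000 randomized curves.

**Intervals.**  Peak locations are tallied into ten ploidy intervals
centred on the integers 1–10.  Interval *k* covers `[k−0.5, k+0.5)` —
lower-closed, half-open, so a location exactly at 1.5 belongs to
interval 2 deterministically — with locations below 0.5 folded into
interval 1 and locations at or above 9.5 into interval 10.  Every real
location therefore maps to exactly one interval and counts always sum to
the number of peaks.  Diploid populations peak in interval 1, tetraploid
in interval 2; aneuploid populations scatter peaks across the higher
intervals.

## The classifier and OCRI2

Feature tables carry a class character per row: `c` (carcinoma), `n`
(normal), `k` (leukoplakia).  Classifiers are fit on `c`/`n` rows only —
`k` rows are only ever scored, which is the point of the index: the model
learns the normal/cancer contrast and the leukoplakia cases land in
between.  Unknown-group cases are carried with the non-training sentinel
`k` so they can be scored but never fitted.

Training follows a two-cohort protocol.  Within the training cohort a
stratified random 70% is used for model optimization and 30% for internal
evaluation (the `svmfull` variant uses 100%).  Hyperparameters are chosen
by mean accuracy over 10-fold stratified cross-validation repeated 5 times
(50 resamples per candidate); exact ties go to the earliest candidate in
grid order, so results are reproducible from the seed alone.  Cross-
examination trains on one cohort's optimization split and evaluates on all
`c`/`n` rows of the other cohort, then reverses the roles with the same
spec and seed.

Model kinds and default grids:

| kind      | estimator                                  | tuned grid                 |
|-----------|--------------------------------------------|----------------------------|
| `rf`      | random forest, 500 trees, bootstrap        | features/split {2, 6, 10}  |
| `cf`      | extremely randomized forest, 500 trees     | features/split {2, 6, 10}  |
| `svm`     | RBF SVM, data-driven kernel width          | cost {0.25, 0.5, 1}        |
| `svmfull` | as `svm`, fit on 100% of the cohort        | cost {0.25, 0.5, 1}        |
| `knn`     | k-nearest neighbours, counts untransformed | k {5, 7, 9}                |

`rf` is the production model.  `cf` stands in for a conditional-
inference-style forest: no unbiased-split forest implementation exists in
this package's dependency set, and the extremely randomized variant —
whose split thresholds are drawn at random rather than exhaustively
optimized — is the nearest available forest baseline; its results should
be read as approximate.  Non-forest OCRI2 values use the estimator's
probability output (Platt-calibrated for the SVM) and are likewise
approximations of the forest-vote definition.  An optional `standardize`
switch scales counts before the distance-based models; it is off by
default since the counts share one scale.

One computational choice: hyperparameter candidates are *scored* in CV
with 100-tree forests and the winning candidate is refit at the full 500
trees (`ModelSpec.cv_n_estimators`).  Candidate ranking over the
three-point features-per-split grid is insensitive to forest size well
below 500 trees, and scoring at full size would make the 150-fit grid
search needlessly slow on a single core.  Setting
`cv_n_estimators=None` scores at full size.

**OCRI2** for forest models is the exact fraction of trees voting `c`
(granularity 1/500 by default), verified in the tests against per-tree
enumeration.  The risk cut-off is 0.5, inclusive on the high side:
OCRI2 ≥ 0.5 ⇒ high risk.

## Evaluation statistics

Cancer is the positive class.  Sensitivity, specificity, PPV and NPV come
from the confusion matrix; any metric whose denominator is zero is
reported as explicitly undefined, never as 0.  AUC uses the rank
(Mann–Whitney) formulation — the probability a random carcinoma outscores
a random normal, ties counted half — and is invariant under monotone
transforms of the scores.

The follow-up comparison tests the 2×2 table of risk group by malignant
transformation with the two-sided chi-square with Yates continuity
correction in its safeguarded form `Σ (max(|O−E|−0.5, 0))²/E`, so
perfectly independent tables give statistic 0 and p = 1, and the corrected
statistic never exceeds the uncorrected Pearson statistic.  The chi-square
is retained even at small expected counts (the reference outcome table has
a minimum expectation of ≈1.13) because that is the published comparison;
a two-sided Fisher exact test is available as `fisher_exact` for users who
prefer an exact small-sample test.  The three-category traditional-method
comparison uses the plain Pearson chi-square with df = 2 — the continuity
correction is defined only for one degree of freedom — and empty
categories are dropped (they contribute nothing to the statistic).

## The synthetic cytometry simulator

Each group profile is a per-case Gaussian mixture over DI:

* **normal** — diploid (mean 1.0, sd 0.05, weight 0.93) plus
  tetraploid/G2 (mean 2.0, sd 0.10, weight 0.07); no aneuploid component.
* **oscc** — the same backbone (weights 0.85/0.15) plus, in every case,
  2–4 aneuploid components with means drawn uniformly over DI 2.5–8
  (sd 0.25) carrying 45% of the mixture weight, so each simulated tumour
  scatters peaks differently across the high intervals.
* **olk_low / olk_high** — normal-like with a light aneuploid component in
  10% of cases, and oscc-like with aneuploid components in 60% of cases.

Aneuploid components are included per case, not per cell, modelling clonal
lesions.  Cell counts are drawn uniformly from 50–300 per case, a typical
brush-biopsy yield; DI values are resampled until positive, which with the
default means and spreads essentially never triggers.  All parameters are
exposed for power experiments.

What the simulator does **not** emulate: imaging noise, staining
artifacts, debris, inter-laboratory DI calibration drift, replicate
slides, or any correlation between DI profile and clinical covariates.
Passing tests therefore demonstrate that the transformation and classifier
recover planted distributional structure of the kind the method assumes —
not clinical performance on real cytometry data.

One emergent property worth knowing: under the nrd0 rule a normal case's
bandwidth is tiny (the IQR is set by the tight diploid component), so the
sparse tetraploid cells fragment into several interval-2 micro-peaks,
while the high-variance carcinoma cases smooth to at most one interval-2
peak.  The interval-2 count is thus an accidental within-cohort
discriminator that does not generalize across cohorts; with 50 cases per
class the cross-cohort error this induces is at most a few percent, which
is why cross-examination sensitivity/specificity hover at 0.95–1.0 rather
than exactly 1.0.

## Problem sizes and seeds

The bundled end-to-end checks use two simulated cohorts of 50 normal + 50
carcinoma cases for cross-examination, 100 cases per group for the
interval-signature rates, and a 20+20 cohort for the determinism check —
sizes at which the planted structure dominates sampling noise while a full
tuned fit stays cheap.  Every random element (simulation, splitting, CV
resampling, tree growth) derives from a single user-supplied seed;
repeating any seeded run reproduces OCRI2 values bit for bit.

## Known limitations

* The peaks method operates on density local maxima only; peak prominence,
  width and mass are deliberately discarded (they are not part of the
  transformation this package implements).
* DI values are taken as given; no debris exclusion or pre-filtering is
  applied before density estimation.
* One `case_id` is one DI sample set; replicate slides per patient, if
  present, must be merged or disambiguated upstream.
* Follow-up analysis is restricted to the 2×2/2×3 contingency comparisons
  and descriptive proportions; no time-to-event modelling.
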