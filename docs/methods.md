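# Methods

## The model

`randomknn` implements a random-subspace ensemble of k-nearest-neighbour
classifiers (Random KNN) and a feature-selection procedure built on it
(RKNN-FS), aimed at the "small *n*, large *p*" regime typical of gene
expression: tens to hundreds of samples, thousands of features, and a small
unknown subset of class-informative features buried in noise.

**Random KNN.** From the *p* features, *r* subspaces of size *m* are drawn
independently, each uniformly without replacement. Each subspace carries one
base KNN classifier: a query point is assigned the majority label of its *k*
nearest training points under Euclidean distance restricted to the
subspace's columns. The ensemble prediction is the majority over the *r*
base votes — a majority of a majority. KNN is a stable learner, so the
ensemble draws no bootstrap samples; all diversity comes from the feature
subspaces. For prediction every base classifier uses the full training set
as its neighbour pool.

**Feature support (bidirectional voting).** To rank features, the samples
are split in half into a *base* subset (neighbour pool) and a *query*
subset; each of the *r* base classifiers classifies the query half against
the base half and records its accuracy `acc` on it. Features vote for class
labels through the classifiers that contain them, and each classifier's
accuracy votes back for its features: the *support* of feature *f* is the
mean `acc` over the classifiers whose subspace contains *f*, and its
multiplicity *M(f)* is how many do. Two bookkeeping identities hold exactly
and are asserted throughout the test suite:

    sum_f M(f) * support(f) = m * sum_c acc(c)        sum_f M(f) = r * m

With the *dynamic* partition (default) the half-split is redrawn for every
base classifier; with the *fixed* partition it is drawn once per run and
shared. Dynamic partitioning adds diversity and is the default.

**Two-stage backward elimination (RKNN-FS).** Keeping the top-ranked
features after a single support run ("direct selection") is aggressive;
instead the ranking is applied recursively. Stage 1 (geometric): iteration 1
computes supports on all *p* features; each subsequent iteration keeps the
top `ceil(p_prev * (1-q))` features and recomputes, for
`ni = floor(ln(min_dim/p) / ln(1-q))` iterations, never dropping below
`min_dim` features. The quality of a feature *set* is the mean accuracy of
its *r* base classifiers; the iteration *before* the accuracy peak
("pre-max", the conservative choice with the larger set) seeds stage 2.
Stage 2 (linear): starting from the pre-max set, drop the *d* lowest-ranked
features per iteration for `floor((p_start - min_dim)/d)` steps and return
the set with the best mean accuracy, together with a Random KNN model fitted
on it.

**External LOOCV.** When selection is part of the pipeline, leave-one-out
cross-validation must be *external*: for each held-out sample the entire
RKNN-FS procedure is rerun on the other n−1 samples and only the resulting
final model sees the held-out point. Selecting once on all n samples and
cross-validating the classifier alone would leak the held-out label into the
selection. Stability is summarised by the SD and coefficient of variation
(×100) of accuracy across repeated runs and by the mean/SD of the selected-
set size across folds and runs.

## Parameters

| name | default | meaning and rationale |
|---|---|---|
| `k` | 3 | neighbours per base KNN; small values (1 or 3) suit small-n data because similarity is local |
| `r` | 2000 | base classifiers; accuracy saturates beyond ~1000, 2000 is the benchmarking default |
| `m` | `round(sqrt(p))` | subspace size; the square-root rule maximises dissimilarity between subspaces. Re-derived from the current p each elimination iteration; an explicit m is capped at the current p |
| `q` | 0.2 | proportion of features dropped per geometric iteration |
| `d` | 1 | features dropped per linear iteration |
| `partition_mode` | dynamic | half-split redrawn per classifier (vs fixed once per run) |
| `min_dim` | 4 | floor on the retained feature count |
| `zscore` | off | per-feature standardisation; KNN distance is scale-sensitive, so rescaling is an explicit recorded choice, never silent |
| `seed` | 0 | fixes subspaces, partitions and therefore every output bit-for-bit |

## Numerical and design choices

* **Distance and votes.** Euclidean distance (the conventional KNN choice);
  unweighted votes only. Distance ties at the k-th neighbour are broken by
  sample identifier, so the neighbour set is unique and independent of row
  order; vote ties (both within a base KNN and across the ensemble) go to
  the first label in canonical sorted order. These rules exist purely to
  make runs reproducible; no claim of statistical superiority is attached.
* **Support ties** during ranking are broken by higher multiplicity, then
  feature id. A feature never sampled by any subspace has *undefined*
  support and is reported unranked (NA), not imputed as 0 — a 0 would
  falsely mark it maximally irrelevant. With the defaults `r*m >> p ln p`,
  so this is rare and warned about.
* **Rounding in the schedule.** The iteration-count formulas are used with
  floor and retention with ceiling: floor guarantees the count never
  undershoots `min_dim`, ceiling avoids stalls at small p; a loop guard
  stops elimination early if a retention would fall below `min_dim`.
* **Pre-max at the boundary.** If the accuracy peak is the first iteration,
  the pre-max index is clamped to that iteration. Argmax ties take the
  earliest iteration, i.e. the larger (conservative) feature set.
* **Odd n** gives the base half the extra sample (`ceil(n/2)`), so the
  neighbour pool is never the smaller half.
* **Accuracy is measured on the query half only** — no self-classification.
* **Stage-1-only mode.** For fast screening the linear stage can be
  skipped; the selected set is then the best-accuracy iteration of the
  geometric stage (earliest on ties). Used when stage 2's fine-tuning is
  not worth n-fold repetition, e.g. inside large cross-validation studies.
* **Per-fold seeds** in LOOCV are derived from the master seed by a
  splitmix64-style mix, so folds are decorrelated but the whole result is a
  pure function of the master seed. Sample standard deviations (n−1) are
  used in all summaries.
* **Missing values are rejected**, never imputed; imputation is upstream
  preprocessing.

## The synthetic generator

Real benchmark datasets in this regime are external downloads, so the test
bed is synthetic: `n` samples, `p` features, `c` classes; noise features are
i.i.d. standard normal, and each of `n_informative` planted features adds a
class-dependent mean offset, adjacent classes `shift` noise-SDs apart.
Labels follow `class_proportions` (multinomial by default, exact counts on
request) to support unbalanced designs. The generator returns the planted
ids as ground truth, so recovery can be scored.

What it does *not* model: probe/batch effects, heavy tails, correlated
features, platform normalisation artefacts. Passing tests on these data
show the algorithms work under clean Gaussian signal at the stated sizes;
they bound, but do not demonstrate, behaviour on any particular real
platform.

## Problem sizes used in tests and the acceptance script

The package's benchmark condition is n=60, p=500 with 10 planted features
at shift 1.5 and the default parameters (r=2000, k=3, m=√p, q=0.2) — a
deliberately scaled-down analogue of microarray panels (which run to
p≈15,000), chosen so the full two-stage procedure and its 5-seed replication
complete on a single CPU in well under a minute per run. The external-LOOCV
benchmark uses n=40, p=200, r=500 for the same reason: LOOCV multiplies the
whole selection cost by n. Exact-value tests run on a fixed 8×6 integer
dataset whose distances are hand-checkable.

## Known limitations

* Only classification; no regression mode, no distance-weighted voting,
  no non-Euclidean metrics, no approximate neighbour indexes.
* Supports carry no significance measure (no permutation null).
* The geometric/linear schedule is not auto-tuned; q and d are user
  choices.
* Complexity is O(r·k·m·n log n)-ish per support run and the elimination
  multiplies it by the iteration count; p in the tens of thousands works
  but LOOCV at that scale is expensive by construction.
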