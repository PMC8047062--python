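# Methods

## Problem and architecture

Egocentric dietary-assessment studies produce image streams far too large
for exhaustive human review, and only a small share of frames contain
food-related activity. `foodtag` triages such a corpus into Food / Non-food
using only the output of an upstream image annotator: per image, an ordered
list of up to 200 textual tags with likelihood values in [0, 1]. The package
treats the annotator as an external black box (an adapter seam exists at the
JSON Lines file format; no API client is implemented) and contributes the
stages downstream of it:

1. **Vocabulary selection.** Tags are counted by presence (one count per
   image containing the tag, regardless of likelihood). The feature
   vocabulary is the minimal count-descending prefix of the histogram whose
   cumulative count reaches a coverage fraction of all tag occurrences
   (default 0.5). Ties at equal count break lexicographically so the
   selection is deterministic across platforms. Vocabulary size is monotone
   in coverage.

2. **Probabilistic interface.** For each vocabulary tag, `P(Food | T=1)` and
   `P(Food | T=0)` are estimated by count ratios on the (balanced) training
   set, with a symmetric pseudo-count `α`:
   `p_pos = (n_food_with + α) / (n_with + 2α)` and analogously for `p_neg`.
   `α = 0` reproduces pure ratios but is undefined for tags present in none
   or all training images, so the default is `α = 1` (Laplace). "Annotated
   with the tag" means presence in the tag list; no likelihood cutoff is
   applied at the counting stage — likelihoods enter only through the
   feature formula. The food-prediction power of a tag with likelihood `v`
   is the affine map `P = p_pos·v + p_neg·(1−v)`; a vocabulary tag absent
   from an image contributes `v = 0`, hence `p_neg`, since an unreported tag
   carries no positive evidence.

3. **Shallow classifier.** Default: SVC with polynomial kernel, degree 3,
   C = 1, `gamma="scale"`, `coef0 = 1`. Features are in [0, 1] by
   construction and are not standardized by default (a flag exists).
   The LDA comparator uses its continuous discriminant score for ROC
   sweeps. Classifier choice and all hyperparameters sit in
   `ExperimentConfig` / `train_sln`.

4. **Evaluation.** Sensitivity, specificity, burden index
   `B = 100(TP+FP)/N`, and ROC curves via a standard threshold sweep (tied
   scores cross the threshold together; curves include the (0,0) and (1,1)
   endpoints, and the trapezoidal area equals the Mann–Whitney pairwise
   statistic, which the tests verify against a brute-force oracle).
   Undefined metrics (empty denominator) raise instead of returning NaN so
   trial summaries cannot silently absorb them. Reported rounding is
   half-up: probabilities to 2 decimals, burden to 1.

## Experiment protocol

`run_trial` / `FoodTagModel.fit` execute: 75/25 random split (train size
`round(0.75·N)`, half-up) → random downsampling of the training majority
class to the minority count (the test set keeps its natural imbalance) →
vocabulary and conditional estimation on the balanced training set →
featurization of both sets → classifier fit → test-set confusion counts.
`repeat_trials` reruns everything from scratch once per seed, re-splitting
and re-balancing each time, and reports per-metric mean and sample
(n−1) standard deviation; a single trial reports sd = 0.

## Synthetic data

The generator defines the study conditions for all quantitative checks:

* label ~ Bernoulli(prevalence); given the label, each tag is present
  independently with probability `q_food` or `q_nonfood`;
* a present tag's likelihood ~ Beta(9, 1) by default (mean 0.9), mirroring
  an annotator that reports only confident tags; absent tags are simply
  missing and are treated as `v = 0` downstream;
* per-image tag lists are ordered by descending likelihood and capped at
  `max_tags` (default 200), keeping the most confident tags.

Because presence is conditionally independent across tags,
`analytic_conditionals` gives the exact population values
`p_pos = πq_F/(πq_F+(1−π)q_N)` (and the complementary form for `p_neg`),
used as the estimator's oracle.

Presets, with the conditions they pin:

* `realistic_config` — ~300 tags with power-law base presence (so 50%
  coverage keeps a head of a few dozen tags), Food prevalence 0.14
  (eating events are a small share of daily frames), ~15% food-leaning and
  ~15% non-food-leaning tags, and a strongly food-leaning explicit
  `"food"` tag so the annotator-only threshold baseline is exercised.
* `informative_config` — several diagnostic tags (`q_food ≥ 0.8`,
  `q_nonfood ≤ 0.2`) at prevalence 0.5; the pipeline should be nearly
  perfect here.
* `uninformative_config` — all tags identical across classes; the chance
  control.
* `recovery_config` — eight tags spanning the diagnostic spectrum with
  complementary presence (`q_F + q_N = 1`) at prevalence 0.5, so each tag is
  present in about half of the corpus and both conditionals are estimated
  from comparable sample sizes; used for the n = 10,000 recovery benchmark
  with tolerance 0.02.

What passing on synthetic data does **not** show: robustness to tag
co-occurrence structure, annotator miscalibration, domain shift between the
annotator's training imagery and field imagery, or any pixel-level effect —
none of which the generator emulates.

## Numerical choices and degenerate inputs

* SVC fits are capped at `max_iter = 200,000`. libsvm's SMO optimizer can
  cycle essentially forever on degenerate, near-constant feature matrices
  (exactly what the uninformative corpus produces); converged fits are
  unaffected by the cap.
* The default operating point of a margin classifier fitted to pure noise
  is arbitrary, so chance-level behavior is asserted on the threshold-free
  ROC area, not on the burden index.
* Split sizes and reported metrics round half-up; banker's rounding would
  make the 75% split size platform-convention-dependent at ties.
* Balancing downsamples whichever class is the majority; requesting balance
  with a class absent raises.
* `α = 0` conditional estimation raises a `ZeroDivisionError` naming the
  degenerate tag and suggesting a positive `α`.
* Annotation validation rejects likelihoods outside [0, 1], duplicate tags
  within an image, duplicate image ids, labels other than 0/1, and tag
  lists beyond the cap; parse errors name the offending line.

## Problem sizes

The test suite and the acceptance script run corpora of 1,000–10,000 images
with vocabularies of tens of tags: large enough that Monte-Carlo tolerances
(0.02 on recovered conditionals at n = 10,000; ±0.05 on chance-level ROC
area) hold with wide margin, and small enough that the whole suite runs in
well under a minute on one CPU.

## Known limitations

* Tags are modelled and featurized independently; no joint tag statistics.
* No probability calibration of SVM scores; the burden index at the default
  operating point depends on the balanced-training convention.
* The evidence-count baseline needs a curated food-related tag list; a
  default editable list ships with the package, and on synthetic corpora
  the food-leaning generator tags play that role.
* The 200-tag cap is enforced at validation and generation; whether an
  upstream annotator applies its own cap is outside the package's control.
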