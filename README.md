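# foodtag

Food/non-food triage of egocentric (wearable-camera) images, driven not by
pixels but by the textual **tags** an upstream annotation network assigns to
each image.

Wearable cameras used in dietary assessment capture tens of thousands of
images per day, of which only a small fraction show food-related activity.
`foodtag` implements a composite classification approach for flagging those
images so that human reviewers only need to inspect a fraction of the
corpus: a black-box deep annotator supplies, for every image, a list of tags
with likelihood values; a probabilistic interface layer turns the tags into
conditional-probability features; and a shallow classifier (polynomial-kernel
SVM, or LDA as a comparator) makes the final Food / Non-food call.

## The model

For image tags `Tag 1 … Tag M`, the annotator reports likelihoods
`v_i = P(T_i = 1)` — its confidence that tag *i* correctly describes the
image. From a labeled training corpus the interface estimates, for each tag,

* `P(Food | T_i = 1)` — the fraction of tag-*i*-annotated images labeled Food,
* `P(Food | T_i = 0)` — the same among images lacking the tag,

optionally with a symmetric pseudo-count `α` (α = 0 gives the pure count
ratios). By total probability, the **food-prediction power** of tag *i* is

```
P_i = P(Food | T_i = 1) · v_i + P(Food | T_i = 0) · (1 − v_i)
```

the probability the image contains food considering tag *i* alone. The
feature vector `(P_1, …, P_M)` — over the vocabulary of most frequent tags
covering 50% of all tag occurrences in the training corpus — is fed to the
shallow learner.

Evaluation reports sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`, ROC
curves, and the **burden index**

```
B = 100 · (TP + FP) / (TP + TN + FP + FN)  [%]
```

the percentage of images a human must still review (B = 0% is fully
automatic, B = 100% fully manual). The experiment harness follows the field
protocol: 75/25 random split, majority-class downsampling of the training
set only, and five retrain-from-scratch trials reported as mean ± sd.

Because raw field imagery and the proprietary annotator are unavailable, a
first-class synthetic generator emulates the annotator: labels are
Bernoulli(prevalence), tags appear independently with class-conditional
presence probabilities, and present tags draw Beta-distributed likelihoods.
Its conditionals are analytically known, giving exact oracles for every
stage.

## Worked example

```python
import foodtag as ft
from foodtag import synthetic as syn

data = syn.generate(syn.realistic_config(n_images=10000, seed=1))
res = ft.FoodTagModel(data).fit(seed=1)
print(res.summary())
```

```
Food/Non-food tag classification results
==============================================
classifier:       svm_poly
images:           10000 (1423 food / 8577 non-food)
train fraction:   0.75 (balanced: 2136 images)
vocabulary:       46 tags at 50% coverage
smoothing alpha:  1.0
seed:             1
----------------------------------------------
test confusion:   TP=350  FN=5  TN=2124  FP=21
sensitivity:      0.99
specificity:      0.99
burden index:     14.8%
ROC area:         0.999
==============================================
```

Reading the output: of the 2,500 held-out images, the classifier flags
371 (TP + FP) as food-related — a burden index of 14.8%, so a reviewer
inspects roughly one image in seven instead of all of them — while missing
only 5 of the 355 true food images (sensitivity 0.99). The 46-tag
vocabulary is the head of the power-law tag-frequency histogram that covers
half of all tag occurrences in the balanced 2,136-image training set.

The same pipeline is available from the shell:

```sh
foodtag simulate --preset realistic --n-images 10000 --seed 1 --out corpus.jsonl
foodtag evaluate corpus.jsonl --seed 1
foodtag trials corpus.jsonl --n 5 --seed 1
foodtag baseline corpus.jsonl --mode tag-threshold --threshold 0.7
```

Annotation files are JSON Lines, one image per line:
`{"image_id": "...", "label": 1, "tags": [{"tag": "food", "likelihood": 0.942}, ...]}`.

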