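# Methods

`slrscreen` implements a machine-assisted abstract-screening procedure for
systematic literature reviews (SLRs). Its goal is not a bare
include/exclude verdict but the form of output that health-technology
assessment practice requires: every automatic exclusion carries a PICOS
reason (population, intervention, comparator, outcomes, study design, plus
"other" and "time"), and anything the machine cannot justify is handed back
to a human reviewer.

## The screening cascade

Training data come from a previously screened review: each citation has an
abstract-level decision (with a reason for every exclude) and, for abstract
includes, a full-text decision (with a reason for full-text excludes).
Three labelling schemes turn this into training labels:

* **abstract** — labels follow the abstract-stage decision;
* **full_text** — abstract includes are relabelled by their full-text
  outcome (the more informative decision when available);
* **modified_full_text** — abstract-stage labels after removing citations
  included at abstract level but excluded at full text. These
  "over-inclusions" were decided on information outside the abstract, so
  keeping them as excludes teaches the model to distrust abstracts that
  look exactly like includes.

Whatever the training scheme, evaluation truth is always full-text
inclusion.

The fitted model is a two-stage cascade sharing one bag-of-words
vocabulary:

1. an **overall** include/exclude classifier; and
2. one **pairwise** include-vs-reason classifier per exclusion reason
   present in training, each fit on the subset of all includes plus the
   excludes for that single reason.

At screening time the overall exclusion probability gates everything: below
the decision threshold (default 0.90) the citation passes through as an
include. At or above it, the pairwise models are consulted; the citation is
auto-excluded only if at least one reason model also reaches the threshold,
and the reported reason is the highest-priority qualifying reason under the
fixed hierarchy (study design > population > intervention > comparator >
outcomes > other > time). If no reason qualifies the citation is left
`unclassified` for the human. The threshold comparison is inclusive (≥) so
that boundary behavior is reproducible. The helper `select_threshold`
implements the standard closest-to-top-left-corner ROC criterion used to
justify the 0.90 default.

The evaluation definitions follow from the workflow in which a human
screens everything the machine did not exclude: a true include left
unclassified is a true positive (no harm done), and a true exclude left
unclassified is a false positive (no work saved). Sensitivity
TP/(TP+FN) is therefore the share of true includes *not* thrown away, and
specificity TN/(TN+FP) the share of true excludes cleared automatically.
Ratios with empty denominators are reported as undefined (`None`), never
silently zeroed.

Two reason-quality metrics accompany them: the share of stage-1 exclusions
that received a reason, and — among auto-excluded true excludes — the share
whose *reviewer* reason cleared the threshold. A stricter variant
(reported reason exactly equals the reviewer reason) is also emitted, since
the hierarchy can report a different qualifying reason than the reviewer
chose.

## Features

Tokenization lowercases, splits on anything outside `[a-z0-9]`, drops a
pinned English stopword list (shipped as package data so results do not
depend on an external resource), and removes pure-number tokens; tokens
mixing digits and letters (e.g. `her2`) survive. No stemming or
lemmatization is applied, and terms are raw counts, not tf-idf — the
simplest representation consistent with a bag-of-words count model.

Vocabulary thinning is one of:

* **minimum corpus frequency** — drop terms occurring fewer than 5, 10,
  100 or 500 times across all citations; or
* **top-k variable importance** — keep the 50, 100 or 500 terms ranked by
  an algorithm-specific score: mean decrease in impurity over the bags for
  bagged CART, and the absolute gap between smoothed class-conditional log
  term probabilities for naive Bayes. The linear SVM has no native
  importance criterion, so importance mode is rejected for it. Ties break
  lexicographically for determinism.

Finally, zero-variance predictors are removed relative to the set being
screened: terms constant across all training rows, or present exclusively
in the training or the screening set, are dropped from both.

## Classifiers

* **svm** — linear-kernel SVM (standard for high-dimensional sparse text;
  with a linear kernel the cost C is the only tuning parameter, grid
  {0.25, 1, 2, 8, 32, 256}). Probabilities come from a Platt-style sigmoid
  calibrated within the training data. During cross-validated tuning on
  the ROC metric the raw decision values are used for fold AUC — the AUC is
  invariant to the monotone Platt map, so this is mathematically identical
  and cheaper.
* **naive_bayes** — authored here, modelled on the klaR variant the field
  uses: per-term class-conditional densities over counts, either Gaussian
  ("no kernel", standard deviation floored at 1e-3) or a Silverman-bandwidth
  Gaussian KDE ("kernel"); grid = {kernel, no kernel} × Laplace weight
  {0, 0.5, 1}. The Laplace weight smooths every per-term likelihood as
  f̃(x) = (n_c·f(x) + λ)/(n_c + λ) with n_c the class size — it reduces to
  the raw density at λ=0 and, because the model is multiplicative across
  terms, keeps any single rare feature from zeroing a posterior.
* **bagged_cart** — 25 bootstrap bags of unpruned CART trees; the
  exclusion probability is the fraction of bags voting exclude. Nothing is
  tuned, so no tuning metric applies; the single grid point is still
  cross-validated (fold AUC) so the recorded CV score is meaningful.

Tuning is stratified k-fold cross-validation (default ten folds, fold
assignment re-randomized per component model from its seed) over the
declared grid, scored by mean fold ROC AUC or mean fold sensitivity of the
include class at the 0.5 posterior cut. The 0.90 screening threshold plays
no role during tuning. Ties keep the earlier grid point in declared order.

**Downsampling.** With typical inclusion rates of a few percent the
excludes swamp the includes, and classifiers trained on such data overfit
the majority class. When enabled, each component model's training rows are
balanced 1:1 by seeded random removal from the majority class (in the
overall model that is always the excludes, so every include is retained;
inside a pairwise subset the includes can be the majority, and the same
majority-to-minority rule applies).

If a pairwise reason model cannot be fit (a reason with fewer training
examples than CV folds), it is skipped with a warning rather than failing
the whole model; affected citations can still be auto-excluded under the
remaining reasons or deferred. A model with no fittable reason model at all
is flagged `degenerate` and can only emit include/unclassified.

## The simulation harness

`enumerate_scenarios` crosses datasets × 3 schemes × downsampling on/off ×
7 feature settings × 3 algorithms × tuning metrics, removing the two
structurally invalid pairings (SVM with importance mode; bagged CART with a
metric). With five datasets this is 870 cells (420 naive Bayes, 240 SVM,
210 bagged CART). `run_scenarios` executes each cell end to end
(deduplicate, derive labels, 75/25 stratified split, feature pipeline, fit
cascade, screen the test set, score), with per-cell seeds derived
deterministically from a master seed and per-cell failures recorded rather
than aborting the batch. `paired_factor_test` compares two levels of one
factor with a two-sided paired t-test over cells matched on every other
factor; cells without a partner are dropped and counted. Zero-variance
difference vectors are flagged (degenerate if their mean is nonzero)
instead of dividing by zero. Factor averages use the simple mean over
matched cells.

The 75/25 stratified split (round-half-up per stratum, seeded permutation)
mimics updating an existing review with a fresh search; it is configurable
and not a claim about practice.

## Synthetic corpora

Real screening datasets of this kind are proprietary, so the generator
emulates their shape. Five reference profiles pin corpus size, abstract
inclusion rate and full-text retention to the published summaries of five
large reviews (psoriasis 4442/13.8%/27.9%, lung cancer 12,769/1.7%/30.7%,
liver cancer 8507/13.4%/25.8%, melanoma 3089/4.0%/33.1%, obesity
5187/4.4%/20.6%; 33,994 abstracts in total).

Class counts are deterministic (round-half-up of the configured rates) so
generator tests can assert them exactly; class membership is randomized.
Abstract text is a bag of tokens drawn from a mixture: a 500-term shared
background vocabulary with Zipf-like weights (mass 1 − s) plus a 30-term
class signature (mass s), where s = `signature_strength` (default 0.35).
Each exclusion reason and the include class have their own signature.
Over-included citations (abstract include, full-text exclude) draw their
signature from a 50/50 blend of the include signature and their reason's
signature — this is what makes the modified-full-text scheme matter.
Abstract lengths are Poisson with mean 120 tokens, floored at 10. The
per-reason exclusion frequencies are not published for the reference
reviews; the default distribution (study design .25, population .25,
intervention .15, outcomes .15, other .10, comparator .05, time .05) is a
synthetic assumption weighted toward the reasons that dominate in practice.

What the generator does **not** emulate: natural language (grammar,
collocations, section structure), inter-document topic correlation,
reviewer disagreement or label noise, and duplicated records. Passing
benchmarks on these corpora therefore demonstrates that the machinery
recovers a planted class-conditional vocabulary signal at realistic sizes
and imbalance — not that any particular accuracy will be achieved on a real
review.

## Benchmark conditions and problem sizes

Two synthetic benchmarks back the acceptance script and the end-to-end
tests, with sizes chosen to keep a full run at desk scale:

* **Parameter recovery** — the reference configuration (SVM, ROC metric,
  downsampling, minimum frequency 5, full-text labels) on five
  psoriasis-profile corpora of 2000 citations at default signal strength;
  held-out (25%) sensitivity is expected ≥ 0.95 per seed. At
  `signature_strength = 0` the same pipeline's auto-exclusions must be
  statistically unrelated to truth (Fisher exact test) — the no-signal
  calibration.
* **Downsampling contrast** — 12 matched scenario pairs (two 700-citation
  corpora × 3 schemes × {SVM, bagged CART}) differing only in
  downsampling. This experiment uses a deliberately weak signal
  (`signature_strength = 0.10`): at the default strength the task
  saturates and both arms tie at sensitivity 1.0, which still satisfies
  the directional claim but shows nothing. Class imbalance harms
  sensitivity precisely when the signal is weak, so the weak-signal
  condition is where the contrast is informative. The asserted property is
  directional only: mean paired sensitivity gain ≥ 0.

## Known limitations

* The SVM's Platt calibration on near-separable training data pushes
  probabilities toward 0/1, which interacts with the fixed 0.90 threshold;
  on real (noisier) data the threshold trade-off will differ.
* The kernel-density naive Bayes loops over terms at prediction time and is
  the slowest component; it is intended for the moderate vocabularies that
  frequency filtering produces.
* Pairwise reason models see only includes and one reason's excludes, so
  their probabilities are not calibrated against the other reasons; the
  hierarchy, not probability magnitude, arbitrates among qualifying
  reasons.
* `deduplicate` uses a normalized title+abstract key; records that differ
  by truncation or OCR noise are not merged.
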