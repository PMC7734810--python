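# slrscreen

Machine-assisted abstract screening for systematic literature reviews
(SLRs), built for evidence-synthesis teams that must document a PICOS
reason for every exclusion. Given a previously screened review as training
data, `slrscreen` classifies each new citation as an **include**, an
**exclude with a reason** (study design, population, intervention,
comparator, outcomes, other, or time), or **unclassified** — deferred to a
human reviewer. One human screens everything the machine does not exclude;
the machine only removes citations it can justify.

## The method

Abstracts are represented as bag-of-words count vectors (lowercased,
stopword/number/punctuation-free, optionally thinned by corpus frequency or
variable importance, with zero-variance predictors removed). A two-stage
cascade is fit on these features:

1. an **overall** include/exclude classifier, and
2. a **pairwise** include-vs-reason classifier for each exclusion reason
   present in training.

A citation is auto-excluded only when the overall exclusion probability
*and* at least one reason model reach the decision threshold (default
0.90); the reported reason is the highest-priority qualifying reason under
the fixed hierarchy study design > population > intervention > comparator >
outcomes > other > time. Three classifiers are supported — linear SVM
(cost grid {0.25, 1, 2, 8, 32, 256}), naive Bayes (Gaussian or
kernel-density likelihoods × Laplace correction {0, 0.5, 1}), and 25-bag
bagged CART — each tuned by stratified 10-fold cross-validation on ROC AUC
or include-class sensitivity. Training classes can be balanced 1:1 by
downsampling the excludes.

With TP = true include not auto-excluded, FN = true include auto-excluded,
TN = true exclude auto-excluded, FP = true exclude left to the human
(truth = full-text decision), the screening metrics are

    sensitivity = TP/(TP+FN)   specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)   accuracy    = (TP+TN)/(TP+FN+TN+FP)

A factorial harness (`evalsim`) runs the full grid of design choices —
datasets × 3 labelling schemes × downsampling × 7 feature settings × 3
algorithms × 2 tuning metrics, 174 valid cells per dataset — and compares
factor levels with paired t-tests. A generator (`synthcorpus`) produces
labelled corpora with the size, imbalance, and reason structure of five
large published reviews, so everything is testable without proprietary
data. See `docs/methods.md` for the full model description.

## Worked example

Screening an "update" of a psoriasis-profile review (2000 synthetic
citations, 13.8% abstract-inclusion rate; 75% used as the previous review,
25% as the update to screen):

```bash
slrscreen synth --spec psoriasis --n 2000 --seed 7 --out corpus.csv
# ... split corpus.csv 75/25 into previous_review.csv / update.csv ...
slrscreen train --input previous_review.csv --scheme full_text \
    --algorithm svm --metric roc --downsample --min-freq 5 --seed 7 \
    --out model.bin
slrscreen screen --model model.bin --input update.csv --out decisions.csv
slrscreen evaluate --decisions decisions.csv --truth update.csv
```

which prints:

```
trained svm on 1500 citations (58 includes); reason models: study_design,
  population, intervention, comparator, outcomes, other, time; saved to model.bin
screened 500 citations: 438 auto-excluded with a reason, 1 unclassified
  (for human review), 61 passed as includes -> decisions.csv
TP=19 FN=0 TN=438 FP=43
sensitivity        100.0%
specificity        91.1%
precision          30.6%
accuracy           91.4%
excluded w/ reason 99.8%
correct reason     100.0% (strict match 99.3%)
```

Reading: none of the 19 true includes was thrown away (sensitivity 100%),
the machine cleared 438 of the 481 true excludes with a reason
(specificity 91.1%), and the reviewer would screen only the remaining 62
citations. The same pipeline is available as library calls
(`generate_corpus`, `derive_labels`, `stratified_split`,
`fit_screening_model`, `screen`, `confusion_counts`,
`performance_metrics`).

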