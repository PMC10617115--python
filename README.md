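# rbfs — reweighting boosting feature selection for lncRNA–protein interaction prediction

Long non-coding RNAs (lncRNAs) regulate gene expression largely through
physical interactions with proteins, and predicting which lncRNA–protein
pairs interact (LPI prediction) from sequence alone is a standard binary
classification task: each candidate pair is represented by a
high-dimensional feature vector (here, the concatenated k-mer compositions
of the two sequences), most of whose dimensions are irrelevant or
redundant. `rbfs` implements **reweighting boosting feature selection
(RBFS)**, a wrapper method that finds a small, non-redundant feature subset
while a boosting-style sample reweighting keeps the search focused on the
pairs the current model finds hardest.

## The method

Let X ∈ ℝ^{n×p} be the pair-feature matrix, y ∈ {0,1}^n the interaction
labels, and ω ∈ Δ^{n−1} a sample-weight vector initialized to ω_j = 1/n.
Each iteration *i*:

1. **Rank.** An XGBoost ensemble is fitted on (X, y) with weights ω and
   every feature is scored by total split gain; the top *q* not-yet-selected
   features form the candidate window.
2. **Scan.** Each candidate f is scored by the mean stratified k-fold CV
   accuracy (k = 5) of the classifier on S ∪ {f}, where S is the current
   selected set; all candidates in one iteration share identical folds.
3. **Accept.** The best candidate joins S iff it *strictly* improves the
   incumbent accuracy.
4. **Reweight.** The classifier is refit on S (weighted); with per-sample
   cross-entropy ∂_j = −log P̂(y_j), the weights update multiplicatively,

       ω_j ← ω_j · ∂_j^{(i)} / ∂_j^{(i−1)},   then  ω ← ω / Σ_j ω_j ,

   so a pair whose true-class probability moved toward 1 loses weight and a
   persistently misclassified pair gains it (on the first update the
   previous scores are taken as 1).
5. **Terminate.** The first time no candidate is acceptable — no strict
   improvement, or every rankable feature is already in S — the weights are
   reset to 1/n and the search continues; the second such trigger stops the
   algorithm and S (of size m ≪ p) is final.

The selected subset is evaluated by stratified 5-fold cross-validation
(precision, recall, accuracy, F1, AUROC, AUPR), and a noise harness
re-runs the whole procedure on copies of the dataset perturbed by one
appended random sample and one appended random feature, reporting the
spread of AUROC/AUPR across groups as a stability measure.

## Worked example

`examples/feature_selection.py` plants 3 informative columns among 80
(logistic model, effect size 2.0 per column) in a 200-pair dataset and runs
the full loop:

```
dataset: 200 x 80, planted columns [1, 70, 77], Bayes AUROC 0.9346
selected 5 features: [1, 77, 70, 28, 76]
planted features recovered: 3/3
  iter  1 phase 1  acc 0.6450  accepted feature 1
  iter  2 phase 1  acc 0.7550  accepted feature 77
  iter  3 phase 1  acc 0.8300  accepted feature 70
  iter  4 phase 1  acc 0.8300  trigger: no_improvement -> weight reset
  iter  5 phase 2  acc 0.8350  accepted feature 28
  iter  6 phase 2  acc 0.8500  accepted feature 76
  iter  7 phase 2  acc 0.8500  trigger: no_improvement -> stop
5-fold CV on selected set: AUROC 0.9026, AUPR 0.8992, accuracy 0.8050
```

All three planted columns are accepted first and the incumbent CV accuracy
increases strictly at every acceptance; the final 5-feature model reaches
an AUROC within a few points of the generator's Bayes ceiling (0.9346), the
best any classifier could do on these features. The other examples cover
featurization (`feature_extraction.py`), the weight dynamics
(`reweighting_demo.py`), the noise harness (`noise_stability.py`) and the
end-to-end pipeline with its run artifacts (`full_pipeline.py`).

## Command line

A thin CLI wraps the library: `rbfs extract` (FASTA + pair list → feature
table), `rbfs select`, `rbfs evaluate`, `rbfs noise`, `rbfs simulate`, and
`rbfs run` (full pipeline from a `key: value` config file). See
`rbfs --help`.

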