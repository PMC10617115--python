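# Methods

## Problem setting

Sequence-based lncRNA–protein interaction (LPI) prediction is treated as
binary classification over pairs. A pair (l, r) is represented by the
concatenation of the two partners' k-mer composition vectors; the label is
1 when the interaction is known and 0 for a sampled non-interacting pair.
The scientific question the package addresses is not the classifier itself
but the selection of a small feature subset that preserves (or improves)
classification performance — the feature space is large and highly
redundant, and wrapper selection with an adaptive sample weighting is the
method implemented here.

## Featurization

k-mer composition is the vector of overlapping length-k substring counts
over the canonical alphabet, normalized by the number of counted windows,
in lexicographic order. Defaults: k ∈ {1,2,3,4} for nucleotide sequences
(4+16+64+256 = 340 features) and k ∈ {1,2} for amino acids (20+400 = 420),
so a pair has 760 features. These defaults are a deliberate, reproducible
stand-in for descriptor-suite features; they are configurable upward when a
higher-dimensional representation is wanted.

Handling of non-canonical symbols: sequences are uppercased; `U` is read as
`T`; ambiguity codes (`N`, IUPAC nucleotide codes, `X/B/Z/J/U/O` for
proteins, gaps) are accepted in input but excluded from counting — only
windows made entirely of canonical symbols count, and the denominator is
the number of such valid windows. This keeps the feature space fixed
instead of exploding the alphabet, at the cost of slightly re-weighting
compositions of ambiguity-rich sequences.

Negative pairs are drawn uniformly without replacement from the zero
entries of the interaction matrix, with a mandatory seed; the ratio of
negatives to positives is a parameter (default 1:1, typical published LPI
benchmarks range from 1:1 to about 1:2). Uniform sampling assumes
unobserved pairs are true negatives, which is optimistic for sparse
interaction maps — a known limitation of the construction, shared with the
benchmarks it emulates.

## Sample reweighting

Weights ω form a probability vector, initialized uniform. After each
accepted feature the classifier is refit on the selected columns and each
sample j is scored by its cross-entropy ∂_j = −ln P̂(true class of j); the
update is the successive-iteration ratio

ω_j ← ω_j · ∂_j^{(i)}/∂_j^{(i−1)}, followed by normalization.

Numerical choices:

* probabilities are clipped to [1e-12, 1] before the log, so ∂ is finite;
* previous-iteration scores below 1e-12 (perfectly classified last round)
  are floored at 1e-12 before division;
* on the first update after (re)initialization the previous scores are
  taken as 1, i.e. uniform weights are multiplied by the raw cross-entropy
  — this gives hard samples extra weight from the very first round;
* natural log; since the update is followed by normalization, only
  relative ratios matter and the log base is immaterial;
* if every updated weight is zero (all samples perfectly classified) the
  update falls back to uniform weights and logs a warning.

## The selection loop

Per iteration: rank all p features by total-gain importance of an XGBoost
fit under the current weights (ties by ascending feature index; features
never used by a tree score exactly 0); scan the top q ranked features not
yet selected; score each candidate by unweighted stratified k-fold CV
accuracy of the ensemble on S ∪ {candidate}; accept the best candidate only
on strict improvement of the incumbent accuracy (tolerance 0 — any
accuracy-equal candidate triggers termination). Features are re-ranked
after every acceptance, since the weight update is meant to steer the
search; ranking once and consuming the list would make the reweighting
inert.

Sample weights are used where the model is *fit* (ranking, and the
post-acceptance refit that produces the probabilities for the weight
update) but not inside candidate CV, where accuracy is defined on raw
samples. Whether weighted CV would be preferable is genuinely open; the
unweighted choice keeps candidate scores comparable across iterations.

Termination is two-phase. A trigger fires when no candidate is acceptable:
either the best candidate fails to improve the incumbent, or the candidate
window is empty because every rankable feature is already selected (the
"feature would be selected twice" situation — since the window excludes
already-selected features, a repeat selection manifests as exhaustion).
The first trigger resets ω to 1/n and continues from the current S — the
reset gives every sample an equal say once more, letting the search escape
a weighting that has become too concentrated; the second trigger stops.
A `max_iterations` safety net (default 100) bounds the loop regardless;
each phase can accept at most p distinct features and each acceptance
strictly increases a quantity bounded by 1, so the loop halts.

Candidate windows within one iteration share identical CV folds (fold seed
derived from the run seed and iteration index), so candidate accuracies are
directly comparable; every stage seed is derived from the single run seed
via `numpy.random.SeedSequence` spawn keys, making any stage independently
re-runnable.

Defaults: q = 10 (large enough to escape one bad ranking head, small
enough for desk-scale CV scans), k = 5 stratified folds, ensemble of 200
trees, depth 6, learning rate 0.1. The simulation studies in the test
suite and the acceptance script use a lighter ensemble (60 trees, depth 3,
rate 0.1, `EnsembleConfig.light()`): at the study's problem size (500×200,
twenty runs plus a five-group noise experiment, each group re-running the
whole selection) the light ensemble keeps a full study in minutes on one
CPU while leaving the loop's behaviour — recovery, monotonicity,
stability — unchanged in kind.

## Evaluation

Precision TP/(TP+FP), recall TP/(TP+FN), accuracy (TP+TN)/n, F1 the
harmonic mean of precision and recall, with class 1 = interaction. Ratios
with zero denominator are reported as 0 and flagged `undefined` rather than
NaN. AUROC is the ROC area (equal to the pairwise concordance probability
with ties half-credited); AUPR is average precision, the conservative
step-wise estimator without linear interpolation. Label predictions
threshold the positive-class probability at 0.5. Cross-validation is
stratified k-fold, fold assignment derived from the run seed; reports carry
per-fold values and mean ± sd.

Note that average precision is *not* bounded below by the positive
prevalence on a per-dataset basis (ranking every positive last gives
AP = (1/P) Σᵢ i/(N+i) < P/n); the property suite asserts the correct
worst-ordering bound.

## Noise-robustness harness

Each group appends one noise sample (features drawn per column, uniform
within the column's observed range by default, or Gaussian matched to its
mean/sd; label uniform on {0,1}) and one noise feature (independent draws
per sample), then re-runs the *entire* selection and cross-validation on
the perturbed copy — the experiment probes the stability of the selection
procedure, not just of a fixed model. The report is a G-row AUROC/AUPR
table plus the per-metric spread (max − min). Appending is the default
reading of "adding noise to the last row and column"; an overwrite mode is
available behind a flag. The perturbation is a pure function of
(seed, group index).

## Synthetic data

Real LPI benchmarks are curated from interaction databases and are not
redistributed here; two seeded generators stand in.

**Feature-level.** X has p standard-normal columns; a random subset of
n_informative columns drives labels through a logistic model with equal
log-odds coefficients (effect_size each); the intercept is calibrated to
the target prevalence by bisection on E[σ(b0 + σ_z Z)] (tolerance 0.01).
Optionally the informative columns are observed with additive Gaussian
noise (noise_sd; default 0 — labels depend directly on the observed
columns). The generator reports its own Bayes AUROC: the optimal observed
score is monotone in the informative-column sum, and
P(s_pos > s_neg) is computed by Gauss–Hermite quadrature of
η(s) = E[σ(t)|s] inside a trapezoid integral of the class-conditional
densities (the quadrature agrees with large-sample Monte Carlo to ~3·10⁻⁴).
Defaults — 500 samples, 200 features, 5 informative, effect size 2.0,
prevalence 0.5 — define the simulation study used throughout the tests.

**Sequence-level.** Uniform-random sequences with a nucleotide motif
planted in a fraction of lncRNAs and an amino-acid motif in a fraction of
proteins; a pair interacts with probability p_co when both partners carry
their motif and p_background otherwise. Written as FASTA + pair list so
the whole featurization path is exercised; the ground truth lists the
motif's constituent k-mers, which are exactly the features the planted
signal enriches.

What the generators do *not* emulate: real nucleotide/amino-acid
composition biases, phylogenetic and family structure among sequences,
hub lncRNAs/proteins that interact promiscuously (and the attendant
information-leakage concerns in pair-level CV), and label noise in curated
interactions. Passing the simulation studies therefore demonstrates the
algorithm's correctness and its behaviour under its own assumptions —
planted-signal recovery, dimensionality reduction, stability — not
performance on any real benchmark.

## Known limitations

* Greedy forward selection with a strict-improvement rule can stop early
  on plateaus; the weight reset gives one second chance by design, not an
  exhaustive search.
* Pair-level CV folds ignore shared lncRNAs/proteins across pairs;
  entity-disjoint splitting is out of scope here.
* The negative-sampling assumption (unobserved = non-interacting) inflates
  apparent performance on sparse interaction maps.
* With very unbalanced or tiny datasets a stratified fold can lose a
  class; the evaluator raises rather than silently degrading.
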