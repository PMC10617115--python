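"""Planted-feature recovery with the full selection loop.

Generates a feature-level synthetic dataset (200 pairs x 80 features, 3
informative columns driving the labels through a logistic model), runs the
two-phase selection loop, and compares the selected set with the planted
ground truth and the generator's Bayes AUROC ceiling.
"""

from rbfs import (
    EnsembleConfig,
    SelectionConfig,
    SyntheticSpec,
    crossvalidate,
    generate_feature_dataset,
    make_classifier,
    select_features,
)

spec = SyntheticSpec(n_samples=200, n_features=80, n_informative=3,
                     effect_size=2.0, seed=42)
data, truth = generate_feature_dataset(spec)
print(f"dataset: {data.n_samples} x {data.n_features}, "
      f"planted columns {truth.informative_indices}, "
      f"Bayes AUROC {truth.bayes_auroc:.4f}")

ensemble = EnsembleConfig.light()
result = select_features(
    data.X, data.labels,
    SelectionConfig(q=8, k=5, seed=42, ensemble=ensemble),
)

print(f"selected {result.n_selected} features: {result.selected}")
recovered = set(truth.informative_indices) & set(result.selected)
print(f"planted features recovered: {len(recovered)}/{len(truth.informative_indices)}")
for rec in result.history:
    what = (f"accepted feature {rec.accepted}" if rec.accepted is not None
            else f"trigger: {rec.reason}" + (" -> weight reset" if rec.reset else " -> stop"))
    print(f"  iter {rec.iteration:2d} phase {rec.phase}  acc {rec.incumbent_accuracy:.4f}  {what}")

report = crossvalidate(data.X, data.labels, result.selected, k=5, seed=42,
                       model_factory=lambda s: make_classifier(ensemble, s))
print(f"5-fold CV on selected set: AUROC {report.mean['auroc']:.4f}, "
      f"AUPR {report.mean['aupr']:.4f}, accuracy {report.mean['accuracy']:.4f}")
# AUROC close to the Bayes ceiling with a handful of features means the loop
# found the signal-carrying columns and little else.
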