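"""Noise-robustness experiment.

Perturbs a pair dataset by appending one noise sample (row) and one noise
feature (column), re-runs feature selection + cross-validation on each of G
perturbed copies, and tabulates AUROC/AUPR per group together with the
spread (max - min) across groups — a stable method shows a narrow band.

The appended row draws each feature from the configured distribution
(uniform within the observed range of that column, or Gaussian matched to
its mean/sd) and gets a uniformly random 0/1 label; the appended column is
an independent noise draw per sample.  An overwrite mode (replace the last
row/column instead of appending) is available behind a flag; appending is
the default since it preserves the original data.  Every perturbation is a
pure function of (seed, group index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .core import SelectionConfig, SelectionResult, make_classifier, select_features
from .evaluation import MetricsReport, crossvalidate
from .featurization import PairDataset

__all__ = ["NoiseConfig", "add_noise", "run_noise_experiment"]

_DISTRIBUTIONS = ("uniform-in-feature-range", "gaussian-feature-matched", "none")


@dataclass(frozen=True)
class NoiseConfig:
    groups: int = 5
    noise_distribution: str = "uniform-in-feature-range"
    seed: int = 0
    overwrite: bool = False  # replace last row/column instead of appending

    def __post_init__(self) -> None:
        if self.groups < 1:
            raise ValueError("groups must be >= 1")
        if self.noise_distribution not in _DISTRIBUTIONS:
            raise ValueError(
                f"noise_distribution must be one of {_DISTRIBUTIONS}"
            )


def _draw_row(X: np.ndarray, dist: str, rng) -> np.ndarray:
    if dist == "uniform-in-feature-range":
        lo, hi = X.min(axis=0), X.max(axis=0)
        return rng.uniform(lo, hi)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    return rng.normal(mu, sd)


def _draw_col(n: int, dist: str, rng) -> np.ndarray:
    if dist == "uniform-in-feature-range":
        return rng.uniform(0.0, 1.0, size=n)
    return rng.normal(0.0, 1.0, size=n)


def add_noise(data: PairDataset, cfg: NoiseConfig, group_index: int) -> PairDataset:
    """Return a perturbed copy of ``data``; the input is never mutated.

    Appending mode: output shape is (n+1) x (p+1).  Overwrite mode: the last
    row and column are replaced in place of the copy, shape unchanged.  With
    ``noise_distribution="none"`` the copy is returned unperturbed.
    """
    if data.n_samples < 1 or data.n_features < 1:
        raise ValueError("dataset must be non-empty")
    if cfg.noise_distribution == "none":
        return PairDataset(
            data.X.copy(),
            data.labels.copy(),
            list(data.feature_names),
            list(data.pair_ids),
            provenance=dict(data.provenance),
        )
    rng = np.random.default_rng(derive_seed(cfg.seed, 41, group_index))
    row = _draw_row(data.X, cfg.noise_distribution, rng)
    label = int(rng.integers(0, 2))
    if cfg.overwrite:
        X = data.X.copy()
        X[-1, :] = row
        X[:, -1] = _draw_col(data.n_samples, cfg.noise_distribution, rng)
        labels = data.labels.copy()
        labels[-1] = label
        return PairDataset(
            X,
            labels,
            list(data.feature_names),
            list(data.pair_ids),
            provenance={**data.provenance, "noise_group": group_index},
        )
    col = _draw_col(data.n_samples + 1, cfg.noise_distribution, rng)
    X = np.empty((data.n_samples + 1, data.n_features + 1))
    X[:-1, :-1] = data.X
    X[-1, :-1] = row
    X[:, -1] = col
    labels = np.append(data.labels, label)
    names = list(data.feature_names) + [f"noise:g{group_index}"]
    pair_ids = list(data.pair_ids) + [("noise", f"g{group_index}")]
    return PairDataset(
        X, labels, names, pair_ids,
        provenance={**data.provenance, "noise_group": group_index},
    )


def run_noise_experiment(
    data: PairDataset,
    cfg: NoiseConfig,
    selection: SelectionConfig | None = None,
    eval_k: int = 5,
) -> dict:
    """Perturb, re-select and re-evaluate G times; tabulate AUROC/AUPR.

    Each group re-runs the entire selection (the experiment probes the
    stability of feature selection, not just of the final classifier).
    Returns a dict with a per-group :class:`pandas.DataFrame` table, the
    per-metric spread (max - min), and the per-group selection results.
    """
    selection = selection or SelectionConfig()
    rows = []
    selections: list[SelectionResult] = []
    reports: list[MetricsReport] = []
    for g in range(1, cfg.groups + 1):
        perturbed = add_noise(data, cfg, g)
        sel_cfg = replace(selection, seed=derive_seed(cfg.seed, 42, g))
        result = select_features(perturbed.X, perturbed.labels, sel_cfg)
        report = crossvalidate(
            perturbed.X,
            perturbed.labels,
            result.selected,
            k=eval_k,
            seed=derive_seed(cfg.seed, 43, g),
            model_factory=lambda s, e=selection.ensemble: make_classifier(e, s),
        )
        selections.append(result)
        reports.append(report)
        rows.append(
            {
                "group": g,
                "auroc": report.mean["auroc"],
                "aupr": report.mean["aupr"],
                "n_selected": result.n_selected,
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    spread = {
        "auroc": float(table["auroc"].max() - table["auroc"].min()),
        "aupr": float(table["aupr"].max() - table["aupr"].min()),
    }
    return {
        "table": table,
        "spread": spread,
        "selections": selections,
        "reports": reports,
    }
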