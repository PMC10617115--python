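"""The reweighting-boosting feature-selection (RBFS) loop.

Starting from uniform sample weights, each iteration (a) ranks all features
by total-gain importance of a gradient-boosted tree ensemble fitted under
the current sample weights, (b) scans the top-q ranked features not yet
selected, (c) scores each candidate by the stratified k-fold CV accuracy of
the classifier on the incumbent set plus that candidate, and (d) greedily
accepts the best candidate iff it strictly improves on the incumbent
accuracy.  On acceptance the classifier is refit (weighted) on the selected
columns and its training-set class probabilities drive the multiplicative
cross-entropy weight update for the next iteration.

Termination is two-stage: the first time no candidate is acceptable (no
strict improvement, or every feature is already selected so the window is
empty — the "feature selected twice" condition), the sample weights are
reset to the uniform 1/n vector and the search continues from the current
set; the second trigger (or the max_iterations safety net) stops the
algorithm and the current set is final.

Candidate CV evaluation is unweighted (accuracy is defined on raw samples);
sample weights enter the ranking fit and the post-acceptance refit that
produces the probabilities for the weight update.  Within one iteration all
candidates share identical CV folds so their accuracies are comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .reweighting import (
    CrossEntropyScores,
    SampleWeights,
    cross_entropy_scores,
    reset_weights,
    update_weights,
)

__all__ = [
    "EnsembleConfig",
    "SelectionConfig",
    "FeatureRanking",
    "IterationRecord",
    "SelectionResult",
    "make_classifier",
    "rank_features",
    "evaluate_candidate",
    "select_features",
    "fit_final_model",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Gradient-boosted tree hyperparameters (xgboost backend)."""

    n_estimators: int = 200
    max_depth: int = 6
    learning_rate: float = 0.1

    # a lighter configuration for desk-scale experiments / simulation studies
    @classmethod
    def light(cls) -> "EnsembleConfig":
        return cls(n_estimators=60, max_depth=3, learning_rate=0.1)


def make_classifier(cfg: EnsembleConfig, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        learning_rate=cfg.learning_rate,
        tree_method="hist",
        n_jobs=1,
        random_state=int(seed),
        eval_metric="logloss",
    )


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of the selection loop.

    q: candidate-window size (top-q ranked, not-yet-selected features
    scanned per iteration); k: CV fold count; max_iterations: safety net on
    total iterations across both phases.
    """

    q: int = 10
    k: int = 5
    seed: int = 0
    max_iterations: int = 100
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)


@dataclass
class FeatureRanking:
    """Features ordered by importance, best first; ties by ascending index."""

    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)


def rank_features(
    X,
    y,
    w: SampleWeights | None = None,
    seed: int = 0,
    ensemble: EnsembleConfig | None = None,
    k: int = 5,
) -> FeatureRanking:
    """Rank all features by total-gain importance under sample weights ``w``.

    Features never used by any tree score exactly 0 and rank after every
    feature with positive gain; ties break toward the lower index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if n < 2 * k:
        raise ValueError(f"n={n} too small for k={k} folds (need >= {2 * k})")
    ensemble = ensemble or EnsembleConfig()
    sample_weight = None if w is None else w.w * n
    model = make_classifier(ensemble, seed)
    model.fit(X, y, sample_weight=sample_weight)
    gain = model.get_booster().get_score(importance_type="total_gain")
    scores = np.zeros(p)
    for name, g in gain.items():
        scores[int(name[1:])] = g
    order = np.lexsort((np.arange(p), -scores))
    return FeatureRanking(order=order, scores=scores)


def evaluate_candidate(
    X,
    y,
    feature_subset,
    k: int = 5,
    seed: int = 0,
    ensemble: EnsembleConfig | None = None,
) -> float:
    """Mean stratified k-fold CV accuracy of the classifier restricted to
    ``feature_subset``.  Folds are fixed by ``seed``; deterministic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature_subset must be non-empty")
    if min(subset) < 0 or max(subset) >= X.shape[1]:
        raise ValueError("feature_subset references an invalid column")
    if k < 2:
        raise ValueError("k must be >= 2")
    ensemble = ensemble or EnsembleConfig()
    Xs = X[:, subset]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(Xs, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"fold {fold} training split is missing a class; "
                "check stratification / class balance"
            )
        model = make_classifier(ensemble, derive_seed(seed, fold))
        model.fit(Xs[tr], y[tr])
        accs.append(float((model.predict(Xs[te]) == y[te]).mean()))
    return float(np.mean(accs))


@dataclass
class IterationRecord:
    """One iteration of the loop: what was scanned, what happened."""

    iteration: int
    phase: int
    candidates: list[int]
    candidate_accuracies: list[float]
    accepted: int | None
    reason: str | None  # None | "no_improvement" | "exhausted" | "max_iterations"
    incumbent_accuracy: float
    weight_hash: str
    reset: bool = False
    weights: np.ndarray | None = None  # in-memory snapshot, not serialized

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("weights")
        return d


@dataclass
class SelectionResult:
    """Ordered selected features plus the full per-iteration history."""

    selected: list[int]
    history: list[IterationRecord]
    config: SelectionConfig
    seed: int
    feature_names: list[str] | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def accepted_accuracies(self) -> list[float]:
        return [r.incumbent_accuracy for r in self.history if r.accepted is not None]

    def selected_names(self) -> list[str]:
        if self.feature_names is None:
            return [f"f{i}" for i in self.selected]
        return [self.feature_names[i] for i in self.selected]

    def to_json(self) -> str:
        cfg = asdict(self.config)
        return json.dumps(
            {
                "selected": [int(i) for i in self.selected],
                "selected_names": self.selected_names(),
                "seed": self.seed,
                "config": cfg,
                "history": [r.to_dict() for r in self.history],
            },
            indent=2,
        )


def _weight_hash(w: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(w).tobytes()).hexdigest()[:16]


def fit_final_model(
    X,
    y,
    selected,
    seed: int = 0,
    ensemble: EnsembleConfig | None = None,
    sample_weight: np.ndarray | None = None,
):
    """Fit the ensemble on the selected columns; return (model, probs).

    ``probs`` is the training-set class-probability matrix (rows sum to 1).
    """
    selected = list(selected)
    if not selected:
        raise ValueError("empty selection")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    ensemble = ensemble or EnsembleConfig()
    model = make_classifier(ensemble, seed)
    model.fit(X[:, selected], y, sample_weight=sample_weight)
    probs = model.predict_proba(X[:, selected])
    return model, probs


def select_features(X, y, config: SelectionConfig | None = None) -> SelectionResult:
    """Run the full two-phase selection loop; see the module docstring."""
    config = config or SelectionConfig()
    if config.max_iterations <= 0:
        raise ValueError("max_iterations must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    seed = config.seed

    w = reset_weights(n)
    d_prev: CrossEntropyScores | None = None
    selected: list[int] = []
    incumbent = -np.inf
    phase = 1
    history: list[IterationRecord] = []

    def trigger(it: int, reason: str, cands, accs) -> bool:
        """Handle a termination trigger; returns True when the loop must stop."""
        nonlocal phase, w, d_prev
        stop = phase == 2
        rec = IterationRecord(
            iteration=it,
            phase=phase,
            candidates=[int(c) for c in cands],
            candidate_accuracies=[float(a) for a in accs],
            accepted=None,
            reason=reason,
            incumbent_accuracy=float(incumbent),
            weight_hash="",
            reset=not stop,
        )
        if not stop:
            phase = 2
            w = reset_weights(n)
            d_prev = None
        rec.weights = w.w.copy()
        rec.weight_hash = _weight_hash(w.w)
        history.append(rec)
        return stop

    for it in range(1, config.max_iterations + 1):
        ranking = rank_features(
            X, y, w, seed=derive_seed(seed, 1, it), ensemble=config.ensemble, k=config.k
        )
        in_s = set(selected)
        window = [int(f) for f in ranking.order if int(f) not in in_s][: config.q]
        if not window:
            if trigger(it, "exhausted", [], []):
                break
            continue
        fold_seed = derive_seed(seed, 2, it)
        accs = [
            evaluate_candidate(
                X, y, selected + [f], k=config.k, seed=fold_seed, ensemble=config.ensemble
            )
            for f in window
        ]
        best_pos = int(np.argmax(accs))  # ties break toward the better-ranked feature
        best_f, best_acc = window[best_pos], accs[best_pos]
        if best_acc <= incumbent or best_f in in_s:
            if trigger(it, "no_improvement", window, accs):
                break
            continue
        # acceptance: extend the set, refit weighted, update sample weights
        selected.append(best_f)
        incumbent = best_acc
        _, probs = fit_final_model(
            X,
            y,
            selected,
            seed=derive_seed(seed, 3, it),
            ensemble=config.ensemble,
            sample_weight=w.w * n,
        )
        d_curr = cross_entropy_scores(probs, y, iteration=it)
        w = update_weights(w, d_curr, d_prev)
        d_prev = d_curr
        history.append(
            IterationRecord(
                iteration=it,
                phase=phase,
                candidates=window,
                candidate_accuracies=[float(a) for a in accs],
                accepted=int(best_f),
                reason=None,
                incumbent_accuracy=float(incumbent),
                weight_hash=_weight_hash(w.w),
                weights=w.w.copy(),
            )
        )
    else:
        history.append(
            IterationRecord(
                iteration=config.max_iterations,
                phase=phase,
                candidates=[],
                candidate_accuracies=[],
                accepted=None,
                reason="max_iterations",
                incumbent_accuracy=float(incumbent),
                weight_hash=_weight_hash(w.w),
                weights=w.w.copy(),
            )
        )

    return SelectionResult(
        selected=selected, history=history, config=config, seed=seed
    )
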