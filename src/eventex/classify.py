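"""Pluggable classifier contract over sparse examples.

The pipeline's four steps are all plain multiclass classification over
sparse named features, so any classifier exposing per-class confidence
scores can be plugged in.  Two adapters are provided: a scikit-learn wrapper
(decision values where available, class-membership probabilities otherwise)
and an "always correct" oracle that simply returns each example's annotated
class — the tool used to measure the performance impact of each pipeline
component in isolation.

Recall adjustment trades precision for recall in trigger prediction by
scaling the negative class's confidence with a multiplier beta in [0, 1]:
beta = 1 leaves predictions unchanged, smaller beta converts borderline
negatives into the best-scoring positive class, and the number of positive
predictions is non-increasing in beta.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .features import NEGATIVE_CLASS, Example, FeatureSpace


class CapabilityError(RuntimeError):
    """The adapter does not support the requested operation."""


@dataclass
class PredictionRecord:
    example_id: str
    scores: dict[str, float]
    predicted: str


def _argmax(scores: dict[str, float]) -> str:
    # deterministic: ties broken by class name
    return max(sorted(scores), key=lambda c: scores[c])


class OracleClassifier:
    """Dummy classifier that returns the correct class for annotated examples.

    Confidence is 1 for the gold class and 0 elsewhere.  Useful for replacing
    individual pipeline components to estimate how much error each one
    contributes.  Unlabelled examples are an error: the oracle cannot guess.
    """

    supports_confidences = True
    supports_importances = False

    def train(self, examples: list[Example], **hyperparameters) -> "OracleClassifier":
        return self

    def predict(self, examples: list[Example]) -> list[PredictionRecord]:
        records = []
        for ex in examples:
            if ex.gold_class is None:
                raise ValueError(f"example {ex.id} has no gold class; oracle cannot predict")
            records.append(
                PredictionRecord(ex.id, {ex.gold_class: 1.0, NEGATIVE_CLASS: 0.0}
                                 if ex.gold_class != NEGATIVE_CLASS
                                 else {NEGATIVE_CLASS: 1.0}, ex.gold_class)
            )
        return records

    def classes(self) -> list[str]:
        return []


class SklearnClassifier:
    """Adapter for scikit-learn estimators over a frozen feature space.

    Confidences come from ``decision_function`` when the estimator has one,
    otherwise from ``predict_proba``.  Estimators exposing
    ``feature_importances_`` also support importance ranking.  Any estimator
    taking a ``random_state`` receives an explicit seed.
    """

    def __init__(self, estimator, feature_space: FeatureSpace | None = None, seed: int = 1):
        self.estimator = estimator
        self.space = feature_space or FeatureSpace()
        if "random_state" in getattr(estimator, "get_params", dict)():
            estimator.set_params(random_state=seed)
        self._classes: list[str] = []

    @property
    def supports_confidences(self) -> bool:
        return hasattr(self.estimator, "decision_function") or hasattr(
            self.estimator, "predict_proba"
        )

    @property
    def supports_importances(self) -> bool:
        return hasattr(self.estimator, "feature_importances_") or hasattr(
            self.estimator, "coef_"
        )

    def train(self, examples: list[Example], **hyperparameters) -> "SklearnClassifier":
        if hyperparameters:
            self.estimator.set_params(**hyperparameters)
        X = self.space.transform(examples)
        self.space.freeze()
        y = [ex.gold_class for ex in examples]
        if any(c is None for c in y):
            raise ValueError("training requires gold classes on all examples")
        self.estimator.fit(X, y)
        self._classes = list(self.estimator.classes_)
        return self

    def predict(self, examples: list[Example]) -> list[PredictionRecord]:
        if not examples:
            return []
        X = self.space.transform(examples)
        if hasattr(self.estimator, "decision_function"):
            raw = self.estimator.decision_function(X)
            if raw.ndim == 1:  # binary: one column for the positive class
                raw = np.stack([-raw, raw], axis=1)
        else:
            raw = self.estimator.predict_proba(X)
        records = []
        for ex, row in zip(examples, raw):
            scores = {c: float(v) for c, v in zip(self._classes, row)}
            records.append(PredictionRecord(ex.id, scores, _argmax(scores)))
        return records

    def classes(self) -> list[str]:
        return list(self._classes)


def adjust_recall(
    records: list[PredictionRecord], beta: float, negative_class: str = NEGATIVE_CLASS
) -> list[PredictionRecord]:
    """Scale the negative class's confidence by beta and re-take the argmax.

    When a record carries signed decision values its scores are first shifted
    so the minimum is zero (argmax- and order-preserving, independent of
    beta); nonnegative confidences are scaled directly.  beta = 1 is the
    identity; beta = 0 assigns every example its best positive class.  The
    count of positive predictions is non-increasing in beta.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    out = []
    for r in records:
        scores = dict(r.scores)
        if negative_class in scores and len(scores) > 1:
            lo = min(scores.values())
            if lo < 0:
                scores = {c: v - lo for c, v in scores.items()}
            scores[negative_class] *= beta
        out.append(PredictionRecord(r.example_id, scores, _argmax(scores)))
    return out


def positive_count(records: list[PredictionRecord], negative_class: str = NEGATIVE_CLASS) -> int:
    return sum(1 for r in records if r.predicted != negative_class)


def micro_f_examples(
    records: list[PredictionRecord],
    examples: list[Example],
    negative_class: str = NEGATIVE_CLASS,
) -> float:
    """Micro-averaged F over positive classes, in percent."""
    gold = {ex.id: ex.gold_class for ex in examples}
    tp = fp = fn = 0
    for r in records:
        g = gold[r.example_id]
        p = r.predicted
        if p != negative_class and p == g:
            tp += 1
        elif p != negative_class:
            fp += 1
            if g != negative_class:
                fn += 1
        elif g != negative_class:
            fn += 1
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 200 * precision * recall / (precision + recall)


def tune_parameters(
    train_examples: list[Example],
    devel_examples: list[Example],
    adapter_factory,
    grid: dict[str, list],
    beta_grid: list[float] | None = None,
    objective=None,
):
    """Exhaustive grid search over (hyperparameters × beta).

    ``adapter_factory()`` must return a fresh untrained adapter;
    ``objective(records, devel_examples)`` scores a prediction (default:
    micro-averaged F over positive classes).  The winner is deterministic:
    best score, ties broken by largest beta, then by the smallest value of
    each hyperparameter in sorted key order.
    """
    if not grid and not beta_grid:
        raise ValueError("empty grid")
    if objective is None:
        objective = micro_f_examples
    beta_grid = beta_grid or [1.0]
    keys = sorted(grid)
    combos = list(itertools.product(*(grid[k] for k in keys))) or [()]
    best = None
    for combo in combos:
        params = dict(zip(keys, combo))
        adapter = adapter_factory()
        adapter.train(train_examples, **params)
        base = adapter.predict(devel_examples)
        for beta in beta_grid:
            records = adjust_recall(base, beta)
            score = objective(records, devel_examples)
            key = (score, beta, tuple(-_as_ordinal(params[k]) for k in keys))
            if best is None or key > best[0]:
                best = (key, params, beta, score)
    _, params, beta, score = best
    return {"params": params, "beta": beta, "score": score}


def _as_ordinal(v):
    try:
        return float(v)
    except (TypeError, ValueError):
        return 0.0


#: default regularization grid: log-spaced 10^-3 .. 10^6
DEFAULT_C_GRID = [10.0 ** k for k in range(-3, 7)]


def rank_feature_importances(
    adapter, feature_space: FeatureSpace | None = None
) -> list[tuple[str, float]]:
    """Per-feature importance weights, normalized and sorted descending.

    Tree ensembles report mean decrease in node impurity over all trees;
    linear models fall back to mean absolute coefficient magnitude.
    """
    if not getattr(adapter, "supports_importances", False):
        raise CapabilityError("adapter does not expose feature importances")
    est = adapter.estimator
    if hasattr(est, "feature_importances_"):
        weights = np.asarray(est.feature_importances_, dtype=float)
    else:
        coef = np.atleast_2d(est.coef_)
        weights = np.abs(coef).mean(axis=0)
    total = weights.sum()
    if total > 0:
        weights = weights / total
    space = feature_space or adapter.space
    names = space.names
    pairs = [(names[i], float(w)) for i, w in enumerate(weights[: len(names)])]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


def feature_group(name: str) -> str:
    """Map a feature name to its generator group (for importance reports)."""
    if name.startswith("arg"):
        return "args"
    if name.startswith("trg_"):
        return "trigger"
    if name.startswith("ctx_"):
        return "context"
    if name.startswith(("e1_", "e2_")):
        return "entity"
    if name.startswith("linear_"):
        return "linear"
    if name.startswith(("dist_", "t1HOut_", "chain_dist", "dep_dist")):
        return "dependencies"
    if name.startswith(("dep_", "tok_", "path_", "tokenPath_", "ngram_", "noDepPath")):
        return "path"
    if name.startswith(("bow_", "sentAnnType_")):
        return "sentence"
    if name.startswith(("stem_", "dt_", "tt_")):
        return "subtoken"
    if name.startswith("specWord_"):
        return "spec"
    return "token"


@dataclass
class GroupSummary:
    group: str
    count: int
    median: float
    q1: float
    q3: float
    outliers: int
    top: list[tuple[str, float]] = field(default_factory=list)


def grouped_importance_report(
    ranked: list[tuple[str, float]], top_k: int = 10
) -> dict[str, GroupSummary]:
    """Box-plot style per-group summaries of feature-importance weights.

    Outliers are points beyond 1.5 interquartile ranges from the quartiles.
    Every feature falls in exactly one group.
    """
    groups: dict[str, list[tuple[str, float]]] = {}
    for name, w in ranked:
        groups.setdefault(feature_group(name), []).append((name, w))
    report = {}
    for g, items in sorted(groups.items()):
        values = np.array([w for _, w in items])
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        outliers = int(((values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)).sum())
        report[g] = GroupSummary(
            group=g,
            count=len(items),
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            outliers=outliers,
            top=sorted(items, key=lambda p: (-p[1], p[0]))[:top_k],
        )
    return report
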