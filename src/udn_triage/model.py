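"""Linear logistic classifier over the feature tiers, with split,
hyperparameter-search, and evaluation utilities.

The classifier is an L2-regularized logistic regression (a linear decision
boundary); its confidence score for ranking is the signed distance of a
feature vector to the separating hyperplane, (w.x + b)/||w||.  Evaluation
reports sensitivity, specificity, balanced accuracy and AUROC with the
accepted class as positive.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata, wilcoxon
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import Application, Label
from .features import FeaturePipeline, FeatureVector, Tier

#: inverse-regularization strengths searched by default
DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
#: class-weight settings searched by default
DEFAULT_CLASS_WEIGHTS = ("balanced", None)


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.8
    validation: float = 0.1
    test: float = 0.1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if min(fracs) < 0 or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must be non-negative and sum to 1")


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    ideal = [n * f for f in fractions]
    base = [math.floor(x) for x in ideal]
    remainder = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return base


def stratified_split(
    apps: Sequence[Application], spec: SplitSpec
) -> tuple[list[Application], list[Application], list[Application]]:
    """Disjoint, exhaustive train/validation/test partition.

    Within each label, counts are allocated by largest-remainder rounding,
    which keeps every split's label proportion within one application of
    the cohort proportion.
    """
    if len(apps) < 10:
        raise ValueError("need at least 10 applications to split")
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train, spec.validation, spec.test)
    groups: dict[str, list[int]]
    if spec.stratified:
        groups = {}
        for i, a in enumerate(apps):
            groups.setdefault(a.label, []).append(i)
    else:
        groups = {"all": list(range(len(apps)))}
    splits: tuple[list[int], ...] = ([], [], [])
    for label in sorted(groups):
        idx = np.array(groups[label])
        rng.shuffle(idx)
        sizes = _largest_remainder(len(idx), fractions)
        start = 0
        for s, size in zip(splits, sizes):
            s.extend(idx[start:start + size].tolist())
            start += size
    return tuple([apps[i] for i in sorted(s)] for s in splits)  # type: ignore[return-value]


# --------------------------------------------------------------------------
# metrics

def auroc(labels: Sequence[Label], scores: Sequence[float]) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) definition:
    the probability a random accepted application outscores a random
    not-accepted one, with ties counted one half."""
    y = np.array([1 if l == "accepted" else 0 for l in labels])
    s = np.asarray(scores, dtype=float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes in the evaluation set")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auroc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy, "auroc": self.auroc,
        }


def metrics_from_scores(
    labels: Sequence[Label], scores: Sequence[float], threshold: float = 0.0
) -> MetricsReport:
    y = np.array([l == "accepted" for l in labels])
    s = np.asarray(scores, dtype=float)
    pred = s > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        balanced_accuracy=balanced_accuracy(sens, spec),
        auroc=auroc(labels, s),
    )


# --------------------------------------------------------------------------
# training

@dataclass
class TrainedModel:
    """A fitted linear decision function over named features."""

    weights: dict[str, float]
    intercept: float
    tier: Tier
    hyperparameters: dict = field(default_factory=dict)
    pipeline: FeaturePipeline | None = None

    def __post_init__(self) -> None:
        arr = np.array(list(self.weights.values()), dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("model weights must be finite")
        self._norm = float(np.linalg.norm(arr))

    @property
    def weight_norm(self) -> float:
        return self._norm

    def feature_state_hash(self) -> str:
        payload = json.dumps(sorted(self.weights), separators=(",", ":")).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_json(self) -> str:
        return json.dumps({
            "tier": self.tier.label,
            "intercept": self.intercept,
            "hyperparameters": self.hyperparameters,
            "feature_state_hash": self.feature_state_hash(),
            "weights": self.weights,
        }, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        obj = json.loads(text)
        return cls(
            weights=obj["weights"], intercept=obj["intercept"],
            tier=Tier.from_name(obj["tier"]), hyperparameters=obj.get("hyperparameters", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text())


def decision_score(model: TrainedModel, x: FeatureVector) -> float:
    """Signed distance to the separating hyperplane: (w.x + b)/||w||.

    Positive scores predict acceptance; features absent from the model (or
    the vector) contribute zero.
    """
    if model.weight_norm == 0.0:
        raise ValueError("signed distance undefined for a zero weight vector")
    z = model.intercept + sum(model.weights.get(name, 0.0) * v for name, v in x.items())
    return z / model.weight_norm


def _scores_from_matrix(model: TrainedModel, names: Sequence[str], X: sp.spmatrix) -> np.ndarray:
    if model.weight_norm == 0.0:
        raise ValueError("signed distance undefined for a zero weight vector")
    w = np.array([model.weights.get(n, 0.0) for n in names])
    return (X @ w + model.intercept) / model.weight_norm


def score_applications(model: TrainedModel, apps: Sequence[Application],
                       pipeline: FeaturePipeline | None = None) -> np.ndarray:
    """Signed distances for a batch of applications."""
    pipe = pipeline or model.pipeline
    if pipe is None:
        raise ValueError("a fitted feature pipeline is required for scoring")
    return _scores_from_matrix(model, pipe.feature_names(), pipe.transform_matrix(apps))


def _fit_logistic(X: sp.spmatrix, y: np.ndarray, C: float, class_weight) -> LogisticRegression:
    clf = LogisticRegression(
        C=C, class_weight=class_weight,
        solver="liblinear", max_iter=2000, tol=1e-6,
    )
    clf.fit(X, y)
    return clf


def train(
    train_set: Sequence[Application],
    validation_set: Sequence[Application],
    tier: Tier | str,
    grid_C: Sequence[float] = DEFAULT_C_GRID,
    grid_class_weight: Sequence = DEFAULT_CLASS_WEIGHTS,
    **pipeline_kwargs,
) -> TrainedModel:
    """Grid-search an L2 logistic model over (C, class weight).

    Feature components are fitted on the training set only; the candidate
    maximizing validation AUROC wins, with ties broken toward stronger
    regularization (smaller C).
    """
    tier = Tier.from_name(tier)
    labels = {a.label for a in train_set}
    if len(labels) < 2:
        raise ValueError("training set must contain both classes")
    pipe = FeaturePipeline(tier, **pipeline_kwargs).fit(train_set)
    Xtr = pipe.transform_matrix(train_set)
    ytr = np.array([a.label == "accepted" for a in train_set], dtype=int)
    Xva = pipe.transform_matrix(validation_set)
    yva = [a.label for a in validation_set]

    best = None
    for ci, C in enumerate(sorted(grid_C)):
        for wi, cw in enumerate(grid_class_weight):
            clf = _fit_logistic(Xtr, ytr, C, cw)
            val_auc = auroc(yva, clf.decision_function(Xva))
            key = (-val_auc, ci, wi)
            if best is None or key < best[0]:
                best = (key, C, cw, clf)
    assert best is not None
    _, C, cw, clf = best
    names = pipe.feature_names()
    coef = clf.coef_.ravel()
    return TrainedModel(
        weights={n: float(w) for n, w in zip(names, coef)},
        intercept=float(clf.intercept_[0]),
        tier=tier,
        hyperparameters={"C": C, "class_weight": cw},
        pipeline=pipe,
    )


def evaluate(
    model: TrainedModel,
    eval_set: Sequence[Application],
    pipeline: FeaturePipeline | None = None,
    threshold: float = 0.0,
) -> MetricsReport:
    """Score an evaluation set and report the four headline metrics."""
    scores = score_applications(model, eval_set, pipeline)
    return metrics_from_scores([a.label for a in eval_set], scores, threshold)


# --------------------------------------------------------------------------
# paired model comparison

def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired values; if every
    pair is tied the test is undefined and p = 1 is reported."""
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(diffs == 0.0):
        return 1.0
    return float(wilcoxon(diffs, alternative="two-sided").pvalue)


def compare_models(
    apps: Sequence[Application],
    tier_a: Tier | str,
    tier_b: Tier | str,
    n_repeats: int = 10,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    class_weight="balanced",
    **pipeline_kwargs,
) -> float:
    """Paired comparison of two feature tiers.

    Repeated stratified k-fold cross-validation with folds shared between
    the tiers; per-fold test AUROCs form the pairs for a two-sided
    Wilcoxon signed-rank test.
    """
    y = np.array([a.label == "accepted" for a in apps], dtype=int)
    auc_a: list[float] = []
    auc_b: list[float] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for tr_idx, te_idx in skf.split(np.zeros(len(apps)), y):
            tr = [apps[i] for i in tr_idx]
            te = [apps[i] for i in te_idx]
            te_labels = [a.label for a in te]
            for tier, out in ((tier_a, auc_a), (tier_b, auc_b)):
                pipe = FeaturePipeline(Tier.from_name(tier), **pipeline_kwargs).fit(tr)
                clf = _fit_logistic(pipe.transform_matrix(tr), y[tr_idx], C, class_weight)
                out.append(auroc(te_labels, clf.decision_function(pipe.transform_matrix(te))))
    return wilcoxon_paired(auc_a, auc_b)
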