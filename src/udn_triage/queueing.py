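"""Capacity-constrained review-queue simulation and ranking heuristics.

Review sessions occur every ``d`` days (first session on day ``d``) and at
most ``a`` applications are reviewed per session.  An application becomes
eligible at the first session strictly after its submission day; at each
session the highest-priority eligible applications are reviewed, under one
of four ranking heuristics:

* ``fifo`` — submission order, no priority judgment;
* ``udn_order`` — the historically recorded review days (bypasses the
  session mechanics entirely);
* ``classifier`` — descending out-of-fold classifier confidence (signed
  distance to the decision hyperplane);
* ``accept_first`` — an oracle ordering: all eventually-accepted
  applications (FIFO within class) ahead of all not-accepted ones; this
  lower-bounds the accepted group's mean processing time.

Processing time is (review day - submission day) / 30.44, in months.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import MONTH_DAYS, Application, Label
from .features import FeaturePipeline, Tier
from .model import TrainedModel, _fit_logistic, _scores_from_matrix

ConfidenceTable = Mapping[str, float]


class Heuristic(str, Enum):
    FIFO = "fifo"
    UDN_ORDER = "udn_order"
    CLASSIFIER = "classifier"
    ACCEPT_FIRST = "accept_first"

    @classmethod
    def from_name(cls, name: "str | Heuristic") -> "Heuristic":
        if isinstance(name, Heuristic):
            return name
        return cls(name.replace("-", "_").lower())


@dataclass(frozen=True)
class Schedule:
    """Review sessions every ``period_d`` days, ``budget_a`` applications
    reviewable per session."""

    period_d: int
    budget_a: int

    def __post_init__(self) -> None:
        if self.period_d < 1 or self.budget_a < 1:
            raise ValueError("period_d and budget_a must be positive integers")


@dataclass(frozen=True)
class SimResult:
    heuristic: Heuristic
    review_days: dict[str, int]
    processing_months: dict[str, float]
    labels: dict[str, Label]

    def group(self, label: Label) -> np.ndarray:
        return np.array([m for i, m in self.processing_months.items()
                         if self.labels[i] == label])

    def mean_months(self, label: Label) -> float:
        g = self.group(label)
        return float(g.mean()) if g.size else float("nan")

    def sd_months(self, label: Label) -> float:
        g = self.group(label)
        return float(g.std(ddof=1)) if g.size > 1 else float("nan")

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            label: {"mean_months": self.mean_months(label),
                    "sd_months": self.sd_months(label),
                    "n": int(self.group(label).size)}
            for label in ("accepted", "not_accepted")
        }


# --------------------------------------------------------------------------
# out-of-fold confidence scores

def crossval_scores(
    apps: Sequence[Application],
    tier: Tier | str = Tier.SEMANTIC_TYPES,
    k: int = 5,
    seed: int = 0,
    C: float = 1.0,
    class_weight="balanced",
    **pipeline_kwargs,
) -> dict[str, float]:
    """Out-of-fold signed-distance score for every application.

    Stratified k-fold cross-validation; each application is scored exactly
    once, by a model whose training fold excluded it, with feature
    components refit per fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    tier = Tier.from_name(tier)
    y = np.array([a.label == "accepted" for a in apps], dtype=int)
    if min(y.sum(), len(y) - y.sum()) < k:
        raise ValueError("each class must have at least k members")
    table: dict[str, float] = {}
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(np.zeros(len(apps)), y):
        tr = [apps[i] for i in tr_idx]
        te = [apps[i] for i in te_idx]
        pipe = FeaturePipeline(tier, **pipeline_kwargs).fit(tr)
        clf = _fit_logistic(pipe.transform_matrix(tr), y[tr_idx], C, class_weight)
        names = pipe.feature_names()
        model = TrainedModel(
            weights={n: float(w) for n, w in zip(names, clf.coef_.ravel())},
            intercept=float(clf.intercept_[0]), tier=tier,
        )
        scores = _scores_from_matrix(model, names, pipe.transform_matrix(te))
        for app, s in zip(te, scores):
            table[app.id] = float(s)
    return table


# --------------------------------------------------------------------------
# priorities and simulation

def priority(heuristic: Heuristic | str, app: Application,
             scores: ConfidenceTable | None = None) -> tuple:
    """Sortable key (ascending = reviewed first) for one application."""
    heuristic = Heuristic.from_name(heuristic)
    if heuristic is Heuristic.FIFO:
        return (app.submission_day, app.id)
    if heuristic is Heuristic.CLASSIFIER:
        if scores is None or app.id not in scores:
            raise ValueError(f"classifier heuristic needs a confidence score for {app.id}")
        return (-scores[app.id], app.submission_day, app.id)
    if heuristic is Heuristic.ACCEPT_FIRST:
        return (app.label != "accepted", app.submission_day, app.id)
    if heuristic is Heuristic.UDN_ORDER:
        if app.recorded_review_day is None:
            raise ValueError(f"udn_order heuristic needs a recorded review day for {app.id}")
        return (app.recorded_review_day, app.id)
    raise ValueError(f"unknown heuristic {heuristic!r}")


def _simulate_sessions(
    apps: Sequence[Application],
    keys: Sequence[tuple],
    schedule: Schedule,
) -> dict[str, int]:
    """Core event loop: returns review day per application id."""
    order = sorted(range(len(apps)), key=lambda i: (apps[i].submission_day, apps[i].id))
    review_day: dict[str, int] = {}
    heap: list[tuple] = []
    next_arrival = 0
    day = 0
    while len(review_day) < len(apps):
        day += schedule.period_d
        while next_arrival < len(order) and apps[order[next_arrival]].submission_day < day:
            i = order[next_arrival]
            heapq.heappush(heap, (keys[i], apps[i].id))
            next_arrival += 1
        for _ in range(min(schedule.budget_a, len(heap))):
            _, app_id = heapq.heappop(heap)
            review_day[app_id] = day
    return review_day


def simulate_queue(
    apps: Sequence[Application],
    heuristic: Heuristic | str,
    schedule: Schedule,
    scores: ConfidenceTable | None = None,
) -> SimResult:
    """Run the review-session simulation under one ranking heuristic.

    Every application is eventually reviewed; ``udn_order`` ignores the
    schedule and replays the recorded review days.
    """
    heuristic = Heuristic.from_name(heuristic)
    if not apps:
        raise ValueError("no applications to simulate")
    if heuristic is Heuristic.UDN_ORDER:
        review_day = {}
        for a in apps:
            if a.recorded_review_day is None:
                raise ValueError(f"application {a.id} has no recorded review day")
            review_day[a.id] = a.recorded_review_day
    else:
        keys = [priority(heuristic, a, scores) for a in apps]
        review_day = _simulate_sessions(apps, keys, schedule)
    months = {a.id: (review_day[a.id] - a.submission_day) / MONTH_DAYS for a in apps}
    return SimResult(
        heuristic=heuristic,
        review_days=review_day,
        processing_months=months,
        labels={a.id: a.label for a in apps},
    )


# --------------------------------------------------------------------------
# (d, a) sweep

def sweep(
    apps: Sequence[Application],
    heuristics: Iterable[Heuristic | str],
    d_values: Sequence[int],
    a_values: Sequence[int],
    scores: ConfidenceTable | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Full-factorial (heuristic, d, a) sweep of mean processing times.

    Returns a tidy frame (heuristic, d, a, label, mean_months, sd_months,
    n) and — when both the classifier and accept-first heuristics are in
    the sweep — the (d, a) cell minimizing the absolute gap between their
    accepted-group means, ties resolved toward smaller a then smaller d.
    """
    heuristics = [Heuristic.from_name(h) for h in heuristics]
    if not heuristics or not d_values or not a_values:
        raise ValueError("sweep grid must be non-empty")
    rows = []
    acc_means: dict[tuple[Heuristic, int, int], float] = {}
    for d in d_values:
        for a in a_values:
            for h in heuristics:
                res = simulate_queue(apps, h, Schedule(period_d=d, budget_a=a), scores)
                acc_means[(h, d, a)] = res.mean_months("accepted")
                for label in ("accepted", "not_accepted"):
                    rows.append({
                        "heuristic": h.value, "d": d, "a": a, "label": label,
                        "mean_months": res.mean_months(label),
                        "sd_months": res.sd_months(label),
                        "n": int(res.group(label).size),
                    })
    frame = pd.DataFrame(rows)
    best = None
    if Heuristic.CLASSIFIER in heuristics and Heuristic.ACCEPT_FIRST in heuristics:
        cells = sorted(
            ((abs(acc_means[(Heuristic.CLASSIFIER, d, a)]
                  - acc_means[(Heuristic.ACCEPT_FIRST, d, a)]), a, d)
             for d, a in itertools.product(d_values, a_values)),
        )
        gap, a, d = cells[0]
        best = {"d": d, "a": a, "gap_months": gap}
    return frame, best


def percent_reduction(baseline_mean: float, new_mean: float) -> float:
    """Percent reduction of a mean processing time relative to a baseline."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (baseline_mean - new_mean) / baseline_mean
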