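"""Classifier: splitting, signed distances, metrics, grid search, and
paired model comparison."""

import itertools
import math

import numpy as np
import pytest

import udn_triage as u
from udn_triage.model import metrics_from_scores, wilcoxon_paired

from conftest import make_app


# --------------------------------------------------------------------------
# splitting

def _balanced_apps(n):
    return [make_app(id=f"A{i:05d}", label="accepted" if i % 2 else "not_accepted",
                     submission_day=i, recorded_review_day=i + 30)
            for i in range(n)]


def test_split_sizes_largest_remainder():
    apps = _balanced_apps(2421)
    tr, va, te = u.stratified_split(apps, u.SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (1937, 242, 242)


def test_split_disjoint_exhaustive_and_stratified(small_cohort):
    tr, va, te = u.stratified_split(small_cohort, u.SplitSpec(seed=3))
    ids = [a.id for part in (tr, va, te) for a in part]
    assert sorted(ids) == sorted(a.id for a in small_cohort)
    global_frac = sum(a.label == "accepted" for a in small_cohort) / len(small_cohort)
    for part in (tr, va, te):
        n_acc = sum(a.label == "accepted" for a in part)
        assert abs(n_acc - global_frac * len(part)) <= 1.0


def test_split_deterministic_and_seed_sensitive(small_cohort):
    a = u.stratified_split(small_cohort, u.SplitSpec(seed=5))
    b = u.stratified_split(small_cohort, u.SplitSpec(seed=5))
    c = u.stratified_split(small_cohort, u.SplitSpec(seed=6))
    assert a == b and a != c


def test_split_single_label_degenerates_gracefully():
    apps = [make_app(id=f"A{i}", label="accepted") for i in range(20)]
    tr, va, te = u.stratified_split(apps, u.SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (16, 2, 2)


def test_split_too_small_rejected():
    with pytest.raises(ValueError):
        u.stratified_split(_balanced_apps(5), u.SplitSpec())


def test_bad_fractions_rejected():
    with pytest.raises(ValueError):
        u.SplitSpec(train=0.5, validation=0.1, test=0.1)


# --------------------------------------------------------------------------
# signed distance

def test_decision_score_hand_computed():
    model = u.TrainedModel(weights={"x": 3.0, "y": 4.0}, intercept=0.0,
                           tier=u.Tier.BASELINE)
    assert u.decision_score(model, {"x": 1.0, "y": 1.0}) == pytest.approx(7 / 5)
    # a point on the hyperplane scores zero
    assert u.decision_score(model, {"x": 4.0, "y": -3.0}) == pytest.approx(0.0)
    # missing features contribute zero
    assert u.decision_score(model, {}) == pytest.approx(0.0)


def test_decision_score_scale_invariant():
    a = u.TrainedModel(weights={"x": 3.0, "y": 4.0}, intercept=1.0, tier=u.Tier.BASELINE)
    b = u.TrainedModel(weights={"x": 6.0, "y": 8.0}, intercept=2.0, tier=u.Tier.BASELINE)
    x = {"x": 0.3, "y": -1.7}
    assert u.decision_score(a, x) == pytest.approx(u.decision_score(b, x))


def test_zero_weight_vector_signalled():
    model = u.TrainedModel(weights={"x": 0.0}, intercept=1.0, tier=u.Tier.BASELINE)
    with pytest.raises(ValueError):
        u.decision_score(model, {"x": 1.0})


# --------------------------------------------------------------------------
# metrics

def _auroc_bruteforce(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l == "accepted"]
    neg = [s for l, s in zip(labels, scores) if l == "not_accepted"]
    wins = sum((p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_auroc_examples():
    labels = ["accepted", "accepted", "not_accepted", "not_accepted"]
    assert u.auroc(labels, [0.9, 0.8, 0.7, 0.1]) == pytest.approx(1.0)
    assert u.auroc(labels, [0.9, 0.7, 0.8, 0.1]) == pytest.approx(0.75)
    assert u.auroc(labels, [0.5] * 4) == pytest.approx(0.5)


def test_auroc_matches_pair_counting_oracle():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(4, 12))
        labels = ["accepted" if b else "not_accepted" for b in rng.integers(0, 2, n)]
        if len(set(labels)) < 2:
            continue
        scores = rng.choice([0.0, 0.25, 0.5, 1.0], size=n)  # force ties
        assert u.auroc(labels, scores) == pytest.approx(_auroc_bruteforce(labels, scores))


def test_auroc_monotone_transform_invariant():
    rng = np.random.default_rng(1)
    labels = ["accepted" if b else "not_accepted" for b in rng.integers(0, 2, 30)]
    scores = rng.normal(size=30)
    assert u.auroc(labels, scores) == pytest.approx(u.auroc(labels, np.exp(scores)))


def test_auroc_single_class_signalled():
    with pytest.raises(ValueError):
        u.auroc(["accepted", "accepted"], [0.1, 0.2])


def test_metrics_internally_consistent():
    labels = ["accepted"] * 5 + ["not_accepted"] * 7
    scores = [1.0, 1.0, -1.0, 2.0, 0.5, -1.0, -2.0, 1.0, -0.5, -3.0, 0.1, -0.1]
    rep = metrics_from_scores(labels, scores)
    assert rep.n == 12
    assert rep.balanced_accuracy == (rep.sensitivity + rep.specificity) / 2
    assert rep.tp + rep.fn == 5 and rep.tn + rep.fp == 7


def test_balanced_accuracy_identity():
    assert u.balanced_accuracy(0.860, 0.746) == pytest.approx(0.803)


# --------------------------------------------------------------------------
# training

def _toy_separable(n=40):
    apps = []
    for i in range(n):
        acc = i % 2 == 0
        age = 5.0 + i * 0.1 if acc else 60.0 + i * 0.1
        apps.append(make_app(id=f"T{i:03d}", label="accepted" if acc else "not_accepted",
                             age_at_application=age, age_at_onset=age / 2,
                             duration=age / 2, prior_visits=i % 3,
                             letter="plain letter"))
    return apps


def test_train_separable_toy_set_perfect_at_weak_regularization():
    apps = _toy_separable()
    model = u.train(apps, apps, "baseline", grid_C=(1e3,), grid_class_weight=(None,))
    rep = u.evaluate(model, apps)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0


def test_train_single_class_rejected():
    apps = [make_app(id=f"A{i}") for i in range(20)]
    with pytest.raises(ValueError):
        u.train(apps, apps, "baseline")


def test_train_null_labels_give_chance_validation_auroc(small_cohort):
    """With randomly permuted labels the validation AUROC sits near 0.5."""
    import dataclasses
    rng = np.random.default_rng(0)
    aurocs = []
    for seed in range(8):
        labels = [a.label for a in small_cohort]
        rng.shuffle(labels)
        permuted = [dataclasses.replace(a, label=l,
                                        recorded_review_day=a.submission_day + 30)
                    for a, l in zip(small_cohort, labels)]
        tr, va, te = u.stratified_split(permuted, u.SplitSpec(seed=seed))
        model = u.train(tr, va, "baseline", grid_C=(1.0,), grid_class_weight=(None,))
        aurocs.append(u.evaluate(model, te).auroc)
    assert abs(float(np.mean(aurocs)) - 0.5) < 0.1


def test_better_tier_beats_baseline_on_common_seed(small_cohort):
    tr, va, te = u.stratified_split(small_cohort, u.SplitSpec(seed=0))
    base = u.evaluate(u.train(tr, va, "baseline"), te)
    sem = u.evaluate(u.train(tr, va, "semantic_types"), te)
    assert sem.auroc > base.auroc


def test_model_json_round_trip(tmp_path, small_cohort):
    tr, va, te = u.stratified_split(small_cohort, u.SplitSpec(seed=0))
    model = u.train(tr, va, "walley", grid_C=(1.0,), grid_class_weight=(None,))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = u.TrainedModel.load(path)
    assert loaded.weights == pytest.approx(model.weights)
    assert loaded.intercept == pytest.approx(model.intercept)
    assert loaded.tier == model.tier
    assert loaded.feature_state_hash() == model.feature_state_hash()


def test_prospective_batch_does_not_refit(small_cohort):
    """Scoring a later batch leaves the frozen model untouched."""
    tr, va, _ = u.stratified_split(small_cohort, u.SplitSpec(seed=0))
    model = u.train(tr, va, "semantic_types", grid_C=(1.0,), grid_class_weight=(None,))
    hash_before = model.feature_state_hash()
    vocab_before = list(model.pipeline.feature_names())
    batch = u.generate_cohort(u.default_config(n_total=100, seed=99))
    rep = u.evaluate(model, batch)
    assert model.feature_state_hash() == hash_before
    assert model.pipeline.feature_names() == vocab_before
    assert 0.0 <= rep.auroc <= 1.0


# --------------------------------------------------------------------------
# paired comparison

def test_wilcoxon_self_comparison_is_one():
    assert wilcoxon_paired([0.7, 0.8, 0.9], [0.7, 0.8, 0.9]) == 1.0


def test_wilcoxon_exact_enumeration_example():
    a = [1, 2, 3, 4, 5, 6]
    b = [2, 4, 6, 8, 10, 12]
    assert wilcoxon_paired(a, b) == pytest.approx(2 / 64)


def test_compare_models_detects_a_strong_tier(small_cohort):
    p = u.compare_models(small_cohort, "semantic_types", "baseline",
                         n_repeats=2, k=5, seed=0)
    assert p < 0.05
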