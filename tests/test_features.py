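"""Feature families: boundary behaviour, hand-computed values, tier
assembly, and leakage safety."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import udn_triage as u
from udn_triage.features import (
    BaselineNormalizer,
    NotFittedError,
    PhenotypeSimilarity,
    embedding_features,
    tokenize,
)

from conftest import make_app


# --------------------------------------------------------------------------
# baseline

def test_baseline_minmax_boundaries():
    apps = [make_app(id=f"A{i}", age_at_onset=age - 5, duration=5.0,
                     age_at_application=age, prior_visits=v)
            for i, (age, v) in enumerate([(10.0, 0), (50.0, 4)])]
    norm = BaselineNormalizer().fit(apps)
    lo = norm.transform(apps[0])
    hi = norm.transform(apps[1])
    assert lo["baseline:age_at_application"] == 0.0
    assert hi["baseline:age_at_application"] == 1.0
    mid = norm.transform(make_app(age_at_application=30.0, age_at_onset=25.0, duration=5.0))
    assert mid["baseline:age_at_application"] == pytest.approx(0.5)


def test_baseline_clips_outside_training_bounds():
    apps = [make_app(id="A0", age_at_application=10.0, age_at_onset=5, duration=5),
            make_app(id="A1", age_at_application=50.0, age_at_onset=45, duration=5)]
    norm = BaselineNormalizer().fit(apps)
    out = norm.transform(make_app(age_at_application=99.0, age_at_onset=99.0, duration=0))
    assert out["baseline:age_at_application"] == 1.0


def test_unfitted_normalizer_raises():
    with pytest.raises(NotFittedError):
        BaselineNormalizer().transform(make_app())


# --------------------------------------------------------------------------
# symptom-list features

def test_walley_presence_semantics():
    lex = {"ataxia": "objective", "headache": "subjective", "brain fog": "subjective"}
    zeros = u.walley_features("", lex)
    assert set(zeros.values()) == {0.0} and len(zeros) == 3
    one = u.walley_features("notable ataxia on exam", lex)
    assert sum(one.values()) == 1.0 and one["walley:ataxia"] == 1.0
    # presence, not count
    twice = u.walley_features("Ataxia and again ataxia", lex)
    assert twice["walley:ataxia"] == 1.0
    phrase = u.walley_features("reports brain fog daily", lex)
    assert phrase["walley:brain_fog"] == 1.0
    # phrase must be contiguous tokens
    split = u.walley_features("brain scan showed fog", lex)
    assert split["walley:brain_fog"] == 0.0


# --------------------------------------------------------------------------
# TF-IDF bigrams

def test_tfidf_hand_computed_single_document():
    """One training doc 'severe ataxia severe ataxia': bigram counts
    {severe ataxia: 2, ataxia severe: 1}, idf = ln(2/2)+1 = 1, and the
    L2-normalized weights are (2, 1)/sqrt(5)."""
    model = u.fit_tfidf(["severe ataxia severe ataxia"])
    vec = u.transform_tfidf(model, "severe ataxia severe ataxia")
    assert vec["tfidf:severe_ataxia"] == pytest.approx(2 / math.sqrt(5))
    assert vec["tfidf:ataxia_severe"] == pytest.approx(1 / math.sqrt(5))


def test_tfidf_unseen_bigrams_ignored():
    model = u.fit_tfidf(["alpha beta gamma", "beta gamma delta"])
    assert u.transform_tfidf(model, "totally different words") == {}


def test_tfidf_transform_consistent_with_fit():
    corpus = ["alpha beta gamma", "beta gamma delta epsilon", "alpha delta"]
    model = u.fit_tfidf(corpus)
    mat = model.vectorizer.transform(corpus)
    names = model.feature_names
    for i, doc in enumerate(corpus):
        row = {names[j]: v for j, v in zip(mat[i].indices, mat[i].data)}
        assert u.transform_tfidf(model, doc) == pytest.approx(row)


def test_tfidf_empty_corpus_rejected():
    with pytest.raises(ValueError):
        u.fit_tfidf([])


@settings(max_examples=30, deadline=None)
@given(st.lists(st.sampled_from("alpha beta gamma delta".split()), max_size=12))
def test_tfidf_norm_is_zero_or_one(tokens):
    model = u.fit_tfidf(["alpha beta gamma delta alpha beta"])
    vec = u.transform_tfidf(model, " ".join(tokens))
    norm = math.sqrt(sum(v * v for v in vec.values()))
    assert norm == pytest.approx(0.0) or norm == pytest.approx(1.0)


# --------------------------------------------------------------------------
# semantic types

def test_semantic_type_lookup():
    lex = u.load_concept_lexicon()
    vec = u.semantic_type_features("patient reports seizures", lex)
    assert vec["semtype:sign_or_symptom"] == 1.0
    assert sum(vec.values()) == 1.0 and len(vec) == 5
    assert set(u.semantic_type_features("", lex).values()) == {0.0}
    all_types = "ataxia then biopsy for epilepsy of the cerebellum gene mecp2"
    assert set(u.semantic_type_features(all_types, lex).values()) == {1.0}


# --------------------------------------------------------------------------
# cosine and embeddings

def test_cosine_values():
    v = np.array([1.0, 2.0, 3.0])
    assert u.cosine(v, v) == pytest.approx(1.0)
    assert u.cosine([1, 0], [0, 1]) == pytest.approx(0.0)
    assert u.cosine([1, 2, 3], [4, 5, 6]) == pytest.approx(32 / math.sqrt(14 * 77))
    with pytest.raises(ValueError):
        u.cosine([0.0, 0.0], [1.0, 1.0])
    with pytest.raises(ValueError):
        u.cosine([1.0], [1.0, 2.0])


def test_hashed_embedding_is_deterministic():
    backend = u.hashed_embedding()
    text = "recurrent seizures with ataxia"
    assert np.array_equal(backend.embed(text), backend.embed(text))
    assert backend.embed(text).shape == (backend.dimension,)


def test_omim_similarity_identical_text_gives_one(corpus):
    backend = u.hashed_embedding()
    entry = corpus[0]
    vec = u.omim_similarity_features(entry.description, corpus, backend)
    assert len(vec) == len(corpus)
    assert vec[f"omim:{entry.entry_id}"] == pytest.approx(1.0)


def test_omim_similarity_single_entry_corpus():
    backend = u.hashed_embedding()
    corpus = [u.PhenotypeEntry(entry_id="PHE-000001", description="alpha beta")]
    vec = u.omim_similarity_features("gamma alpha", corpus, backend)
    assert len(vec) == 1


def test_omim_similarity_disjoint_vocabulary_is_zero():
    """With a collision-free toy vocabulary, disjoint token sets map to
    orthogonal hashed vectors and the similarity feature is exactly 0."""
    backend = u.hashed_embedding(dimension=4096)
    # pick tokens occupying distinct hash buckets
    pool = [f"tok{i}" for i in range(40)]
    buckets = {t: int(np.flatnonzero(backend.embed(t))[0]) for t in pool}
    chosen: list[str] = []
    for t in pool:
        if buckets[t] not in {buckets[c] for c in chosen}:
            chosen.append(t)
        if len(chosen) == 6:
            break
    letter, entry = " ".join(chosen[:3]), " ".join(chosen[3:])
    corpus = [u.PhenotypeEntry(entry_id="PHE-000001", description=entry)]
    vec = u.omim_similarity_features(letter, corpus, backend)
    assert vec["omim:PHE-000001"] == pytest.approx(0.0)


def test_zero_embedding_signalled(corpus):
    sim = PhenotypeSimilarity(u.hashed_embedding()).fit(corpus)
    with pytest.raises(ValueError):
        sim.transform("")   # no tokens -> zero vector


# --------------------------------------------------------------------------
# assembly

def test_tokenize_dialect():
    assert tokenize("Severe, ATAXIA-like (episodes)!") == \
        ["severe", "ataxia", "like", "episodes"]


def test_baseline_tier_has_exactly_four_features(small_cohort):
    pipe = u.FeaturePipeline("baseline").fit(small_cohort[:50])
    vec = pipe.transform(small_cohort[0])
    assert len(vec) == 4
    assert all(name.startswith("baseline:") for name in vec)


def test_feature_count_monotone_in_tier(small_cohort, corpus):
    train = small_cohort[:60]
    counts = []
    for tier in u.Tier:
        pipe = u.FeaturePipeline(tier, corpus=corpus).fit(train)
        counts.append(len(pipe.feature_names()))
    assert counts == sorted(counts)
    assert counts[0] == 4


def test_identical_applications_get_identical_vectors(small_cohort):
    pipe = u.FeaturePipeline("semantic_types").fit(small_cohort[:60])
    app = small_cohort[0]
    import dataclasses
    clone = dataclasses.replace(app)
    assert pipe.transform(app) == pipe.transform(clone)


def test_transform_matrix_agrees_with_transform(small_cohort, corpus):
    train = small_cohort[:60]
    eval_apps = small_cohort[60:70]
    pipe = u.FeaturePipeline("omim_similarity", corpus=corpus).fit(train)
    names = pipe.feature_names()
    mat = pipe.transform_matrix(eval_apps).toarray()
    for i, app in enumerate(eval_apps):
        dense = pipe.transform(app)
        expected = np.array([dense.get(n, 0.0) for n in names])
        np.testing.assert_allclose(mat[i], expected, atol=1e-12)


def test_all_feature_values_finite_and_binary_families_binary(small_cohort, corpus):
    pipe = u.FeaturePipeline("omim_similarity", corpus=corpus).fit(small_cohort[:60])
    vec = pipe.transform(small_cohort[70])
    assert all(np.isfinite(v) for v in vec.values())
    for name, v in vec.items():
        if name.startswith(("walley:", "semtype:")):
            assert v in (0.0, 1.0)


def test_no_training_set_leakage(small_cohort):
    """Transforming held-out data uses training statistics only: refitting
    TF-IDF on train+test changes the vectors."""
    train, test = small_cohort[:50], small_cohort[250:]
    pipe_train = u.FeaturePipeline("referral_letter").fit(train)
    pipe_leaky = u.FeaturePipeline("referral_letter").fit(list(train) + list(test))
    assert pipe_train.transform(test[0]) != pipe_leaky.transform(test[0])
    # and the clean pipeline's vocabulary is unchanged by what it transforms
    before = list(pipe_train.feature_names())
    pipe_train.transform(test[0])
    assert pipe_train.feature_names() == before


def test_missing_corpus_for_similarity_tier_errors(small_cohort):
    with pytest.raises(ValueError):
        u.FeaturePipeline("omim_similarity", corpus=None).fit(small_cohort[:30])
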