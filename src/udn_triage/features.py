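"""Feature models over referral letters and demographics.

Six cumulative tiers, each adding a feature family on top of the previous
one:

1. ``baseline`` — four min-max-normalized demographics (age at
   application, age at onset, disease duration, prior visits);
2. ``walley`` — binary presence of objective/subjective symptom terms;
3. ``referral_letter`` — TF-IDF-weighted bigrams of the letter text;
4. ``semantic_types`` — five binary features, one per broad semantic type
   (sign/symptom, procedure, disease/syndrome, body part, gene), set when
   any concept-lexicon term of that type occurs in the letter;
5. ``clinical_bert`` — the components of a document embedding of the
   letter (pluggable backend; the default is a deterministic
   feature-hashed bag of words, so no trained weights are required);
6. ``omim_similarity`` — one cosine-similarity feature per phenotype
   catalogue entry, between the letter embedding and the entry embedding.

All statistics (normalization bounds, TF-IDF vocabulary and document
frequencies, corpus-entry embeddings) are fitted on training data only;
transforming unseen text ignores out-of-vocabulary bigrams.  Feature names
are namespaced by tier so the union of families is collision-free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import IntEnum
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import HashingVectorizer, TfidfVectorizer

from .cohort import Application, PhenotypeEntry
from .lexicons import SEMANTIC_TYPES, load_concept_lexicon, load_symptom_lexicon

FeatureVector = dict[str, float]

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


class Tier(IntEnum):
    """Cumulative feature tiers, ordered; each includes all lower tiers."""

    BASELINE = 1
    WALLEY = 2
    REFERRAL_LETTER = 3
    SEMANTIC_TYPES = 4
    CLINICAL_BERT = 5
    OMIM_SIMILARITY = 6

    @classmethod
    def from_name(cls, name: "str | Tier") -> "Tier":
        if isinstance(name, Tier):
            return name
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(f"unknown tier {name!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


class NotFittedError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# tier 1: demographics

BASELINE_FIELDS = ("age_at_application", "age_at_onset", "duration", "prior_visits")


class BaselineNormalizer:
    """Min-max scaling of the four demographic features, fitted on the
    training split; values outside the training range are clipped."""

    def __init__(self) -> None:
        self.bounds_: dict[str, tuple[float, float]] | None = None

    def fit(self, apps: Sequence[Application]) -> "BaselineNormalizer":
        if not apps:
            raise ValueError("cannot fit normalizer on an empty training split")
        self.bounds_ = {
            f: (min(getattr(a, f) for a in apps), max(getattr(a, f) for a in apps))
            for f in BASELINE_FIELDS
        }
        return self

    def transform(self, app: Application) -> FeatureVector:
        if self.bounds_ is None:
            raise NotFittedError("normalizer is not fitted")
        out = {}
        for f in BASELINE_FIELDS:
            lo, hi = self.bounds_[f]
            v = min(max(getattr(app, f), lo), hi)
            out[f"baseline:{f}"] = (v - lo) / (hi - lo) if hi > lo else 0.0
        return out


def baseline_features(app: Application, normalizer: BaselineNormalizer) -> FeatureVector:
    return normalizer.transform(app)


# --------------------------------------------------------------------------
# term presence helpers

def _phrase_present(letter_tokens: Sequence[str], phrase: Sequence[str]) -> bool:
    if len(phrase) == 1:
        return phrase[0] in letter_tokens
    k = len(phrase)
    return any(tuple(letter_tokens[i:i + k]) == tuple(phrase)
               for i in range(len(letter_tokens) - k + 1))


def _present_terms(letter: str, terms: Sequence[str]) -> set[str]:
    tokens = tokenize(letter)
    token_set = set(tokens)
    hits = set()
    for term in terms:
        phrase = tokenize(term)
        if not phrase:
            continue
        if phrase[0] in token_set and _phrase_present(tokens, phrase):
            hits.add(term)
    return hits


# --------------------------------------------------------------------------
# tier 2: objective/subjective symptom list

def walley_features(letter: str, lexicon: Mapping[str, str]) -> FeatureVector:
    """Binary presence (1.0/0.0) of each symptom-lexicon term in the letter;
    case-insensitive whole-token phrase matching, presence not count."""
    if not lexicon:
        raise ValueError("symptom lexicon is empty")
    hits = _present_terms(letter, list(lexicon))
    return {f"walley:{t.replace(' ', '_')}": (1.0 if t in hits else 0.0) for t in sorted(lexicon)}


# --------------------------------------------------------------------------
# tier 3: TF-IDF bigrams

@dataclass
class TfidfModel:
    """Fitted bigram TF-IDF state.

    tf is the raw bigram count in the document, idf = ln((1+n)/(1+df)) + 1,
    and each document vector is L2-normalized; bigrams unseen at fit time
    are ignored at transform time.
    """

    vectorizer: TfidfVectorizer

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def feature_names(self) -> list[str]:
        return [f"tfidf:{b.replace(' ', '_')}"
                for b in self.vectorizer.get_feature_names_out()]


def fit_tfidf(corpus: Sequence[str]) -> TfidfModel:
    if not corpus:
        raise ValueError("cannot fit TF-IDF on an empty corpus")
    vec = TfidfVectorizer(
        tokenizer=tokenize, preprocessor=lambda x: x, token_pattern=None,
        ngram_range=(2, 2), norm="l2", smooth_idf=True, sublinear_tf=False,
    )
    vec.fit(corpus)
    return TfidfModel(vectorizer=vec)


def transform_tfidf(model: TfidfModel, letter: str) -> FeatureVector:
    row = model.vectorizer.transform([letter])
    names = model.feature_names
    return {names[j]: float(v) for j, v in zip(row.indices, row.data)}


# --------------------------------------------------------------------------
# tier 4: semantic types

def semantic_type_features(letter: str, lexicon: Mapping[str, str]) -> FeatureVector:
    """Five binary features: 1.0 iff any lexicon term of that semantic type
    occurs in the letter."""
    if not lexicon:
        raise ValueError("concept lexicon is empty")
    hits = _present_terms(letter, list(lexicon))
    present_types = {lexicon[t] for t in hits}
    return {f"semtype:{st}": (1.0 if st in present_types else 0.0) for st in SEMANTIC_TYPES}


# --------------------------------------------------------------------------
# tiers 5-6: embeddings and phenotype similarity

def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; raises on zero vectors or mismatched lengths."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class EmbeddingBackend:
    """A deterministic text -> vector map; same text must give the same
    vector.  Any callable backend (including a transformer encoder) can be
    wrapped; the package default needs no trained weights."""

    name: str
    dimension: int
    embed: Callable[[str], np.ndarray]

    def embed_many(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([np.asarray(self.embed(t), dtype=float).ravel() for t in texts])


def hashed_embedding(dimension: int = 512) -> EmbeddingBackend:
    """Default backend: signed feature-hashed unigram counts, L2-normalized.

    Fully deterministic across runs and machines, and respects token
    overlap: disjoint vocabularies map to (near-)orthogonal vectors up to
    hash collisions.
    """
    vec = HashingVectorizer(
        n_features=dimension, alternate_sign=True, norm="l2",
        tokenizer=tokenize, preprocessor=lambda x: x, token_pattern=None,
    )

    def embed(text: str) -> np.ndarray:
        return np.asarray(vec.transform([text]).todense()).ravel()

    return EmbeddingBackend(name="hashed-unigram", dimension=dimension, embed=embed)


def embedding_features(letter: str, backend: EmbeddingBackend) -> FeatureVector:
    vec = backend.embed(letter)
    return {f"embed:{j:04d}": float(v) for j, v in enumerate(vec)}


class PhenotypeSimilarity:
    """Per-entry cosine similarities against a phenotype corpus.

    Entry embeddings are computed once at fit time; each letter then yields
    one feature per corpus entry.
    """

    def __init__(self, backend: EmbeddingBackend) -> None:
        self.backend = backend
        self.entry_ids_: list[str] | None = None
        self._matrix: np.ndarray | None = None

    def fit(self, corpus: Sequence[PhenotypeEntry]) -> "PhenotypeSimilarity":
        if not corpus:
            raise ValueError("phenotype corpus is empty")
        self.entry_ids_ = [e.entry_id for e in corpus]
        mat = self.backend.embed_many([e.description for e in corpus])
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms == 0.0):
            raise ValueError("corpus entry produced a zero embedding")
        self._matrix = mat / norms[:, None]
        return self

    def transform(self, letter: str) -> FeatureVector:
        if self._matrix is None or self.entry_ids_ is None:
            raise NotFittedError("phenotype similarity is not fitted")
        v = np.asarray(self.backend.embed(letter), dtype=float).ravel()
        nv = np.linalg.norm(v)
        if nv == 0.0:
            raise ValueError("letter produced a zero embedding")
        sims = self._matrix @ (v / nv)
        return {f"omim:{eid}": float(s) for eid, s in zip(self.entry_ids_, sims)}


def omim_similarity_features(
    letter: str, corpus: Sequence[PhenotypeEntry], backend: EmbeddingBackend
) -> FeatureVector:
    return PhenotypeSimilarity(backend).fit(corpus).transform(letter)


# --------------------------------------------------------------------------
# assembly

class FeaturePipeline:
    """Fit/transform assembly of all feature families up to a tier.

    The fitted state (normalization bounds, TF-IDF vocabulary, entry
    embeddings) comes exclusively from the applications passed to
    :meth:`fit`; ``transform`` of any application uses only that state.
    """

    def __init__(
        self,
        tier: Tier | str,
        concept_lexicon: Mapping[str, str] | None = None,
        symptom_lexicon: Mapping[str, str] | None = None,
        backend: EmbeddingBackend | None = None,
        corpus: Sequence[PhenotypeEntry] | None = None,
    ) -> None:
        self.tier = Tier.from_name(tier)
        self.concept_lexicon = concept_lexicon or load_concept_lexicon()
        self.symptom_lexicon = symptom_lexicon or load_symptom_lexicon()
        self.backend = backend or hashed_embedding()
        self.corpus = list(corpus) if corpus is not None else None
        self.normalizer_: BaselineNormalizer | None = None
        self.tfidf_: TfidfModel | None = None
        self.similarity_: PhenotypeSimilarity | None = None

    def fit(self, apps: Sequence[Application]) -> "FeaturePipeline":
        self.normalizer_ = BaselineNormalizer().fit(apps)
        if self.tier >= Tier.REFERRAL_LETTER:
            self.tfidf_ = fit_tfidf([a.letter for a in apps])
        if self.tier >= Tier.OMIM_SIMILARITY:
            if not self.corpus:
                raise ValueError("omim_similarity tier requires a phenotype corpus")
            self.similarity_ = PhenotypeSimilarity(self.backend).fit(self.corpus)
        return self

    def _check_fitted(self) -> None:
        if self.normalizer_ is None:
            raise NotFittedError("feature pipeline is not fitted")

    def feature_names(self) -> list[str]:
        """Stable column ordering for matrix assembly."""
        self._check_fitted()
        names = [f"baseline:{f}" for f in BASELINE_FIELDS]
        if self.tier >= Tier.WALLEY:
            names += [f"walley:{t.replace(' ', '_')}" for t in sorted(self.symptom_lexicon)]
        if self.tier >= Tier.REFERRAL_LETTER:
            assert self.tfidf_ is not None
            names += self.tfidf_.feature_names
        if self.tier >= Tier.SEMANTIC_TYPES:
            names += [f"semtype:{st}" for st in SEMANTIC_TYPES]
        if self.tier >= Tier.CLINICAL_BERT:
            names += [f"embed:{j:04d}" for j in range(self.backend.dimension)]
        if self.tier >= Tier.OMIM_SIMILARITY:
            assert self.similarity_ is not None and self.similarity_.entry_ids_ is not None
            names += [f"omim:{eid}" for eid in self.similarity_.entry_ids_]
        return names

    def transform(self, app: Application) -> FeatureVector:
        self._check_fitted()
        assert self.normalizer_ is not None
        out = dict(self.normalizer_.transform(app))
        if self.tier >= Tier.WALLEY:
            out.update(walley_features(app.letter, self.symptom_lexicon))
        if self.tier >= Tier.REFERRAL_LETTER:
            assert self.tfidf_ is not None
            out.update(transform_tfidf(self.tfidf_, app.letter))
        if self.tier >= Tier.SEMANTIC_TYPES:
            out.update(semantic_type_features(app.letter, self.concept_lexicon))
        if self.tier >= Tier.CLINICAL_BERT:
            out.update(embedding_features(app.letter, self.backend))
        if self.tier >= Tier.OMIM_SIMILARITY:
            assert self.similarity_ is not None
            out.update(self.similarity_.transform(app.letter))
        return out

    def transform_matrix(self, apps: Sequence[Application]) -> sp.csr_matrix:
        """Sparse design matrix with columns aligned to :meth:`feature_names`.

        Equivalent to stacking :meth:`transform` outputs, but the text
        blocks are vectorized over all letters at once.
        """
        self._check_fitted()
        assert self.normalizer_ is not None
        letters = [a.letter for a in apps]
        blocks: list[sp.spmatrix | np.ndarray] = []
        base = np.array([[self.normalizer_.transform(a)[f"baseline:{f}"]
                          for f in BASELINE_FIELDS] for a in apps])
        blocks.append(sp.csr_matrix(base))
        if self.tier >= Tier.WALLEY:
            terms = sorted(self.symptom_lexicon)
            rows = np.array([[1.0 if t in hits else 0.0 for t in terms]
                             for hits in (_present_terms(l, terms) for l in letters)])
            blocks.append(sp.csr_matrix(rows))
        if self.tier >= Tier.REFERRAL_LETTER:
            assert self.tfidf_ is not None
            blocks.append(self.tfidf_.vectorizer.transform(letters))
        if self.tier >= Tier.SEMANTIC_TYPES:
            terms = list(self.concept_lexicon)
            rows = np.array([
                [1.0 if st in types else 0.0 for st in SEMANTIC_TYPES]
                for types in ({self.concept_lexicon[t] for t in _present_terms(l, terms)}
                              for l in letters)
            ])
            blocks.append(sp.csr_matrix(rows))
        if self.tier >= Tier.CLINICAL_BERT:
            blocks.append(sp.csr_matrix(self.backend.embed_many(letters)))
        if self.tier >= Tier.OMIM_SIMILARITY:
            assert self.similarity_ is not None and self.similarity_._matrix is not None
            emb = self.backend.embed_many(letters)
            norms = np.linalg.norm(emb, axis=1)
            if np.any(norms == 0.0):
                raise ValueError("letter produced a zero embedding")
            blocks.append(sp.csr_matrix((emb / norms[:, None]) @ self.similarity_._matrix.T))
        return sp.hstack(blocks, format="csr")


def assemble(app: Application, pipeline: FeaturePipeline) -> FeatureVector:
    """Feature vector for one application under a fitted pipeline."""
    return pipeline.transform(app)
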