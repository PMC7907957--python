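"""Synthetic application-cohort generator.

Real undiagnosed-disease application data are private, so every downstream
stage of the pipeline (feature extraction, classification, queue
simulation, cohort statistics) is exercised on synthetic cohorts whose
statistical structure mirrors the published cohort summary:

* ~50/50 admission balance over ``n_total`` applications;
* monthly arrival counts from a lognormal matched by moments to a
  configurable mean/SD of applications per month (default 55.0 / 19.7);
* class-conditional demographics: age at symptom onset and disease
  duration are drawn from moment-matched gamma distributions and age at
  application is their sum, which keeps onset <= age by construction and
  recovers all three configured means; prior visits come from a
  moment-matched distribution on small counts;
* class-conditional symptom-category frequencies;
* referral letters whose token distributions differ between classes by a
  controllable effect size ``class_effect`` in [0, 1] (0 = identical
  distributions, 1 = class-disjoint concept vocabulary);
* a recorded review day per application, placed so that the implied
  processing time reproduces the configured per-class mean/SD in months.

A small synthetic phenotype-description corpus (a stand-in for curated
phenotype entries) is generated by :func:`generate_phenotype_corpus`; each
entry is anchored to one symptom category so letters of that category are
nearer to matching entries under any token-overlap embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .lexicons import load_concept_lexicon, load_symptom_lexicon

#: days per month used for every day <-> month conversion in the package
MONTH_DAYS = 30.44

Label = Literal["accepted", "not_accepted"]
LABELS: tuple[Label, Label] = ("accepted", "not_accepted")

#: symptom categories of the published cohort summary, with the per-class
#: application counts used to build the default category distributions
SYMPTOM_CATEGORY_COUNTS: dict[str, tuple[int, int]] = {
    "neurologic": (575, 413),
    "musculoskeletal": (151, 117),
    "allergic": (59, 94),
    "gastroenterologic": (47, 92),
    "rheumatologic": (35, 91),
    "cardiologic": (54, 29),
    "endocrinologic": (27, 45),
    "pulmonologic": (26, 23),
    "hematologic": (22, 23),
    "infectious_disease": (2, 36),
    "dermatologic": (13, 15),
    "nephrologic": (18, 8),
    "ophthalmologic": (14, 8),
    "oncologic": (6, 10),
    "dental": (8, 6),
    "psychiatric": (5, 5),
    "urologic": (1, 6),
    "gynecologic": (2, 2),
    "toxicologic": (0, 5),
    "other": (115, 130),
    "na": (29, 54),
}

SYMPTOM_CATEGORIES = tuple(SYMPTOM_CATEGORY_COUNTS)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class Application:
    """One patient submission to the network."""

    id: str
    submission_day: int
    recorded_review_day: int | None
    label: Label
    age_at_application: float
    age_at_onset: float
    duration: float
    prior_visits: int
    symptom_category: str
    letter: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.submission_day < 0:
            raise ValueError("submission_day must be >= 0")
        if self.recorded_review_day is not None and self.recorded_review_day <= self.submission_day:
            raise ValueError("recorded_review_day must fall after submission_day")
        if self.age_at_onset > self.age_at_application + 1e-9:
            raise ValueError("age_at_onset cannot exceed age_at_application")
        if min(self.age_at_onset, self.duration, self.prior_visits) < 0:
            raise ValueError("demographic fields must be non-negative")


@dataclass(frozen=True)
class PhenotypeEntry:
    """A phenotype-catalogue entry: an id and a free-text description."""

    entry_id: str
    description: str

    def __post_init__(self) -> None:
        if not self.description.strip():
            raise ValueError("description must be non-empty")


@dataclass(frozen=True)
class GroupDemographics:
    """Per-class demographic marginals (means and SDs on the natural scale).

    Age at application is not sampled directly: it is the sum of age at
    onset and disease duration, so its configured mean is implied as
    ``onset_mean + duration_mean``.  ``processing_mean/sd`` (months)
    control the recorded review day used by the historical-order heuristic.
    """

    onset_mean: float
    onset_sd: float
    duration_mean: float
    duration_sd: float
    visits_mean: float
    visits_sd: float
    processing_mean: float
    processing_sd: float

    @property
    def age_mean(self) -> float:
        return self.onset_mean + self.duration_mean


@dataclass(frozen=True)
class LetterParams:
    """Shape of the synthetic referral letters.

    Letters are bags of token emissions from a four-part mixture: a shared
    background vocabulary, a symptom-category vocabulary, concept-lexicon
    terms, and objective/subjective symptom terms.  ``class_effect`` tilts
    the concept and symptom components between classes: each concept term
    carries a fixed +-1 lean and objective (subjective) symptom terms lean
    toward the accepted (not-accepted) class, with emission weight
    ``1 +- class_effect * lean``.
    """

    background_vocab_size: int = 300
    category_vocab_size: int = 25
    mean_length: float = 120.0
    class_effect: float = 0.5
    mix_background: float = 0.50
    mix_category: float = 0.20
    mix_concept: float = 0.20
    mix_symptom: float = 0.10

    def validate(self) -> None:
        if self.background_vocab_size < 1 or self.category_vocab_size < 1:
            raise ConfigurationError("vocabulary sizes must be >= 1")
        if self.mean_length <= 0:
            raise ConfigurationError("mean_length must be positive")
        if not 0.0 <= self.class_effect <= 1.0:
            raise ConfigurationError("class_effect must lie in [0, 1]")
        mix = (self.mix_background, self.mix_category, self.mix_concept, self.mix_symptom)
        if min(mix) < 0 or not math.isclose(sum(mix), 1.0, abs_tol=1e-9):
            raise ConfigurationError("mixture weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class CohortConfig:
    n_total: int
    accepted_fraction: float = 0.5
    arrival_rate_mean: float = 55.0
    arrival_rate_sd: float = 19.7
    demographics: Mapping[Label, GroupDemographics] = field(default_factory=dict)
    symptom_probs: Mapping[Label, Mapping[str, float]] = field(default_factory=dict)
    letter_params: LetterParams = field(default_factory=LetterParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_total < 1:
            raise ConfigurationError("n_total must be positive")
        if not 0.0 < self.accepted_fraction < 1.0:
            raise ConfigurationError("accepted_fraction must lie in (0, 1)")
        if self.arrival_rate_mean <= 0 or self.arrival_rate_sd < 0:
            raise ConfigurationError("arrival rate mean must be positive, SD non-negative")
        for label in LABELS:
            if label not in self.demographics:
                raise ConfigurationError(f"demographics missing for class {label!r}")
            d = self.demographics[label]
            if min(d.onset_sd, d.duration_sd, d.visits_sd, d.processing_sd) < 0:
                raise ConfigurationError("SDs must be non-negative")
            if min(d.onset_mean, d.duration_mean, d.visits_mean) < 0 or d.processing_mean <= 0:
                raise ConfigurationError("demographic means must be non-negative")
            probs = self.symptom_probs.get(label)
            if not probs:
                raise ConfigurationError(f"symptom_probs missing for class {label!r}")
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError("symptom_probs must be a distribution summing to 1")
        self.letter_params.validate()


def default_config(
    n_total: int = 2421,
    class_effect: float = 0.5,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """Cohort configuration matching the published cohort summary.

    Onset/duration/visit and processing-time marginals, symptom-category
    frequencies, arrival rate and the near-even class balance all follow
    the reported accepted vs not-accepted summary statistics.
    """
    demographics = {
        "accepted": GroupDemographics(
            onset_mean=10.8, onset_sd=16.9,
            duration_mean=8.89, duration_sd=9.55,
            visits_mean=0.49, visits_sd=0.56,
            processing_mean=3.29, processing_sd=3.17,
        ),
        "not_accepted": GroupDemographics(
            onset_mean=28.4, onset_sd=20.1,
            duration_mean=8.12, duration_sd=9.58,
            visits_mean=0.30, visits_sd=0.68,
            processing_mean=4.73, processing_sd=4.85,
        ),
    }
    symptom_probs = {
        label: {
            cat: counts[i] / sum(c[i] for c in SYMPTOM_CATEGORY_COUNTS.values())
            for cat, counts in SYMPTOM_CATEGORY_COUNTS.items()
        }
        for i, label in enumerate(LABELS)
    }
    cfg = CohortConfig(
        n_total=n_total,
        demographics=demographics,
        symptom_probs=symptom_probs,
        letter_params=LetterParams(class_effect=class_effect),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_config(n_total: int = 600, seed: int = 0) -> CohortConfig:
    """A no-signal configuration: identical class-conditional distributions.

    Used for null calibration checks — any classifier trained on such a
    cohort should score at chance.
    """
    base = default_config(n_total=n_total, class_effect=0.0, seed=seed)
    return replace(
        base,
        demographics={label: base.demographics["accepted"] for label in LABELS},
        symptom_probs={label: base.symptom_probs["accepted"] for label in LABELS},
    )


# --------------------------------------------------------------------------
# moment-matched samplers

def _gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape/scale of the gamma with the given mean and SD."""
    if mean <= 0:
        raise ConfigurationError("gamma-matched mean must be positive")
    if sd <= 0:
        return math.inf, 0.0  # degenerate: point mass handled by caller
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def _sample_nonneg(mean: float, sd: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Non-negative continuous draws with exactly the requested moments."""
    if sd == 0 or mean == 0:
        return np.full(size, mean)
    shape, scale = _gamma_moments(mean, sd)
    return rng.gamma(shape, scale, size=size)


def _count_distribution(mean: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of a small-count distribution matching
    the requested mean and SD exactly (three-point support {0, 1, k})."""
    if mean < 0:
        raise ConfigurationError("count mean must be non-negative")
    if mean == 0:
        return np.array([0]), np.array([1.0])
    ex2 = sd * sd + mean * mean
    k = max(2, math.ceil(ex2 / mean))
    pk = (ex2 - mean) / (k * k - k)
    p1 = mean - k * pk
    p0 = 1.0 - p1 - pk
    if min(p0, p1, pk) < -1e-12:
        raise ConfigurationError(
            f"no count distribution on {{0,1,{k}}} matches mean={mean}, sd={sd}"
        )
    probs = np.clip([p0, p1, pk], 0.0, None)
    return np.array([0, 1, k]), probs / probs.sum()


# --------------------------------------------------------------------------
# letter model

def _category_vocab(category: str, size: int) -> list[str]:
    slug = "".join(ch for ch in category if ch.isalnum())
    return [f"{slug}finding{j}" for j in range(size)]


def _background_vocab(size: int) -> list[str]:
    return [f"word{j:04d}" for j in range(size)]


class LetterModel:
    """Per-(class, category) emission distributions over letter tokens.

    Emissions are whole lexicon terms (possibly multi-word, emitted as
    consecutive tokens) or single background/category words; the per-class
    tilt applied to concept and symptom terms is the only way the letter
    distribution depends on the admission label.
    """

    def __init__(
        self,
        params: LetterParams,
        concept_lexicon: Mapping[str, str] | None = None,
        symptom_lexicon: Mapping[str, str] | None = None,
        categories: Sequence[str] = SYMPTOM_CATEGORIES,
    ):
        params.validate()
        self.params = params
        concept = concept_lexicon or load_concept_lexicon()
        symptom = symptom_lexicon or load_symptom_lexicon()
        if not concept or not symptom:
            raise ConfigurationError("lexicons must be non-empty")
        self.categories = tuple(categories)
        background = _background_vocab(params.background_vocab_size)

        # fixed +-1 lean per concept term: alternate within each semantic
        # type so every type carries signal for both classes
        concept_terms = sorted(concept)
        by_type: dict[str, int] = {}
        concept_lean = {}
        for term in concept_terms:
            idx = by_type.setdefault(concept[term], 0)
            concept_lean[term] = 1.0 if idx % 2 == 0 else -1.0
            by_type[concept[term]] = idx + 1
        symptom_terms = sorted(symptom)
        symptom_lean = {t: (1.0 if symptom[t] == "objective" else -1.0) for t in symptom_terms}

        e = params.class_effect
        self._tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for category in self.categories:
            cat_vocab = _category_vocab(category, params.category_vocab_size)
            for label in LABELS:
                sign = 1.0 if label == "accepted" else -1.0
                emissions: list[str] = []
                weights: list[float] = []
                for voc, mix in ((background, params.mix_background),
                                 (cat_vocab, params.mix_category)):
                    emissions.extend(voc)
                    weights.extend([mix / len(voc)] * len(voc))
                for terms, lean, mix in (
                    (concept_terms, concept_lean, params.mix_concept),
                    (symptom_terms, symptom_lean, params.mix_symptom),
                ):
                    tilts = np.array([1.0 + sign * e * lean[t] for t in terms])
                    tilts = tilts / tilts.sum() * mix
                    emissions.extend(terms)
                    weights.extend(tilts.tolist())
                probs = np.asarray(weights)
                self._tables[(label, category)] = (np.asarray(emissions, dtype=object),
                                                   probs / probs.sum())

    def sample(self, label: Label, category: str, rng: np.random.Generator) -> str:
        emissions, probs = self._tables[(label, category)]
        n = max(1, rng.poisson(self.params.mean_length))
        idx = rng.choice(len(emissions), size=n, p=probs)
        return " ".join(emissions[i] for i in idx)


def generate_letter(
    label: Label,
    symptom_category: str,
    letter_params: LetterParams,
    rng: np.random.Generator,
    *,
    model: LetterModel | None = None,
) -> str:
    """Draw one referral letter; a prebuilt :class:`LetterModel` may be
    passed to amortize the emission-table construction across letters."""
    model = model or LetterModel(letter_params)
    return model.sample(label, symptom_category, rng)


# --------------------------------------------------------------------------
# cohort generation

def _submission_days(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Integer day indices with lognormal monthly counts, uniform placement."""
    if sd == 0:
        sigma2 = 0.0
    else:
        sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    days: list[np.ndarray] = []
    total = 0
    month = 0
    while total < n:
        count = int(round(rng.lognormal(mu, math.sqrt(sigma2))))
        count = min(count, n - total) if total + count > n else count
        if count > 0:
            start = month * MONTH_DAYS
            days.append(np.floor(start + rng.uniform(0.0, MONTH_DAYS, size=count)).astype(int))
            total += count
        month += 1
    return np.sort(np.concatenate(days))


def generate_cohort(config: CohortConfig) -> list[Application]:
    """Generate a full application cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total

    days = _submission_days(n, config.arrival_rate_mean, config.arrival_rate_sd, rng)
    labels = np.where(rng.random(n) < config.accepted_fraction, "accepted", "not_accepted")
    letter_model = LetterModel(config.letter_params)

    # class-conditional draws, assembled back in submission order
    per_label: dict[str, dict[str, np.ndarray]] = {}
    for label in LABELS:
        m = int(np.sum(labels == label))
        demo = config.demographics[label]
        onset = _sample_nonneg(demo.onset_mean, demo.onset_sd, m, rng)
        duration = _sample_nonneg(demo.duration_mean, demo.duration_sd, m, rng)
        support, probs = _count_distribution(demo.visits_mean, demo.visits_sd)
        visits = rng.choice(support, size=m, p=probs)
        proc_months = _sample_nonneg(demo.processing_mean, demo.processing_sd, m, rng)
        cats = list(config.symptom_probs[label])
        cat_probs = np.array([config.symptom_probs[label][c] for c in cats])
        cat_idx = rng.choice(len(cats), size=m, p=cat_probs)
        per_label[label] = {
            "onset": onset, "duration": duration, "visits": visits,
            "proc": proc_months, "cats": np.array(cats, dtype=object)[cat_idx],
        }

    apps: list[Application] = []
    cursor = {label: 0 for label in LABELS}
    width = max(6, len(str(n)))
    for i in range(n):
        label = labels[i]
        j = cursor[label]
        cursor[label] += 1
        draws = per_label[label]
        onset = float(draws["onset"][j])
        duration = float(draws["duration"][j])
        review_day = int(days[i]) + max(1, int(round(draws["proc"][j] * MONTH_DAYS)))
        category = str(draws["cats"][j])
        apps.append(Application(
            id=f"APP-{i + 1:0{width}d}",
            submission_day=int(days[i]),
            recorded_review_day=review_day,
            label=label,
            age_at_application=onset + duration,
            age_at_onset=onset,
            duration=duration,
            prior_visits=int(draws["visits"][j]),
            symptom_category=category,
            letter=letter_model.sample(label, category, rng),
        ))
    return apps


def generate_phenotype_corpus(
    n_entries: int,
    letter_params: LetterParams,
    rng: np.random.Generator,
    *,
    categories: Sequence[str] = SYMPTOM_CATEGORIES,
    mean_length: float = 40.0,
) -> list[PhenotypeEntry]:
    """Synthetic phenotype-description corpus.

    Entry ``i`` is anchored to symptom category ``i mod len(categories)``:
    70% of its tokens come from that category's vocabulary and the rest
    from the shared background vocabulary, so letters of a category share
    more tokens with matching entries than with others.
    """
    if n_entries < 1:
        raise ConfigurationError("n_entries must be >= 1")
    letter_params.validate()
    background = _background_vocab(letter_params.background_vocab_size)
    entries = []
    for i in range(n_entries):
        category = categories[i % len(categories)]
        cat_vocab = _category_vocab(category, letter_params.category_vocab_size)
        n = max(3, rng.poisson(mean_length))
        tokens = [
            cat_vocab[rng.integers(len(cat_vocab))] if rng.random() < 0.7
            else background[rng.integers(len(background))]
            for _ in range(n)
        ]
        entries.append(PhenotypeEntry(entry_id=f"PHE-{i + 1:06d}", description=" ".join(tokens)))
    return entries


def entry_category(entry: PhenotypeEntry,
                   categories: Sequence[str] = SYMPTOM_CATEGORIES) -> str:
    """Anchor category of a synthetic corpus entry (by its index)."""
    return categories[(int(entry.entry_id.split("-")[1]) - 1) % len(categories)]
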