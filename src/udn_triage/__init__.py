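"""udn_triage: admission-outcome prediction and review-queue
prioritization for undiagnosed-disease application cohorts.

The package generates synthetic application cohorts with a configurable
class signal, builds six cumulative feature models over referral-letter
text and demographics, trains a linear logistic classifier, and simulates
capacity-constrained review sessions under four ranking heuristics to
quantify processing-time gains.
"""

from .cohort import (
    MONTH_DAYS,
    Application,
    CohortConfig,
    ConfigurationError,
    GroupDemographics,
    LetterParams,
    PhenotypeEntry,
    default_config,
    generate_cohort,
    generate_letter,
    generate_phenotype_corpus,
    null_config,
)
from .features import (
    EmbeddingBackend,
    FeaturePipeline,
    Tier,
    baseline_features,
    cosine,
    fit_tfidf,
    hashed_embedding,
    omim_similarity_features,
    semantic_type_features,
    transform_tfidf,
    walley_features,
)
from .lexicons import load_concept_lexicon, load_symptom_lexicon
from .model import (
    MetricsReport,
    SplitSpec,
    TrainedModel,
    auroc,
    balanced_accuracy,
    compare_models,
    decision_score,
    evaluate,
    stratified_split,
    train,
)
from .pipeline import RunConfig, run_pipeline
from .queueing import (
    Heuristic,
    Schedule,
    SimResult,
    crossval_scores,
    percent_reduction,
    priority,
    simulate_queue,
    sweep,
)
from .stats import (
    ContingencyTable2x2,
    GroupSummary,
    bonferroni,
    chi2_2x2,
    summarize_cohort,
    welch_t,
)

__version__ = "0.1.0"
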