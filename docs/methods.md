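# Methods

## Problem setting

Applications to an undiagnosed-diseases program arrive continuously and
are decided in periodic committee sessions of limited capacity. Each
application carries demographics (age at application, age at symptom
onset, disease duration, prior program visits), a symptom category, a
free-text referral letter, a submission day, and — retrospectively — the
committee's accept/not-accept label and the historical review day. The
package (a) trains a classifier to predict the label from the application
materials, and (b) simulates how ranking the review queue by classifier
confidence changes processing time (submission to review) for accepted
and not-accepted applications.

## Synthetic cohort generator

Real application data are private, so all empirical claims in this
repository are about synthetic cohorts built to match published summary
statistics. The generator is deterministic given `CohortConfig.seed`.

**Arrivals.** Monthly application counts are lognormal, matched by
moments to a configurable mean/SD (default 55.0/19.7 per month), with
days placed uniformly within each 30.44-day month. One month = 30.44 days
everywhere in the package.

**Labels.** Bernoulli with `accepted_fraction` (default 0.5, matching a
near-even historical split).

**Demographics.** Age at onset and disease duration are drawn per class
from gamma distributions moment-matched to the configured mean/SD, and
age at application is their sum. Two deliberate choices here:

* *Gamma rather than zero-truncated normal.* Truncating a normal at zero
  shifts its mean (for mean 19.7, SD 18.7 the shift is ≈ +5 years), and
  no zero-truncated normal attains SD > mean at all — yet the reference
  marginals for onset (10.8/16.9) and duration (8.89/9.55) have exactly
  that shape. The gamma family matches any positive (mean, SD) pair
  exactly, so configured means and SDs are recovered to sampling error.
* *Composition instead of rejection.* Sampling age and duration
  independently and resampling until onset = age − duration is
  non-negative would bias both marginals. Composing age = onset +
  duration keeps onset ≤ age by construction and recovers all three
  means exactly; the implied age SD (√(sd_onset² + sd_dur²) ≈ 19.4 /
  22.3 years per class) is accepted as slightly wider than the reference
  18.7 / 21.1 — the cost of exact means and coherent ages.

Prior-visit counts use a three-point distribution on {0, 1, k} solved to
match the configured mean/SD exactly (the reference values, e.g.
0.49/0.56, are underdispersed relative to both truncated-normal and
negative-binomial families). Historical review days place each
application's processing time at a gamma moment-matched to the per-class
reference values (3.29/3.17 and 4.73/4.85 months), so the `udn_order`
heuristic reproduces those distributions.

**Letters.** A letter is a bag of token emissions from a four-part
mixture: shared background vocabulary (weight 0.50), symptom-category
vocabulary (0.20), concept-lexicon terms (0.20), and objective/subjective
symptom terms (0.10); length is Poisson with mean 120 tokens. The only
label dependence is a tilt on the last two components: each concept term
carries a fixed ±1 lean (alternating within each semantic type) and
objective (subjective) symptom terms lean accepted (not-accepted); the
emission weight is 1 ± class_effect·lean. At `class_effect = 0` letters
are label-independent; at 1 the concept vocabularies of the two classes
are disjoint. Defaults (vocabulary sizes 300 background / 25 per
category, mean length 120, class_effect 0.5) are stand-ins chosen to give
a moderately separable, realistic-looking signal; nothing in the
reference material constrains them.

**Phenotype corpus.** Synthetic stand-in for a curated phenotype
catalogue: entry *i* anchors to symptom category *i* mod 21, drawing 70%
of its tokens from that category's vocabulary, so letters are nearer (in
any token-overlap embedding) to matching entries.

**What the generator does not emulate.** Real clinical language (negation,
abbreviations, narrative structure), correlations between demographics
and letter content beyond the symptom category, site effects, drift over
time, and label noise. Passing tests therefore demonstrate that the
pipeline's machinery is correct and well calibrated, not that real
referral letters are this separable — synthetic AUROCs (≈0.99 at
class_effect 0.5) exceed what heterogeneous clinical text yields.

## Features and classifier

Tokenization is lowercase splitting on non-alphanumerics — the simplest
reproducible dialect. TF-IDF uses raw bigram counts, smoothed idf
ln((1+n)/(1+df)) + 1 and L2 normalization (the de-facto standard
formulation). "Normalized" demographics are min-max scaled by
training-split bounds with clipping (bounded and leakage-safe). Concept
and symptom matching is exact whole-token phrase lookup against shipped
~100-term / 40-term lexicons (replaceable via 2-column TSV); this
preserves presence/absence semantics without licensed terminology
resources. The embedding backend is an injection point; the default is
signed feature hashing of unigram counts (dimension 512, L2-normalized),
chosen because it is deterministic bit-for-bit across runs and respects
token overlap. A transformer encoder can be plugged in but is never
required.

All fitted state comes from the training split only; transforming unseen
text ignores out-of-vocabulary bigrams. Within a cross-validation fold,
feature components are refit on that fold's training portion.

The classifier is L2-regularized logistic regression (liblinear). The
grid is C ∈ {10⁻³ … 10³} × class weight {balanced, none}, selected by
validation AUROC with ties broken toward stronger regularization. The
classification threshold is a signed distance of 0 (probability 0.5) —
the canonical default absent a stated operating point; `evaluate` accepts
any other threshold. AUROC is computed by the rank (Mann–Whitney)
formula with ties counted one half. Tier comparisons use a two-sided
Wilcoxon signed-rank test on per-fold AUROCs from repeated stratified
cross-validation (default 10×5) with folds shared between tiers; an
all-tied comparison is reported as p = 1.

## Queue simulation

Sessions occur on days d, 2d, 3d, …; an application is eligible at the
first session strictly after its submission day; each session reviews the
`budget_a` highest-priority eligible applications. Priorities are
lexicographic keys — FIFO (submission day, id); classifier (−score,
submission day, id); accept-first (label ≠ accepted, submission day, id);
historical order replays recorded review days and bypasses the session
mechanics. Ties everywhere resolve by submission day then id, so replays
are deterministic. The simulator is streaming: an application submitted
after a session cannot occupy a slot in it; a purely static ranking is
the special case where all submissions precede the first session.

The (d, a) sweep evaluates the full factorial grid (defaults d ∈ {3, 6,
9, 12, 15, 30}, a ∈ {5, 10, 15, 20, 26, 30, 40}) and reports the cell
minimizing the gap between the classifier's and accept-first's
accepted-group means (ties toward smaller a, then smaller d). The
contended reference condition used in tests and the acceptance study is
d = 14, a = 20: biweekly sessions with a budget below the ≈27 arrivals
per period implied by the 55/month arrival rate.

## Cohort statistics

Group comparisons use the unequal-variance (Welch) t test — from raw
values or directly from (mean, SD, n) summaries — with
Welch–Satterthwaite degrees of freedom; it reproduces the published t
statistics for age at application (−20.7), minimum duration (2.0) and
processing time (−8.6) from the printed summaries. Symptom categories
use Pearson 2×2 χ² (optional Yates correction) with Bonferroni adjustment
over the number of tested categories. Published χ² values for the
flagged symptom rows are not reproducible from the printed counts alone
(plausibly due to excluded missing-data rows) and are deliberately not
asserted; the formula is regression-pinned on those counts instead.

## Numerical and scale choices

* Degenerate inputs raise explicit errors: zero vectors in cosine
  similarity, unfitted components, single-class evaluation sets, zero
  χ² margins, both-variances-zero t tests, empty schedules.
* Sample SDs use ddof = 1 and are reported as absent for groups of one.
* Largest-remainder rounding allocates stratified split sizes (2421
  applications at 0.8/0.1/0.1 → 1937/242/242).
* Study sizes in the test suite and acceptance script — 5000 applications
  for marginal recovery, 1200 + 288 for the retrospective/prospective
  study, 20 × 500 for dominance checks — are the package's desk-scale
  defaults; all scale linearly if larger cohorts are wanted.

## Known limitations

Synthetic separability overstates real-world performance; the letter
model has no syntax, so sequence-aware embeddings degenerate to
bag-of-words signal; the simulator models neither reviewer assignment,
withdrawal, nor fairness constraints — the accept-first ranking in
particular is an analytic lower bound, not a deployable policy, because
it maximally delays exactly the patients who will be refused.
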