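# udn-triage

Admission-outcome prediction and review-queue prioritization for
undiagnosed-disease application cohorts.

Networks that evaluate patients with undiagnosed conditions (such as the
US Undiagnosed Diseases Network, UDN) receive a steady stream of
applications — an application form with demographics plus a free-text
referral letter — that an expert committee reviews in periodic sessions
with limited capacity. This package implements, end to end and on
synthetic data, the analysis workflow for asking two questions:

1. **Can a classifier reproduce the committee's accept/not-accept
   decision from the application materials alone?**
2. **If applications are ranked by predicted likelihood of acceptance,
   how much shorter does the wait become for the patients who will be
   accepted?**

Because real application data are private, the package ships a tested
synthetic-cohort generator whose marginals (arrival rate, class-conditional
demographics, symptom-category frequencies, processing times) are
configured from published cohort summary statistics, with a single
`class_effect` dial in [0, 1] controlling how strongly the referral-letter
token distributions separate the classes.

## The model

An L2-regularized logistic regression with a linear decision boundary is
trained on six cumulative feature tiers:

| tier | adds |
|---|---|
| `baseline` | 4 min-max-normalized demographics (age at application, age at onset, duration, prior visits) |
| `walley` | binary presence of objective/subjective symptom terms |
| `referral_letter` | TF-IDF-weighted letter bigrams (tf·(ln((1+n)/(1+df))+1), L2-normalized) |
| `semantic_types` | 5 binary concept-dictionary features (sign/symptom, procedure, disease/syndrome, body part, gene) |
| `clinical_bert` | components of a document embedding (pluggable backend; default is deterministic signed feature hashing, dim 512) |
| `omim_similarity` | cosine similarity of the letter embedding to each entry of a phenotype-description corpus |

The ranking score is the signed distance to the separating hyperplane,
s(x) = (w·x + b)/‖w‖, computed out-of-fold by stratified 5-fold
cross-validation so every application is scored by a model that never saw
it. A discrete-event simulator then replays review sessions held every
*d* days with a budget of *a* applications per session under four
heuristics — FIFO, the historical order, classifier ranking, and the
oracle accept-first ranking — and reports mean (SD) processing time
(months from submission to review) by admission label.

## Worked example

```python
import udn_triage as u

apps = u.generate_cohort(u.default_config(n_total=1200, class_effect=0.5, seed=1))
train, val, test = u.stratified_split(apps, u.SplitSpec(seed=1))
model = u.train(train, val, "semantic_types")
report = u.evaluate(model, test)
print(f"semantic types: sensitivity={report.sensitivity:.3f} "
      f"specificity={report.specificity:.3f} "
      f"balanced accuracy={report.balanced_accuracy:.3f} AUROC={report.auroc:.3f}")

scores = u.crossval_scores(apps, "semantic_types", k=5, seed=1)
schedule = u.Schedule(period_d=14, budget_a=20)
for h in ("fifo", "udn_order", "classifier", "accept_first"):
    res = u.simulate_queue(apps, h, schedule, scores)
    print(f"{h:>13}: accepted {res.mean_months('accepted'):.2f} "
          f"({res.sd_months('accepted'):.2f}) months")
```

prints

```
semantic types: sensitivity=0.918 specificity=1.000 balanced accuracy=0.959 AUROC=0.992
         fifo: accepted 2.07 (0.94) months
    udn_order: accepted 3.20 (2.85) months
   classifier: accepted 0.27 (0.22) months
 accept_first: accepted 0.25 (0.14) months
```

Reading the output: on this synthetic cohort the semantic-types tier
separates the classes almost perfectly (AUROC 0.992 — synthetic letters
are easier than real clinical text), and under biweekly sessions of 20
reviews the classifier ranking cuts the accepted group's mean wait from
2.07 months (FIFO) or 3.20 months (the historical processing order) to
0.27 months, nearly matching the 0.25-month lower bound of the oracle
accept-first ranking. The price is a longer wait for not-accepted
applications, which is why the heuristic choice is an ethics question as
much as an optimization.

The same workflow is available from the shell:

```bash
udn-triage pipeline --n 1200 --seed 1 --out-dir run1
udn-triage simulate-queue --in run1/applications.jsonl --heuristic classifier \
    -d 14 -a 20 --scores run1/confidence_scores.csv
```

Cohort-comparison statistics (Welch t from group summaries, 2×2 χ² with
Bonferroni adjustment) are in `udn_triage.stats`:

```python
t, df, p = u.welch_t(u.GroupSummary(19.7, 18.7, 1209), u.GroupSummary(36.5, 21.1, 1212))
# t = -20.7, p = 6.2e-88
```

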