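"""End-to-end analysis pipeline.

One call runs the whole study design on synthetic data: generate a cohort
and a phenotype corpus, split it, train and evaluate the classifier at a
feature tier (retrospective), score a later-generated held-out batch with
the frozen model (prospective), compute out-of-fold confidence scores,
simulate the review queue under all four heuristics, sweep the (d, a)
schedule grid, and summarize the cohort.  Every artifact is written under
an output directory and recorded in a manifest stamped with the seed and a
hash of the configuration, so a rerun with the same configuration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as udn_io
from .cohort import default_config, generate_cohort, generate_phenotype_corpus
from .features import FeaturePipeline, Tier, hashed_embedding
from .model import SplitSpec, evaluate, stratified_split, train
from .queueing import Heuristic, Schedule, crossval_scores, percent_reduction, simulate_queue, sweep
from .stats import format_summary, summarize_cohort

log = logging.getLogger("udn_triage")

#: default schedule grid for the (d, a) sweep
DEFAULT_D_VALUES = (3, 6, 9, 12, 15, 30)
DEFAULT_A_VALUES = (5, 10, 15, 20, 26, 30, 40)


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "udn_run"
    n_total: int = 2421
    n_prospective: int = 288
    class_effect: float = 0.5
    tier: str = "semantic_types"
    n_corpus_entries: int = 200
    schedule_d: int = 14
    schedule_a: int = 20
    sweep_d_values: tuple[int, ...] = DEFAULT_D_VALUES
    sweep_a_values: tuple[int, ...] = DEFAULT_A_VALUES
    seed: int = 0

    def config_hash(self) -> str:
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the artifact manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "config": dataclasses.asdict(config), "artifacts": {}, "timings_s": {}}

    def record(name: str, path: Path, started: float) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
        manifest["timings_s"][name] = round(time.time() - started, 3)

    tier = Tier.from_name(config.tier)
    rng = np.random.default_rng(config.seed)

    # --- synthetic data
    t = time.time()
    cohort_cfg = default_config(n_total=config.n_total, class_effect=config.class_effect,
                                seed=config.seed)
    apps = generate_cohort(cohort_cfg)
    path = out / "applications.jsonl"
    udn_io.write_applications(apps, path)
    record("applications", path, t)

    t = time.time()
    corpus = generate_phenotype_corpus(config.n_corpus_entries, cohort_cfg.letter_params,
                                       np.random.default_rng(config.seed + 1))
    path = out / "phenotype_corpus.jsonl"
    udn_io.write_corpus(corpus, path)
    record("corpus", path, t)

    backend = hashed_embedding()
    pipeline_kwargs = {"backend": backend, "corpus": corpus}

    # --- retrospective: split, train with validation grid search, test
    t = time.time()
    train_set, val_set, test_set = stratified_split(apps, SplitSpec(seed=config.seed))
    model = train(train_set, val_set, tier, **pipeline_kwargs)
    path = out / "model.json"
    model.save(path)
    record("model", path, t)

    t = time.time()
    retro = evaluate(model, test_set)
    path = out / "metrics_retrospective.json"
    udn_io.write_json(retro.to_dict(), path)
    record("metrics_retrospective", path, t)
    log.info("retrospective %s: AUROC %.3f", tier.label, retro.auroc)

    # --- prospective: a later batch scored by the frozen model
    t = time.time()
    pros_cfg = default_config(n_total=config.n_prospective, class_effect=config.class_effect,
                              seed=config.seed + 1000)
    pros_apps = generate_cohort(pros_cfg)
    pros = evaluate(model, pros_apps)
    path = out / "metrics_prospective.json"
    udn_io.write_json({"model_hash": model.feature_state_hash(), **pros.to_dict()}, path)
    record("metrics_prospective", path, t)

    # --- ranking: out-of-fold scores, queue simulation, sweep
    t = time.time()
    scores = crossval_scores(apps, tier, k=5, seed=config.seed, **pipeline_kwargs)
    path = out / "confidence_scores.csv"
    udn_io.write_scores(scores, path)
    record("confidence_scores", path, t)

    t = time.time()
    schedule = Schedule(period_d=config.schedule_d, budget_a=config.schedule_a)
    queue_summary = {}
    for h in Heuristic:
        res = simulate_queue(apps, h, schedule, scores)
        queue_summary[h.value] = res.summary()
    fifo_mean = queue_summary["fifo"]["accepted"]["mean_months"]
    clf_mean = queue_summary["classifier"]["accepted"]["mean_months"]
    queue_summary["percent_reduction_accepted_classifier_vs_fifo"] = percent_reduction(
        fifo_mean, clf_mean)
    path = out / "queue_times.json"
    udn_io.write_json(queue_summary, path)
    record("queue_times", path, t)

    t = time.time()
    grid, best = sweep(apps, list(Heuristic), config.sweep_d_values, config.sweep_a_values,
                       scores)
    path = out / "sweep.csv"
    grid.to_csv(path, index=False)
    record("sweep", path, t)
    manifest["sweep_best_cell"] = best

    # --- cohort statistics
    t = time.time()
    report = summarize_cohort(apps)
    path = out / "cohort_summary.json"
    udn_io.write_json(report, path)
    (out / "cohort_summary.txt").write_text(format_summary(report) + "\n")
    record("cohort_summary", path, t)

    manifest["total_s"] = round(time.time() - t0, 3)
    manifest_path = out / "manifest.json"
    udn_io.write_json(manifest, manifest_path)
    return manifest
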