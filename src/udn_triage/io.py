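"""Serialization of applications, phenotype corpora, confidence scores
and metric reports.

Applications round-trip through JSONL (one object per line) or CSV with a
fixed column schema; dates are integer day indices and all text is UTF-8.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from .cohort import Application, PhenotypeEntry

APPLICATION_FIELDS = (
    "id", "submission_day", "recorded_review_day", "label",
    "age_at_application", "age_at_onset", "duration", "prior_visits",
    "symptom_category", "letter",
)


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _app_from_record(rec: dict, path, lineno: int) -> Application:
    missing = [f for f in APPLICATION_FIELDS if f not in rec]
    if missing:
        raise ParseError(path, lineno, f"missing fields: {', '.join(missing)}")
    try:
        rrd = rec["recorded_review_day"]
        rrd = None if rrd in (None, "", "NA") else int(rrd)
        return Application(
            id=str(rec["id"]),
            submission_day=int(rec["submission_day"]),
            recorded_review_day=rrd,
            label=str(rec["label"]),
            age_at_application=float(rec["age_at_application"]),
            age_at_onset=float(rec["age_at_onset"]),
            duration=float(rec["duration"]),
            prior_visits=int(rec["prior_visits"]),
            symptom_category=str(rec["symptom_category"]),
            letter=str(rec["letter"]),
        )
    except (TypeError, ValueError) as exc:
        raise ParseError(path, lineno, str(exc)) from exc


def _app_to_record(app: Application) -> dict:
    return {f: getattr(app, f) for f in APPLICATION_FIELDS}


def write_applications(apps: Sequence[Application], path: str | Path) -> None:
    """Write applications as JSONL or (if the suffix is .csv) CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=APPLICATION_FIELDS)
            writer.writeheader()
            for app in apps:
                rec = _app_to_record(app)
                if rec["recorded_review_day"] is None:
                    rec["recorded_review_day"] = "NA"
                writer.writerow(rec)
    else:
        with path.open("w", encoding="utf-8") as fh:
            for app in apps:
                fh.write(json.dumps(_app_to_record(app)) + "\n")


def read_applications(path: str | Path) -> list[Application]:
    path = Path(path)
    apps: list[Application] = []
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for lineno, rec in enumerate(csv.DictReader(fh), start=2):
                apps.append(_app_from_record(rec, path, lineno))
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(path, lineno, f"invalid JSON: {exc}") from exc
                apps.append(_app_from_record(rec, path, lineno))
    return apps


def write_corpus(corpus: Sequence[PhenotypeEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in corpus:
            fh.write(json.dumps({"entry_id": e.entry_id, "description": e.description}) + "\n")


def read_corpus(path: str | Path) -> list[PhenotypeEntry]:
    entries = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                entries.append(PhenotypeEntry(entry_id=rec["entry_id"],
                                              description=rec["description"]))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return entries


def write_scores(scores: dict[str, float], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "score"])
        for app_id in sorted(scores):
            writer.writerow([app_id, repr(scores[app_id])])


def read_scores(path: str | Path) -> dict[str, float]:
    path = Path(path)
    out: dict[str, float] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                out[row["id"]] = float(row["score"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
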