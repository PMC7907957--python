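"""Term dictionaries used for concept tagging and symptom features.

Two small default lexicons ship with the package as two-column TSV files
(term, label); both can be replaced by user-supplied files of the same
shape.  The concept lexicon maps clinical terms to one of five broad
semantic types; the symptom lexicon marks terms as objective (ascertainable
on examination or testing) or subjective (patient-reported) findings.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

SEMANTIC_TYPES = (
    "sign_or_symptom",
    "procedure",
    "disease_or_syndrome",
    "body_part",
    "gene_or_genome",
)

SYMPTOM_CLASSES = ("objective", "subjective")


def _read_tsv(text: str, allowed: tuple[str, ...], what: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{what} line {lineno}: expected 2 tab-separated columns")
        term, label = parts[0].strip().lower(), parts[1].strip()
        if label not in allowed:
            raise ValueError(f"{what} line {lineno}: unknown label {label!r}")
        out[term] = label
    if not out:
        raise ValueError(f"{what}: lexicon is empty")
    return out


def load_concept_lexicon(path: str | Path | None = None) -> dict[str, str]:
    """Load a term -> semantic-type lexicon (default: the shipped dictionary)."""
    if path is None:
        text = resources.files("udn_triage.data").joinpath("concept_lexicon.tsv").read_text()
    else:
        text = Path(path).read_text()
    return _read_tsv(text, SEMANTIC_TYPES, "concept lexicon")


def load_symptom_lexicon(path: str | Path | None = None) -> dict[str, str]:
    """Load a term -> objective/subjective lexicon (default: the shipped list)."""
    if path is None:
        text = resources.files("udn_triage.data").joinpath("symptom_lexicon.tsv").read_text()
    else:
        text = Path(path).read_text()
    return _read_tsv(text, SYMPTOM_CLASSES, "symptom lexicon")


def save_lexicon(lexicon: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{t}\t{l}\n" for t, l in lexicon.items()))
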