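"""Expert "always patterns": regex rules that force a sentence label.

An always pattern is a regular expression authored by a domain expert
with the semantics "whenever this matches, the sentence's label is X,
unconditionally".  Propagating the pattern set over unlabeled keyword
sentences yields weak labels with provenance ``pattern``; sentences
matched by patterns with *disagreeing* labels are routed to a conflict
stream for human review instead of being labeled, since any disagreement
invalidates the "always" guarantee.

Patterns are applied to sentence text only (never whole-note context),
case-insensitively.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Sentence
from .labels import Label, Provenance, as_label

__all__ = [
    "AlwaysPattern",
    "LabeledSentence",
    "PatternCompileError",
    "propagate",
    "coverage",
    "select_unmatched",
    "read_patterns_tsv",
    "write_patterns_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
]


class PatternCompileError(ValueError):
    """An always pattern failed to compile; names the offending pattern."""


@dataclass(frozen=True)
class AlwaysPattern:
    pattern: str
    label: Label
    author: str = ""
    created_round: int = 0

    def __post_init__(self):
        if self.created_round < 0:
            raise ValueError("created_round must be >= 0")
        object.__setattr__(self, "label", as_label(self.label))
        try:
            compiled = re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise PatternCompileError(
                f"pattern {self.pattern!r} does not compile: {exc}") from None
        object.__setattr__(self, "_compiled", compiled)

    def matches(self, text: str) -> bool:
        return self._compiled.search(text) is not None


@dataclass(frozen=True)
class LabeledSentence:
    sentence: Sentence
    label: Label
    provenance: Provenance
    round: int = 0

    @property
    def key(self) -> tuple[str, int]:
        return self.sentence.key


def propagate(
    patterns: Sequence[AlwaysPattern],
    sentences: Iterable[Sentence],
    round: int = 0,
) -> tuple[list[LabeledSentence], list[tuple[Sentence, frozenset[Label]]]]:
    """Screen unlabeled sentences against the pattern set.

    Returns ``(labeled, conflicts)``: sentences matched by patterns of
    exactly one label become :class:`LabeledSentence` with provenance
    ``pattern``; sentences matched by patterns with disagreeing labels
    are returned in the conflict stream (with the set of labels claimed)
    and stay unlabeled; unmatched sentences appear in neither.
    """
    labeled: list[LabeledSentence] = []
    conflicts: list[tuple[Sentence, frozenset[Label]]] = []
    for sent in sentences:
        hit_labels = {p.label for p in patterns if p.matches(sent.text)}
        if len(hit_labels) == 1:
            labeled.append(LabeledSentence(
                sentence=sent, label=next(iter(hit_labels)),
                provenance=Provenance.PATTERN, round=round))
        elif len(hit_labels) > 1:
            conflicts.append((sent, frozenset(hit_labels)))
    return labeled, conflicts


def coverage(
    patterns: Sequence[AlwaysPattern], sentences: Sequence[Sentence],
) -> tuple[float, int]:
    """Fraction (and count) of sentences matched by >= 1 pattern.

    Label agreement is irrelevant here: a conflicted sentence still
    counts as covered.  Raises on an empty sentence set (the fraction
    is undefined).
    """
    sentences = list(sentences)
    if not sentences:
        raise ValueError("coverage is undefined for an empty sentence set")
    matched = sum(
        1 for s in sentences if any(p.matches(s.text) for p in patterns)
    )
    return matched / len(sentences), matched


def select_unmatched(
    patterns: Sequence[AlwaysPattern], sentences: Iterable[Sentence],
) -> list[Sentence]:
    """Sentences matched by no pattern (complement of the covered set)."""
    return [s for s in sentences
            if not any(p.matches(s.text) for p in patterns)]


# ---------------------------------------------------------------------------
# TSV I/O

def read_patterns_tsv(path: str | Path) -> list[AlwaysPattern]:
    out: list[AlwaysPattern] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            out.append(AlwaysPattern(
                pattern=rec["pattern"], label=as_label(rec["label"]),
                author=rec.get("author", ""),
                created_round=int(rec.get("round", 0) or 0)))
    return out


def write_patterns_tsv(patterns: Iterable[AlwaysPattern], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pattern", "label", "author", "round"])
        for p in patterns:
            w.writerow([p.pattern, p.label.value, p.author, p.created_round])


def write_labels_tsv(labeled: Iterable[LabeledSentence], path: str | Path) -> None:
    """Labeled-sentence TSV: note_id, sentence_index, label, provenance, round."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["note_id", "sentence_index", "label", "provenance", "round"])
        for ls in labeled:
            w.writerow([ls.sentence.note_id, ls.sentence.sentence_index,
                        ls.label.value, ls.provenance.value, ls.round])


def read_labels_tsv(
    path: str | Path, sentences: Sequence[Sentence],
) -> list[LabeledSentence]:
    """Join a labels TSV back onto sentence objects by (note_id, index)."""
    by_key = {s.key: s for s in sentences}
    out: list[LabeledSentence] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            key = (rec["note_id"], int(rec["sentence_index"]))
            if key not in by_key:
                raise KeyError(f"labeled sentence {key} not in sentence set")
            out.append(LabeledSentence(
                sentence=by_key[key], label=as_label(rec["label"]),
                provenance=Provenance(rec["provenance"]),
                round=int(rec.get("round", 0) or 0)))
    return out
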