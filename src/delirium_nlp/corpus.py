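"""Note corpora: I/O, sentence segmentation, and keyword-sentence extraction.

A corpus is an ordered collection of :class:`Note` records (one clinical
note each).  Notes are segmented into :class:`Sentence` units with exact
character offsets, and sentences containing any term of the delirium
:class:`Lexicon` are extracted together with their :class:`KeywordMatch`
spans.  All coordinates are 0-based, half-open ``[start, end)``.

Keyword matching is case-insensitive, anchored at a left word boundary,
and stem-prefix: a lexicon entry such as ``"disorient"`` matches
``"disoriented"`` and ``"disorientation"``; multi-word entries tolerate
any run of whitespace between words.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Note",
    "Sentence",
    "KeywordMatch",
    "Lexicon",
    "DEFAULT_KEYWORDS",
    "CorpusParseError",
    "read_corpus",
    "write_corpus",
    "segment_sentences",
    "extract_keyword_sentences",
    "write_sentences_tsv",
    "read_sentences_tsv",
]

#: Delirium keyword lexicon: 23 terms mixing stems and inflected forms.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "delirium",
    "delirious",
    "encephalopathy",
    "confused",
    "confusion",
    "agitated",
    "agitation",
    "inattentive",
    "inattention",
    "disorient",
    "disoriented",
    "disorientation",
    "reorient",
    "restraints",
    "lethargy",
    "psychosis",
    "hallucination",
    "inappropriate behavior",
    "fluctuating arousal",
    "altered mental status",
    "mental status change",
    "fluctuating mental status",
    "waxing and waning mental status",
)


class CorpusParseError(ValueError):
    """A corpus record is malformed; carries the 0-based record index."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"record {record_index}: {message}")


@dataclass(frozen=True)
class Note:
    """One clinical note."""

    patient_id: str
    note_id: str
    timestamp: datetime
    text: str


@dataclass(frozen=True)
class KeywordMatch:
    """A lexicon hit inside a sentence; span offsets are sentence-local."""

    keyword: str
    start: int
    end: int


@dataclass(frozen=True)
class Sentence:
    """A segmented sentence; ``(start, end)`` index into the note text."""

    note_id: str
    sentence_index: int
    text: str
    start: int
    end: int
    matches: tuple[KeywordMatch, ...] = field(default=())

    @property
    def key(self) -> tuple[str, int]:
        return (self.note_id, self.sentence_index)

    def with_matches(self, matches: Sequence[KeywordMatch]) -> "Sentence":
        return replace(self, matches=tuple(matches))


class Lexicon:
    """Ordered set of lowercase keyword stems with a compiled matcher.

    Matching semantics: for each entry, hits start at a left word
    boundary, the entry's words are matched case-insensitively with any
    whitespace run between them, and the final word may continue with
    further letters (stem-prefix).  The reported span covers the full
    token run, so the lowercased slice always *starts with* the entry.
    """

    def __init__(self, entries: Iterable[str] = DEFAULT_KEYWORDS):
        seen: dict[str, None] = {}
        for e in entries:
            e = " ".join(e.lower().split())
            if not e:
                raise ValueError("empty lexicon entry")
            seen.setdefault(e, None)
        if not seen:
            raise ValueError("lexicon must be non-empty")
        self.entries: tuple[str, ...] = tuple(seen)
        self._patterns: list[tuple[str, re.Pattern[str]]] = [
            (e, self._compile(e)) for e in self.entries
        ]

    @staticmethod
    def _compile(entry: str) -> re.Pattern[str]:
        words = [re.escape(w) for w in entry.split()]
        words[-1] += r"[a-z]*"  # stem-prefix on the final word
        body = r"\s+".join(words)
        return re.compile(r"(?<![a-z0-9])" + body, re.IGNORECASE)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entry: str) -> bool:
        return entry.lower() in self.entries

    def union(self, other: "Lexicon | Iterable[str]") -> "Lexicon":
        extra = other.entries if isinstance(other, Lexicon) else tuple(other)
        return Lexicon(self.entries + tuple(extra))

    def find(self, text: str) -> list[KeywordMatch]:
        """All matches in ``text``, sorted by start offset then entry order."""
        hits: list[tuple[int, int, int, str]] = []
        for order, (entry, pat) in enumerate(self._patterns):
            for m in pat.finditer(text):
                hits.append((m.start(), order, m.end(), entry))
        hits.sort()
        return [KeywordMatch(keyword=e, start=s, end=t) for s, _, t, e in hits]

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        lines = Path(path).read_text().splitlines()
        return cls([ln for ln in lines if ln.strip() and not ln.startswith("#")])


# ---------------------------------------------------------------------------
# corpus I/O

_REQUIRED_FIELDS = ("patient_id", "note_id", "timestamp", "text")


def _note_from_record(i: int, rec: dict) -> Note:
    for f in _REQUIRED_FIELDS:
        if f not in rec or rec[f] is None or (f != "text" and str(rec[f]) == ""):
            raise CorpusParseError(i, f"missing field {f!r}")
    text = str(rec["text"])
    if not text.strip():
        raise CorpusParseError(i, "empty note text")
    ts = rec["timestamp"]
    if not isinstance(ts, datetime):
        try:
            ts = datetime.fromisoformat(str(ts))
        except ValueError:
            raise CorpusParseError(i, f"bad timestamp {ts!r}") from None
    return Note(patient_id=str(rec["patient_id"]), note_id=str(rec["note_id"]),
                timestamp=ts, text=text)


def read_corpus(path: str | Path, format: str | None = None) -> list[Note]:
    """Read notes from JSONL or CSV, preserving file order.

    ``format`` is inferred from the suffix when omitted.  Duplicate
    note_ids raise, and each record must carry patient_id, note_id, an
    ISO-8601 timestamp, and non-empty text.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")
    notes: list[Note] = []
    if format == "jsonl":
        with open(path) as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(i, f"invalid JSON: {exc}") from None
                notes.append(_note_from_record(i, rec))
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for i, rec in enumerate(reader):
                notes.append(_note_from_record(i, rec))
    seen: set[str] = set()
    for n in notes:
        if n.note_id in seen:
            raise ValueError(f"duplicate note_id {n.note_id!r}")
        seen.add(n.note_id)
    return notes


def write_corpus(notes: Iterable[Note], path: str | Path,
                 format: str | None = None) -> None:
    """Write notes as JSONL or CSV (inverse of :func:`read_corpus`)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    rows = [
        {"patient_id": n.patient_id, "note_id": n.note_id,
         "timestamp": n.timestamp.isoformat(), "text": n.text}
        for n in notes
    ]
    if format == "jsonl":
        with open(path, "w") as fh:
            for r in rows:
                fh.write(json.dumps(r) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_REQUIRED_FIELDS))
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# sentence segmentation

# Telegraphic clinical abbreviations that end with '.' but do not end a
# sentence.  Compared lowercase, without the trailing period.
_ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "prof", "st",
    "pt", "pts", "vs", "etc", "eg", "ie", "e.g", "i.e",
    "b.i.d", "t.i.d", "q.i.d", "q.h.s", "q.d", "p.r.n", "a.m", "p.m",
    "wt", "ht", "approx", "no", "neg", "pos",
})

_TERMINATOR = re.compile(r"[.!?]+(?=\s|$)")


def _is_abbreviation(text: str, dot_pos: int) -> bool:
    """True when the '.' at ``dot_pos`` ends a guarded abbreviation."""
    if text[dot_pos] != ".":
        return False
    j = dot_pos
    # take the token (letters and internal dots) preceding the period
    while j > 0 and (text[j - 1].isalpha() or text[j - 1] == "."):
        j -= 1
    token = text[j:dot_pos].lower().rstrip(".")
    if not token:
        return False
    if token in _ABBREVIATIONS:
        return True
    # single-letter initials ("J. Smith") and dotted shorthand ("b.i.d.")
    if len(token) == 1 or "." in token:
        return True
    return False


def segment_sentences(note: Note) -> list[Sentence]:
    """Split a note into sentences with exact half-open char spans.

    Boundaries are hard newlines and ``[.!?]`` runs followed by
    whitespace, guarded by a clinical abbreviation stop-list so that
    "Dr. Smith saw pt." stays one sentence.  Trailing punctuation is
    kept inside the sentence span; only inter-sentence whitespace falls
    outside all spans.
    """
    text = note.text
    sentences: list[Sentence] = []

    def emit(start: int, end: int) -> None:
        # trim whitespace off both ends of the candidate span
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            sentences.append(Sentence(
                note_id=note.note_id, sentence_index=len(sentences),
                text=text[start:end], start=start, end=end))

    for line_m in re.finditer(r"[^\n]+", text):
        line_start, line_end = line_m.start(), line_m.end()
        seg_start = line_start
        for m in _TERMINATOR.finditer(text, line_start, line_end):
            if _is_abbreviation(text, m.end() - 1):
                continue
            emit(seg_start, m.end())
            seg_start = m.end()
        if seg_start < line_end:
            emit(seg_start, line_end)
    return sentences


# ---------------------------------------------------------------------------
# keyword-sentence extraction

def extract_keyword_sentences(
    notes: Iterable[Note], lexicon: Lexicon | None = None,
) -> list[Sentence]:
    """Segment notes and keep only sentences with >= 1 lexicon hit.

    Returns sentences in corpus order with their keyword matches
    attached (sentence-local spans).  The operation is idempotent and
    monotone in the lexicon: enlarging the lexicon can only add
    sentences.
    """
    if lexicon is None:
        lexicon = Lexicon()
    out: list[Sentence] = []
    for note in notes:
        for sent in segment_sentences(note):
            hits = lexicon.find(sent.text)
            if hits:
                out.append(sent.with_matches(hits))
    return out


def write_sentences_tsv(sentences: Iterable[Sentence], path: str | Path) -> None:
    """TSV export: note_id, sentence_index, start, end, text, keywords."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["note_id", "sentence_index", "start", "end", "text", "keywords"])
        for s in sentences:
            kw = ";".join(f"{m.keyword}:{m.start}:{m.end}" for m in s.matches)
            w.writerow([s.note_id, s.sentence_index, s.start, s.end, s.text, kw])


def read_sentences_tsv(path: str | Path) -> list[Sentence]:
    sentences: list[Sentence] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            matches = []
            if rec["keywords"]:
                for part in rec["keywords"].split(";"):
                    kw, s, e = part.rsplit(":", 2)
                    matches.append(KeywordMatch(kw, int(s), int(e)))
            sentences.append(Sentence(
                note_id=rec["note_id"], sentence_index=int(rec["sentence_index"]),
                text=rec["text"], start=int(rec["start"]), end=int(rec["end"]),
                matches=tuple(matches)))
    return sentences
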