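"""Corpus data model, JSON I/O, rule-based sentence splitting, and query-set overlaps.

A corpus is an ordered collection of documents (PMID-like identifier, title,
abstract, optional full text, publication year, journal metadata and the set of
query tags that retrieved the record).  Analysis downstream operates on one
chosen text field per document: the abstract when present, otherwise the full
text.  Sentence splitting is deliberately rule-based and deterministic so that
the whole pipeline runs without any model download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Set

from .errors import CorpusFormatError, ValidationError

__all__ = [
    "Document",
    "Sentence",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "sentencize",
    "split_sentences",
    "query_overlap",
]


@dataclass(frozen=True)
class Document:
    """One publication record.

    ``year`` and ``sjr`` (SCImago Journal Rank) may be missing; ``query_tags``
    records which of the named literature queries returned the document.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    full_text: str = ""
    year: int | None = None
    journal: str = ""
    sjr: float | None = None
    query_tags: frozenset[str] = field(default_factory=frozenset)

    @property
    def text(self) -> str:
        """The analysis text field: abstract if non-empty, else full text."""
        return self.abstract if self.abstract.strip() else self.full_text

    def validate(self) -> None:
        if not self.doc_id:
            raise ValidationError("document with empty doc_id")
        if not (self.abstract.strip() or self.full_text.strip()):
            raise ValidationError(
                f"document {self.doc_id!r}: field 'abstract' or 'full_text' must be non-empty"
            )
        if self.year is not None and not (1800 <= self.year <= 2100):
            raise ValidationError(
                f"document {self.doc_id!r}: field 'year' out of range [1800, 2100]: {self.year}"
            )
        if self.sjr is not None and self.sjr < 0:
            raise ValidationError(f"document {self.doc_id!r}: field 'sjr' negative")


@dataclass(frozen=True)
class Sentence:
    """A sentence span within a document's analysis text field.

    ``start``/``end`` are 0-based half-open character offsets into the source
    field; ``text`` equals the source slice.
    """

    doc_id: str
    index: int
    start: int
    end: int
    text: str


@dataclass
class Corpus:
    """An ordered document collection, optionally with sentences attached."""

    documents: list[Document] = field(default_factory=list)
    sentences: dict[str, list[Sentence]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            doc.validate()
            if doc.doc_id in seen:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def doc(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    @property
    def is_sentencized(self) -> bool:
        return bool(self.sentences)


_REQUIRED = ("doc_id",)


def _doc_from_record(rec: object, pos: int) -> Document:
    if not isinstance(rec, dict):
        raise CorpusFormatError(f"record #{pos} is not a JSON object")
    for key in _REQUIRED:
        if key not in rec or rec[key] in (None, ""):
            raise ValidationError(f"record #{pos}: missing required field {key!r}")
    doc = Document(
        doc_id=str(rec["doc_id"]),
        title=rec.get("title") or "",
        abstract=rec.get("abstract") or "",
        full_text=rec.get("full_text") or "",
        year=int(rec["year"]) if rec.get("year") is not None else None,
        journal=rec.get("journal") or "",
        sjr=float(rec["sjr"]) if rec.get("sjr") is not None else None,
        query_tags=frozenset(rec.get("query_tags") or ()),
    )
    doc.validate()
    return doc


def read_corpus(path: str | Path) -> Corpus:
    """Read a corpus from the JSON dialect (top-level list of document objects).

    Sentences are not populated; call :func:`sentencize` afterwards.
    """
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(
            f"malformed corpus JSON at byte {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(data, list):
        raise CorpusFormatError("corpus file must contain a top-level JSON list")
    docs = [_doc_from_record(rec, i) for i, rec in enumerate(data)]
    return Corpus(documents=docs)


def _doc_to_record(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "title": doc.title,
        "abstract": doc.abstract,
        "full_text": doc.full_text,
        "year": doc.year,
        "journal": doc.journal,
        "sjr": doc.sjr,
        "query_tags": sorted(doc.query_tags),
    }


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus as the JSON dialect; writing is deterministic, so two
    writes of the same corpus are byte-identical and round-trip through
    :func:`read_corpus`."""
    payload = [_doc_to_record(d) for d in corpus.documents]
    text = json.dumps(payload, ensure_ascii=False, indent=2) + "\n"
    Path(path).write_text(text, encoding="utf-8")


# --- sentence splitting -----------------------------------------------------

#: Abbreviations whose trailing period never ends a sentence (matched
#: case-insensitively at a token boundary).
PROTECTED_ABBREVIATIONS: tuple[str, ...] = (
    "e.g.",
    "i.e.",
    "et al.",
    "vs.",
    "fig.",
    "ca.",
)

_TERMINATORS = ".!?"


def _protected(text: str, i: int) -> bool:
    """True if the period at index ``i`` terminates a protected abbreviation
    or a single capital initial (as in author names)."""
    head = text[: i + 1]
    low = head.lower()
    for abbr in PROTECTED_ABBREVIATIONS:
        if low.endswith(abbr):
            k = len(head) - len(abbr)
            if k == 0 or not (head[k - 1].isalnum() or head[k - 1] == "-"):
                return True
    # single capital initial: "J." preceded by start of text or a non-word char
    if i >= 1 and head[i - 1].isupper() and head[i - 1].isalpha():
        if i == 1 or not (head[i - 2].isalnum() or head[i - 2] == "-"):
            return True
    return False


def _is_boundary(text: str, i: int) -> bool:
    """Is the terminator at index ``i`` a sentence boundary?

    Boundary rule: '.', '!' or '?' followed by whitespace and an uppercase
    letter or digit — unless the period sits between digits (decimals) or
    closes a protected abbreviation.
    """
    ch = text[i]
    j = i + 1
    if j >= len(text) or not text[j].isspace():
        return False
    while j < len(text) and text[j].isspace():
        j += 1
    if j >= len(text):
        return False
    nxt = text[j]
    if not (nxt.isupper() or nxt.isdigit()):
        return False
    if ch == ".":
        if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
            return False
        if _protected(text, i):
            return False
    return True


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans (0-based half-open, whitespace-trimmed).

    Degenerate text without any boundary yields a single sentence.
    """
    bounds = [
        i + 1 for i, ch in enumerate(text) if ch in _TERMINATORS and _is_boundary(text, i)
    ]
    spans: list[tuple[int, int]] = []
    start = 0
    for stop in bounds + [len(text)]:
        seg = text[start:stop]
        lead = len(seg) - len(seg.lstrip())
        s = start + lead
        e = start + len(seg.rstrip())
        if e > s:
            spans.append((s, e))
        start = stop
    return spans


def sentencize(corpus: Corpus) -> Corpus:
    """Return a corpus with sentences populated for every document.

    Each document's analysis text field (abstract preferred over full text) is
    partitioned into ordered, non-overlapping sentence spans.
    """
    sentences: dict[str, list[Sentence]] = {}
    for doc in corpus.documents:
        src = doc.text
        spans = split_sentences(src)
        sentences[doc.doc_id] = [
            Sentence(doc_id=doc.doc_id, index=i, start=s, end=e, text=src[s:e])
            for i, (s, e) in enumerate(spans)
        ]
    return Corpus(documents=list(corpus.documents), sentences=sentences)


# --- query overlaps ---------------------------------------------------------


def query_overlap(id_sets: Mapping[str, Set[str]]) -> dict[frozenset[str], int]:
    """Exclusive region counts for a named family of document-ID sets.

    Each element of the union is assigned the signature of the sets containing
    it (a Venn region); the returned counts cover every non-empty region and
    sum to the size of the union.
    """
    if not id_sets:
        raise ValidationError("query_overlap requires at least one named set")
    regions: dict[frozenset[str], int] = {}
    union: set[str] = set().union(*id_sets.values())
    for el in union:
        sig = frozenset(name for name, s in id_sets.items() if el in s)
        regions[sig] = regions.get(sig, 0) + 1
    return regions
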