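"""Dictionary-based entity tagging and normalization.

Tagging collapses all synonym surface forms of an entity to its preferred
label (preflabel), the normalization target under which comention networks and
enrichment statistics are computed.  Matching is leftmost-longest over each
sentence, aligned to token boundaries; synonyms of four or more characters are
matched case-insensitively while shorter ones (typically gene symbols such as
"INS" or "TF") require an exact-case match to avoid false positives on common
words.  Genes and proteins are not distinguished: both carry type "protein".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .corpus import Corpus
from .errors import LexiconError, StateError

__all__ = [
    "LexiconEntry",
    "EntityLexicon",
    "Mention",
    "read_lexicon_tsv",
    "write_lexicon_tsv",
    "tag",
    "entity_document_counts",
    "CASE_SENSITIVE_MAX_LEN",
]

ENTITY_TYPES = ("protein", "disease")

#: Synonyms strictly shorter than this many characters are matched exact-case.
CASE_SENSITIVE_MAX_LEN = 4


@dataclass(frozen=True)
class LexiconEntry:
    preflabel: str
    type: str
    synonyms: tuple[str, ...]
    external_id: str = ""


@dataclass
class EntityLexicon:
    """A list of entities, each with a preferred label, a type and synonyms.

    The preferred label is always included among its own synonyms; preflabels
    are unique within each type.
    """

    entries: list[LexiconEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        normalized = []
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if not e.preflabel:
                raise LexiconError("entry with empty preflabel")
            if e.type not in ENTITY_TYPES:
                raise LexiconError(f"entry {e.preflabel!r}: unknown type {e.type!r}")
            if any(not s for s in e.synonyms):
                raise LexiconError(f"entry {e.preflabel!r}: empty synonym")
            key = (e.preflabel, e.type)
            if key in seen:
                raise LexiconError(f"duplicate preflabel {e.preflabel!r} for type {e.type!r}")
            seen.add(key)
            syns = e.synonyms if e.preflabel in e.synonyms else (e.preflabel,) + e.synonyms
            normalized.append(LexiconEntry(e.preflabel, e.type, tuple(syns), e.external_id))
        self.entries = normalized

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, preflabel: str, type: str | None = None) -> LexiconEntry:
        for e in self.entries:
            if e.preflabel == preflabel and (type is None or e.type == type):
                return e
        raise KeyError(preflabel)

    @property
    def all_synonyms(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out.update(e.synonyms)
        return out


@dataclass(frozen=True)
class Mention:
    """A normalized entity occurrence: sentence-local half-open span,
    the exact matched text, and the (preflabel, type) it normalizes to."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    text_found: str
    preflabel: str
    type: str


# --- lexicon TSV ------------------------------------------------------------


def read_lexicon_tsv(path: str | Path) -> EntityLexicon:
    """Read a lexicon TSV with columns preflabel, type, external_id, synonyms
    (pipe-separated).  Lines starting with '#' are comments."""
    entries: list[LexiconEntry] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise LexiconError(f"line {lineno}: expected 4 tab-separated columns")
        preflabel, etype, external_id, syns = parts
        synonyms = tuple(s for s in syns.split("|") if s)
        entries.append(LexiconEntry(preflabel, etype, synonyms, external_id))
    return EntityLexicon(entries)


def write_lexicon_tsv(lexicon: EntityLexicon, path: str | Path) -> None:
    lines = ["# preflabel\ttype\texternal_id\tsynonyms"]
    for e in lexicon.entries:
        lines.append("\t".join([e.preflabel, e.type, e.external_id, "|".join(e.synonyms)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- tagging ----------------------------------------------------------------


def _is_word_char(ch: str) -> bool:
    # token characters: letters, digits, hyphen
    return ch.isalnum() or ch == "-"


def _aligned(text: str, start: int, end: int) -> bool:
    if start > 0 and _is_word_char(text[start - 1]):
        return False
    if end < len(text) and _is_word_char(text[end]):
        return False
    return True


def _candidates(text: str, lexicon: EntityLexicon):
    """All token-boundary-aligned synonym occurrences in ``text``."""
    low = text.lower()
    for order, entry in enumerate(lexicon.entries):
        for syn in entry.synonyms:
            ci = len(syn) >= CASE_SENSITIVE_MAX_LEN
            hay, needle = (low, syn.lower()) if ci else (text, syn)
            pos = hay.find(needle)
            while pos != -1:
                end = pos + len(needle)
                if _aligned(text, pos, end):
                    yield (pos, end, order, entry)
                pos = hay.find(needle, pos + 1)


def tag(corpus: Corpus, lexicon: EntityLexicon) -> list[Mention]:
    """Tag every sentence of a sentencized corpus with lexicon entities.

    Overlapping candidate matches are resolved leftmost-first, then
    longest-span, then by lexicon order; the output mentions within a sentence
    never overlap.
    """
    if not corpus.is_sentencized:
        raise StateError("tag() requires a sentencized corpus; call sentencize() first")
    mentions: list[Mention] = []
    for doc in corpus.documents:
        for sent in corpus.sentences.get(doc.doc_id, ()):
            cands = sorted(
                _candidates(sent.text, lexicon),
                key=lambda c: (c[0], -(c[1] - c[0]), c[2]),
            )
            last_end = -1
            for start, end, _, entry in cands:
                if start < last_end:
                    continue
                mentions.append(
                    Mention(
                        doc_id=doc.doc_id,
                        sentence_index=sent.index,
                        start=start,
                        end=end,
                        text_found=sent.text[start:end],
                        preflabel=entry.preflabel,
                        type=entry.type,
                    )
                )
                last_end = end
    return mentions


def entity_document_counts(
    mentions: Sequence[Mention],
    min_count: int = 0,
    type_filter: str | None = None,
) -> pd.DataFrame:
    """Document-level mention counts per entity.

    Returns a table (preflabel, type, n_documents) where ``n_documents`` is the
    number of distinct documents with at least one mention of the entity; rows
    below ``min_count`` are dropped; sorted by count descending, ties
    alphabetical by preflabel.
    """
    docs: dict[tuple[str, str], set[str]] = {}
    for m in mentions:
        if type_filter is not None and m.type != type_filter:
            continue
        docs.setdefault((m.preflabel, m.type), set()).add(m.doc_id)
    rows = [
        {"preflabel": pl, "type": t, "n_documents": len(ds)}
        for (pl, t), ds in docs.items()
        if len(ds) >= min_count
    ]
    frame = pd.DataFrame(rows, columns=["preflabel", "type", "n_documents"])
    if len(frame):
        frame = frame.sort_values(
            ["n_documents", "preflabel"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return frame
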