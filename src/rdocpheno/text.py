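"""Text normalization, tokenization, and the translation-provider contract.

Admission notes may arrive bilingual (the motivating corpus mixed English and
Korean); translation is abstracted behind :class:`TranslationProvider` so the
pipeline never depends on a live machine-translation service.  Two providers
ship: :class:`IdentityProvider` (default, for monolingual text) and
:class:`DictionaryProvider`, a deterministic word-for-word stub used in tests
and in the simulator's bilingual mode.

Normalization is deliberately minimal and language-agnostic: NFKC Unicode
normalization, casefolding, punctuation replaced by spaces (apostrophes
internal to a word are kept, so "can't" survives as one token), and whitespace
collapsed.  No stemming or lemmatization is applied: scores are defined by
exact term matching, and stemming would silently change what a lexicon term
denotes.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol, runtime_checkable

from .errors import FormatError, PipelineError

__all__ = [
    "NoteDocument",
    "TranslationProvider",
    "IdentityProvider",
    "DictionaryProvider",
    "normalize_text",
    "tokenize",
    "prepare_document",
    "read_notes_dir",
    "read_notes_csv",
]

# Any char that is not a word character or apostrophe becomes a space;
# underscores are punctuation for our purposes despite being in \w.
_NON_TOKEN = re.compile(r"[^\w']|_")
# Apostrophes not flanked by word characters on both sides are punctuation.
_EDGE_APOSTROPHE = re.compile(r"(?<!\w)'|'(?!\w)")
_WS = re.compile(r"\s+")


def normalize_text(text: str, keep_apostrophes: bool = True) -> str:
    """Normalize raw note text for matching.

    Lowercases (casefold), applies NFKC, maps every non-alphanumeric
    character to a space except apostrophes internal to a word, and
    collapses whitespace.  Total and idempotent.
    """
    s = unicodedata.normalize("NFKC", text).casefold()
    s = s.replace("’", "'")  # curly apostrophe, NFKC leaves it alone
    s = _NON_TOKEN.sub(" ", s)
    if keep_apostrophes:
        s = _EDGE_APOSTROPHE.sub(" ", s)
    else:
        s = s.replace("'", " ")
    return _WS.sub(" ", s).strip()


def tokenize(text: str) -> list[str]:
    """Split normalized text on spaces, preserving order (empty text -> [])."""
    return text.split(" ") if text else []


@dataclass(frozen=True)
class NoteDocument:
    """One admission note: raw text plus (after preparation) its token sequence."""

    note_id: str
    admission_id: str
    raw_text: str
    tokens: tuple[str, ...] | None = None

    @property
    def prepared(self) -> bool:
        return self.tokens is not None


@runtime_checkable
class TranslationProvider(Protocol):
    """Contract for the translate step: a pure function of its input within one run."""

    provider_name: str

    def translate(self, text: str) -> str: ...


class IdentityProvider:
    """No-op provider for text already in the lexicon's language."""

    provider_name = "identity"

    def translate(self, text: str) -> str:
        return text


class DictionaryProvider:
    """Word-for-word deterministic translation stub.

    Splits on whitespace, maps each word through the dictionary (unknown
    words pass through unchanged).  Adequate for token-substitution test
    corpora; not a model of real translation.
    """

    provider_name = "dictionary"

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DictionaryProvider":
        mapping = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != ["source", "target"]:
                raise FormatError(f"{path}: expected header 'source,target'")
            for row in reader:
                if len(row) != 2:
                    raise FormatError(f"{path}: malformed row {row!r}")
                mapping[row[0]] = row[1]
        return cls(mapping)

    def translate(self, text: str) -> str:
        if not text:
            return ""
        return " ".join(self.mapping.get(w, w) for w in text.split())


def prepare_document(
    note: NoteDocument,
    provider: TranslationProvider | None = None,
    keep_apostrophes: bool = True,
) -> NoteDocument:
    """Translate, normalize, and tokenize one note; raw_text is left untouched.

    Provider failures are wrapped in :class:`PipelineError` carrying the
    note_id — a document is never silently skipped.
    """
    provider = provider if provider is not None else IdentityProvider()
    try:
        translated = provider.translate(note.raw_text)
    except Exception as exc:  # noqa: BLE001 - contract: no silent skip
        raise PipelineError(
            f"translation failed for note {note.note_id!r}: {exc}", note_id=note.note_id
        ) from exc
    tokens = tuple(tokenize(normalize_text(translated, keep_apostrophes=keep_apostrophes)))
    return replace(note, tokens=tokens)


def read_notes_dir(path: str | Path) -> list[NoteDocument]:
    """Read a directory of UTF-8 ``<admission_id>.txt`` files, sorted by id."""
    path = Path(path)
    docs = []
    for p in sorted(path.glob("*.txt")):
        admission_id = p.stem
        docs.append(
            NoteDocument(note_id=admission_id, admission_id=admission_id, raw_text=p.read_text(encoding="utf-8"))
        )
    return docs


def read_notes_csv(path: str | Path) -> list[NoteDocument]:
    """Read a two-column ``admission_id,text`` CSV of notes."""
    docs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["admission_id", "text"]:
            raise FormatError(f"{path}: expected header 'admission_id,text'")
        for row in reader:
            if len(row) != 2:
                raise FormatError(f"{path}: malformed row {row!r}")
            docs.append(NoteDocument(note_id=row[0], admission_id=row[0], raw_text=row[1]))
    return docs
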