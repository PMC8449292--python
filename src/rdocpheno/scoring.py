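"""Presence-fraction RDoC scoring — the pipeline's core statistic.

A document's score for domain *d* is

    s_d = (number of distinct terms of T_d that appear in the document) / |T_d|

Presence, not frequency: a term that occurs fifty times counts once (if a
10-term list has 2 of its terms in a note, the note scores 2/10 = 20%,
however often those 2 terms repeat).  Multi-word terms match as contiguous
token subsequences of the prepared document.  Scores are carried as fractions
in [0, 1]; rescaling to percentage points happens only at the regression
stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ValidationError
from .lexicon import Lexicon
from .text import NoteDocument

__all__ = ["RdocScoreVector", "score_document", "score_corpus", "write_scores", "write_audit"]


@dataclass(frozen=True)
class RdocScoreVector:
    """Per-domain presence fractions for one admission, with the matched terms kept for audit."""

    admission_id: str
    scores: Mapping[str, float]
    matched_terms: Mapping[str, frozenset[str]]


def _ngram_sets(tokens: Sequence[str], lengths: set[int]) -> dict[int, set[tuple[str, ...]]]:
    """All contiguous n-grams of ``tokens`` for each required length, as sets."""
    out: dict[int, set[tuple[str, ...]]] = {}
    n = len(tokens)
    for k in lengths:
        out[k] = {tuple(tokens[i : i + k]) for i in range(n - k + 1)} if k <= n else set()
    return out


def score_document(doc: NoteDocument, lexicon: Lexicon) -> RdocScoreVector:
    """Score one prepared document against every domain of the lexicon.

    A term matches iff its token sequence occurs contiguously in
    ``doc.tokens``; each term counts at most once.  Raises
    :class:`ValidationError` if the document was never prepared.
    """
    if doc.tokens is None:
        raise ValidationError(f"document {doc.note_id!r} has no tokens; run prepare_document first")

    term_tokens: dict[str, dict[str, tuple[str, ...]]] = {
        d: {t: tuple(t.split(" ")) for t in lexicon.terms[d]} for d in lexicon.domains
    }
    lengths = {len(tt) for per_domain in term_tokens.values() for tt in per_domain.values()}
    grams = _ngram_sets(doc.tokens, lengths)

    scores: dict[str, float] = {}
    matched: dict[str, frozenset[str]] = {}
    for d in lexicon.domains:
        hits = frozenset(t for t, tt in term_tokens[d].items() if tt in grams[len(tt)])
        matched[d] = hits
        scores[d] = len(hits) / lexicon.size(d)
    return RdocScoreVector(admission_id=doc.admission_id, scores=scores, matched_terms=matched)


def score_corpus(docs: Sequence[NoteDocument], lexicon: Lexicon) -> list[RdocScoreVector]:
    """Score every document; output order matches input order, one vector per admission."""
    seen: set[str] = set()
    for doc in docs:
        if doc.admission_id in seen:
            raise ValidationError(f"duplicate admission_id {doc.admission_id!r} in corpus")
        seen.add(doc.admission_id)
    return [score_document(doc, lexicon) for doc in docs]


def write_scores(vectors: Sequence[RdocScoreVector], lexicon: Lexicon, path: str | Path) -> None:
    """Score matrix CSV: ``admission_id,<domain1>,...``, fractions with 6 decimals."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["admission_id", *lexicon.domains])
        for v in vectors:
            writer.writerow([v.admission_id, *(f"{v.scores[d]:.6f}" for d in lexicon.domains)])


def write_audit(vectors: Sequence[RdocScoreVector], lexicon: Lexicon, path: str | Path) -> None:
    """Audit CSV of every matched (admission, domain, term) triple."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["admission_id", "domain", "matched_term"])
        for v in vectors:
            for d in lexicon.domains:
                for t in sorted(v.matched_terms[d]):
                    writer.writerow([v.admission_id, d, t])
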