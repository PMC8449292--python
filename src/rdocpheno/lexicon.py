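"""The RDoC term lexicon: five domains, each a set of (possibly multi-word) terms.

The domain score of a document is the fraction of a domain's terms present in
it, so the lexicon's term sets are the denominators of every score.  The
canonical five NIMH RDoC domains are shipped as ``CANONICAL_DOMAINS``, but
arbitrary domain sets are accepted so synthetic lexicons and future domain
lists work unchanged.

On-disk format: two-column UTF-8 CSV with header exactly ``domain,term``,
one term per row, multi-word terms quoted per RFC 4180.  Terms are stored
normalized with the same normalization as documents (see
:mod:`rdocpheno.text`) so there is exactly one normalization code path.

The published NIMH RDoC working-group term list is not redistributed here;
save the real list in this format and pass its path to :func:`load_lexicon`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ValidationError
from .text import normalize_text

__all__ = ["CANONICAL_DOMAINS", "Lexicon", "load_lexicon", "write_lexicon"]

logger = logging.getLogger(__name__)

#: The five domains of the NIMH RDoC framework, in conventional order.
CANONICAL_DOMAINS: tuple[str, ...] = (
    "positive_valence",
    "negative_valence",
    "cognitive_systems",
    "social_processes",
    "arousal_regulatory",
)

_HEADER = ["domain", "term"]


@dataclass(frozen=True)
class Lexicon:
    """An ordered set of named domains, each mapping to a set of normalized terms."""

    domains: tuple[str, ...]
    terms: Mapping[str, frozenset[str]]

    def __post_init__(self):
        if len(set(self.domains)) != len(self.domains):
            raise ValidationError("duplicate domain names")
        if set(self.domains) != set(self.terms):
            raise ValidationError("domains and term-set keys differ")
        for d in self.domains:
            ts = self.terms[d]
            if not ts:
                raise ValidationError(f"domain {d!r} has no terms")
            if any(not t for t in ts):
                raise ValidationError(f"domain {d!r} contains an empty term")

    def size(self, domain: str) -> int:
        """|T_d| — the score denominator for ``domain``."""
        return len(self.terms[domain])

    @property
    def n_terms(self) -> int:
        return sum(len(v) for v in self.terms.values())


def make_lexicon(domain_terms: Mapping[str, Iterable[str]]) -> Lexicon:
    """Build a validated Lexicon from raw (unnormalized) terms, in mapping order."""
    domains = tuple(domain_terms)
    normalized: dict[str, frozenset[str]] = {}
    for d, raw in domain_terms.items():
        terms = frozenset(normalize_text(t) for t in raw)
        if "" in terms:
            raise ValidationError(f"domain {d!r}: a term is empty after normalization")
        normalized[d] = terms
    return Lexicon(domains=domains, terms=normalized)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon CSV.

    Duplicate (domain, term) rows are collapsed with a logged warning (set
    semantics); a missing or wrong header is a :class:`FormatError`.
    """
    path = Path(path)
    domains: list[str] = []
    terms: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _HEADER:
            raise FormatError(f"{path}: expected header 'domain,term', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            domain, term = row[0].strip(), normalize_text(row[1])
            if not term:
                raise ValidationError(f"{path}:{lineno}: term empty after normalization")
            if domain not in terms:
                domains.append(domain)
                terms[domain] = set()
            if term in terms[domain]:
                logger.warning("%s:%d: duplicate term %r in domain %r collapsed", path, lineno, term, domain)
            terms[domain].add(term)
    if not domains:
        raise ValidationError(f"{path}: lexicon has no terms")
    return Lexicon(domains=tuple(domains), terms={d: frozenset(v) for d, v in terms.items()})


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon CSV that reloads equal (terms sorted within domain)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for d in lexicon.domains:
            for t in sorted(lexicon.terms[d]):
                writer.writerow([d, t])
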