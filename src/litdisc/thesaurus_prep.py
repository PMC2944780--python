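"""Keyword cleaning rules applied before pattern compilation.

Full gene names as catalogued (e.g. ``"programmed cell death 1 (PDCD1)"``)
are poor literal search terms: parenthesized annotations are deleted and
commas become spaces.  Gene symbols and aliases shorter than three
characters are dropped outright, and the remaining symbols are screened
against a pinned English word list so that symbols like "AND" or "CELL"
cannot flood the concordance with false hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import Concept

#: Reason codes for dropped keywords.
DROP_NONE = "none"
DROP_TWO_LETTER = "two_letter"
DROP_ENGLISH_WORD = "english_word"
DROP_EMPTY = "empty_after_normalization"

_PAREN_RE = re.compile(r"\([^()]*\)")
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class CleanedKeyword:
    """A thesaurus keyword after normalization/filtering.

    ``dropped`` is ``"none"`` for retained keywords, otherwise the reason the
    keyword was removed from matching.
    """

    original: str
    normalized: str
    keyword_type: str
    dropped: str = DROP_NONE

    @property
    def kept(self) -> bool:
        return self.dropped == DROP_NONE


def normalize_full_name(name: str) -> str:
    """Normalize a full (gene) name for literal matching.

    Parenthesized spans are removed innermost-out until none remain, each
    comma becomes a space, whitespace runs collapse to single spaces, and
    the result is stripped.  May return an empty string, in which case the
    caller should drop the keyword.
    """
    out = name
    while True:
        reduced = _PAREN_RE.sub(" ", out)
        if reduced == out:
            break
        out = reduced
    # unbalanced parentheses are simply removed
    out = out.replace("(", " ").replace(")", " ")
    out = out.replace(",", " ")
    return _WS_RE.sub(" ", out).strip()


def load_dictionary(path: str | Path | None = None) -> frozenset[str]:
    """Load the English word list (one word per line, uppercased on read).

    Without a path, the word list shipped with the package is used; pinning
    the lexicon keeps the symbol filter reproducible across machines.
    """
    if path is None:
        text = (
            resources.files("litdisc.data").joinpath("english_words.txt").read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(
        w.strip().upper() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def _clean_symbol(symbol: str, keyword_type: str, dictionary: frozenset[str]) -> CleanedKeyword:
    stripped = symbol.strip()
    if not stripped:
        return CleanedKeyword(symbol, "", keyword_type, DROP_EMPTY)
    if len(stripped) < 3:
        return CleanedKeyword(symbol, stripped, keyword_type, DROP_TWO_LETTER)
    if stripped.upper() in dictionary:
        return CleanedKeyword(symbol, stripped, keyword_type, DROP_ENGLISH_WORD)
    return CleanedKeyword(symbol, stripped, keyword_type)


def filter_symbols(
    symbols: Sequence[str],
    dictionary: frozenset[str],
    keyword_type: str = "symbol",
) -> list[CleanedKeyword]:
    """Apply the symbol filters: length-2 removal, then English-word removal.

    The dictionary comparison is case-insensitive (the word list is stored
    uppercase); symbols that survive are kept verbatim.  The function is
    idempotent: filtering the retained symbols again changes nothing.
    """
    return [_clean_symbol(s, keyword_type, dictionary) for s in symbols]


def clean_concept(
    concept: Concept, dictionary: frozenset[str]
) -> list[CleanedKeyword]:
    """Clean every keyword of one concept.

    Gene symbols/aliases go through the symbol filters; full names — and all
    keywords of non-gene concepts, which are phrase descriptions — go
    through full-name normalization.  The dictionary filter is applied only
    to gene symbols and aliases.
    """
    cleaned: list[CleanedKeyword] = []
    for text, ktype in concept.keywords:
        if concept.category == "gene" and ktype in ("symbol", "alias"):
            cleaned.append(_clean_symbol(text, ktype, dictionary))
        else:
            norm = normalize_full_name(text)
            if not norm:
                cleaned.append(CleanedKeyword(text, "", ktype, DROP_EMPTY))
            else:
                cleaned.append(CleanedKeyword(text, norm, ktype))
    return cleaned


def clean_thesaurus(
    concepts: Iterable[Concept],
    dictionary: frozenset[str] | None = None,
) -> dict[str, tuple[Concept, list[CleanedKeyword]]]:
    """Clean a whole thesaurus.

    Returns a mapping ``concept_id -> (concept, cleaned keywords)``.
    Concepts whose keywords are all dropped are excluded (a concept with no
    searchable keyword cannot be tagged).
    """
    if dictionary is None:
        dictionary = load_dictionary()
    out: dict[str, tuple[Concept, list[CleanedKeyword]]] = {}
    for concept in concepts:
        cleaned = clean_concept(concept, dictionary)
        if any(kw.kept for kw in cleaned):
            out[concept.concept_id] = (concept, cleaned)
    return out
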