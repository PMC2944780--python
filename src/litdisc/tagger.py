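"""Keyword matching, symbol disambiguation and concordance building.

Matching follows a boundary contract rather than generic word boundaries:
an occurrence counts only when the characters flanking the keyword are one
of ``] [ . - ) ( , : ;``, a space, or the string edge, with an optional
trailing plural "s" absorbed.  Inside full names, each single space may
match either whitespace or a dash ("cell death" also hits "cell-death").
Full names and non-gene descriptions match case-insensitively; gene symbols
match case-sensitively as written, because case-folding symbols would
re-introduce the English-word collisions the thesaurus cleaning removed.

A gene hit supported only by symbol/alias matches is ambiguous (symbols
collide across genes and with abbreviations); it is kept only when at least
one informative word of the gene's full name also occurs in the document,
otherwise it is discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_io import Concept, ConfigError, Corpus, DocumentRecord, PubDate
from .thesaurus_prep import CleanedKeyword, clean_thesaurus

#: Characters allowed to flank a keyword occurrence.
BOUNDARY_CHARS = "][.-)(,:; "
_BOUND = r"[\]\[.\-(),:; ]"

#: Words of a full gene name too generic to disambiguate a symbol hit.
FULL_NAME_STOPWORDS = frozenset(
    {
        "gene", "protein", "factor", "family", "member", "type", "like",
        "receptor", "molecule", "antigen", "associated", "related", "domain",
        "containing", "subunit", "chain", "class", "group", "candidate",
        "putative", "homolog", "human", "alpha", "beta", "gamma", "delta",
    }
)

_WORD_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class MatchPattern:
    """A compiled matcher for one cleaned keyword of one concept."""

    concept_id: str
    keyword_type: str
    pattern: str
    regex: re.Pattern = field(repr=False, compare=False, hash=False, default=None)  # type: ignore[assignment]

    def search(self, text: str) -> bool:
        return self.regex.search(text) is not None


def compile_pattern(
    kw: CleanedKeyword,
    concept_id: str,
    category: str = "gene",
    allow_plural_symbols: bool = False,
) -> MatchPattern:
    """Compile the boundary-contract regex for a cleaned keyword.

    Parameters
    ----------
    kw
        A retained (not dropped) cleaned keyword.
    concept_id, category
        Owner of the keyword; the category decides case handling.
    allow_plural_symbols
        Whether the optional trailing "s" also applies to gene symbols
        (off by default: plural forms of symbols are not conventional).
    """
    if not kw.kept:
        raise ValueError(f"cannot compile dropped keyword {kw.original!r}")
    is_symbol = category == "gene" and kw.keyword_type in ("symbol", "alias")
    if is_symbol:
        core = re.escape(kw.normalized)
        plural = "s?" if allow_plural_symbols else ""
        flags = 0
    else:
        # full names / phrase descriptions: each internal whitespace run
        # matches one whitespace or one dash
        words = kw.normalized.split()
        core = r"[\s-]".join(re.escape(w) for w in words)
        plural = "s?"
        flags = re.IGNORECASE
    pattern = rf"(?:^|(?<={_BOUND})){core}{plural}(?={_BOUND}|$)"
    return MatchPattern(
        concept_id=concept_id,
        keyword_type=kw.keyword_type,
        pattern=pattern,
        regex=re.compile(pattern, flags),
    )


@dataclass
class CompiledThesaurus:
    """A cleaned thesaurus with compiled patterns and disambiguation words."""

    concepts: dict[str, Concept]
    patterns: list[MatchPattern]
    #: per gene concept: compiled regexes for informative full-name words
    full_name_word_res: dict[str, list[re.Pattern]]

    @property
    def categories(self) -> dict[str, str]:
        return {cid: c.category for cid, c in self.concepts.items()}


def _full_name_words(
    cleaned: Sequence[CleanedKeyword], min_word_len: int
) -> list[str]:
    words: list[str] = []
    for kw in cleaned:
        if kw.keyword_type != "full_name" or not kw.kept:
            continue
        for w in kw.normalized.split():
            lw = w.lower()
            if len(w) < min_word_len or lw in FULL_NAME_STOPWORDS:
                continue
            if any(ch.isdigit() for ch in w):
                continue
            words.append(w)
    return words


def compile_thesaurus(
    concepts: Iterable[Concept],
    dictionary: frozenset[str] | None = None,
    allow_plural_symbols: bool = False,
    min_full_name_word_len: int = 4,
) -> CompiledThesaurus:
    """Clean and compile a thesaurus for tagging.

    ``min_full_name_word_len`` is the minimum length of a full-name word
    that may vouch for an ambiguous symbol hit; shorter words (and
    stopwords/numerals) are too unspecific.
    """
    cleaned = clean_thesaurus(concepts, dictionary)
    if not cleaned:
        raise ConfigError("thesaurus is empty after cleaning")
    out_concepts: dict[str, Concept] = {}
    patterns: list[MatchPattern] = []
    word_res: dict[str, list[re.Pattern]] = {}
    for cid, (concept, kws) in cleaned.items():
        out_concepts[cid] = concept
        for kw in kws:
            if kw.kept:
                patterns.append(
                    compile_pattern(kw, cid, concept.category, allow_plural_symbols)
                )
        if concept.category == "gene":
            word_res[cid] = [
                re.compile(
                    rf"(?:^|(?<={_BOUND})){re.escape(w)}s?(?={_BOUND}|$)",
                    re.IGNORECASE,
                )
                for w in _full_name_words(kws, min_full_name_word_len)
            ]
    return CompiledThesaurus(out_concepts, patterns, word_res)


def tag_document(
    doc: DocumentRecord, patterns: Sequence[MatchPattern]
) -> set[tuple[str, str]]:
    """Match all patterns against one document.

    Returns the deduplicated set of ``(concept_id, keyword_type)`` hits over
    title, body and substances; several occurrences of one keyword count
    once.
    """
    text = doc.search_text
    hits: set[tuple[str, str]] = set()
    for pat in patterns:
        key = (pat.concept_id, pat.keyword_type)
        if key in hits:
            continue
        if pat.search(text):
            hits.add(key)
    return hits


def disambiguate_symbol_hits(
    doc: DocumentRecord,
    hits: set[tuple[str, str]],
    thesaurus: CompiledThesaurus,
) -> set[tuple[str, str]]:
    """Drop ambiguous gene-symbol hits lacking full-name-word support.

    A concept hit supported by a full-name match bypasses the check.  A
    symbol/alias-only hit is retained iff at least one informative word of
    the concept's full name occurs in the document text.  Non-gene
    categories are never disambiguated.  Gene concepts without any full-name
    keyword cannot be checked and are retained.
    """
    by_concept: dict[str, set[str]] = {}
    for cid, ktype in hits:
        by_concept.setdefault(cid, set()).add(ktype)
    text = doc.search_text
    kept: set[tuple[str, str]] = set()
    for cid, ktypes in by_concept.items():
        concept = thesaurus.concepts.get(cid)
        symbol_only = (
            concept is not None
            and concept.category == "gene"
            and "full_name" not in ktypes
        )
        if symbol_only:
            word_res = thesaurus.full_name_word_res.get(cid, [])
            if word_res and not any(r.search(text) for r in word_res):
                continue  # discarded as ambiguous
        kept.update((cid, kt) for kt in ktypes)
    return kept


@dataclass(frozen=True)
class MentionIndex:
    """Non-redundant document/concept concordance with publication dates.

    ``doc_to_concepts`` covers every document in the corpus (possibly with
    an empty concept set) so that the total document count N — the
    denominator of all occurrence probabilities — is the corpus size, not
    the number of documents with hits.
    """

    doc_to_concepts: dict[str, frozenset[str]]
    concept_to_docs: dict[str, frozenset[str]]
    dates: dict[str, PubDate]

    @property
    def n_docs(self) -> int:
        return len(self.doc_to_concepts)

    @classmethod
    def from_doc_concepts(
        cls,
        doc_concepts: Mapping[str, Iterable[str]],
        dates: Mapping[str, PubDate],
    ) -> "MentionIndex":
        d2c = {d: frozenset(cs) for d, cs in doc_concepts.items()}
        c2d: dict[str, set[str]] = {}
        for d, cs in d2c.items():
            for c in cs:
                c2d.setdefault(c, set()).add(d)
        return cls(
            doc_to_concepts=d2c,
            concept_to_docs={c: frozenset(ds) for c, ds in c2d.items()},
            dates=dict(dates),
        )

    def subset(self, doc_ids: Iterable[str]) -> "MentionIndex":
        keep = set(doc_ids)
        return MentionIndex.from_doc_concepts(
            {d: cs for d, cs in self.doc_to_concepts.items() if d in keep},
            {d: dt for d, dt in self.dates.items() if d in keep},
        )


def build_concordance(
    corpus: Corpus,
    thesaurus: Iterable[Concept] | CompiledThesaurus,
    dictionary: frozenset[str] | None = None,
) -> MentionIndex:
    """Tag every document and assemble the mention index.

    Disambiguation is applied per document; dates are carried from the
    records.  Output is independent of document order.
    """
    if not isinstance(thesaurus, CompiledThesaurus):
        thesaurus = compile_thesaurus(thesaurus, dictionary)
    if not thesaurus.patterns:
        raise ConfigError("thesaurus has no compiled patterns")
    doc_concepts: dict[str, set[str]] = {}
    dates: dict[str, PubDate] = {}
    for doc in corpus:
        hits = tag_document(doc, thesaurus.patterns)
        hits = disambiguate_symbol_hits(doc, hits, thesaurus)
        doc_concepts[doc.doc_id] = {cid for cid, _ in hits}
        dates[doc.doc_id] = doc.pub_date
    return MentionIndex.from_doc_concepts(doc_concepts, dates)


def write_concordance_tsv(
    index: MentionIndex,
    categories: Mapping[str, str],
    path,
) -> None:
    """Export ``doc_id, concept_id, category, year`` rows (sorted)."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "concept_id", "category", "year"])
        for doc_id in sorted(index.doc_to_concepts):
            for cid in sorted(index.doc_to_concepts[doc_id]):
                writer.writerow(
                    [
                        doc_id,
                        cid,
                        categories.get(cid, ""),
                        str(index.dates[doc_id]),
                    ]
                )


def read_concordance_tsv(path) -> tuple[MentionIndex, dict[str, str]]:
    """Read a concordance TSV back into an index plus category map.

    Note: documents with zero hits are not representable in this export, so
    a round-tripped index may have a smaller N than the original corpus.
    """
    import csv

    from .corpus_io import SchemaError

    doc_concepts: dict[str, set[str]] = {}
    dates: dict[str, PubDate] = {}
    categories: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in ["doc_id", "concept_id", "category", "year"]:
            if col not in (reader.fieldnames or []):
                raise SchemaError(f"{path}: missing column {col!r}")
        for row in reader:
            doc_concepts.setdefault(row["doc_id"], set()).add(row["concept_id"])
            dates[row["doc_id"]] = PubDate.parse(row["year"])
            if row["category"]:
                categories[row["concept_id"]] = row["category"]
    return MentionIndex.from_doc_concepts(doc_concepts, dates), categories
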