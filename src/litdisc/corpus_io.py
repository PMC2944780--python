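"""Reading and writing abstract corpora and keyword thesauri.

Two corpus encodings are supported: a constrained Medline-XML dialect
(``PMID``, ``ArticleTitle``, ``AbstractText``, ``PubDate``,
``ChemicalList/NameOfSubstance``) and a flat TSV with one document per row.
Both produce the same in-memory :class:`Corpus` of dated
:class:`DocumentRecord` objects, so everything downstream is
encoding-agnostic.  Thesauri are TSV files mapping concept identifiers to
typed keywords (full name, symbol, alias) within one of six closed
categories.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

log = logging.getLogger(__name__)

#: The closed set of thesaurus categories (genes, GO biological processes,
#: liver pathologies, diseases, pathways, drugs).
CATEGORIES = frozenset(
    {"gene", "disease", "drug", "pathway", "biological_process", "liver_pathology"}
)

#: Keyword roles a thesaurus entry may take.
KEYWORD_TYPES = frozenset({"full_name", "symbol", "alias"})

_MONTH_NAMES = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


class CorpusFormatError(ValueError):
    """Raised for malformed corpus or thesaurus files."""


class SchemaError(CorpusFormatError):
    """Raised when a tabular file is missing columns or uses unknown codes."""


class ConfigError(ValueError):
    """Raised for invalid run configurations (e.g. an empty thesaurus)."""


@dataclass(frozen=True)
class PubDate:
    """A publication date with at least year precision.

    Month and day may be absent (Medline records frequently carry only a
    year).  For arithmetic, a year-only date is treated as July 1 of that
    year — the unbiased midpoint — and a month-only date as the 15th.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if not 1800 <= self.year <= 2100:
            raise CorpusFormatError(f"year {self.year} outside [1800, 2100]")
        if self.month is not None and not 1 <= self.month <= 12:
            raise CorpusFormatError(f"month {self.month} out of range")
        if self.day is not None:
            if self.month is None:
                raise CorpusFormatError("day given without month")
            # delegates day-of-month validation to datetime
            dt.date(self.year, self.month, self.day)

    def as_date(self) -> dt.date:
        """Concrete calendar date (midpoint conventions for missing fields)."""
        if self.month is None:
            return dt.date(self.year, 7, 1)
        return dt.date(self.year, self.month, self.day or 15)

    def as_float(self) -> float:
        """Fractional year, e.g. 1999.5 for mid-1999."""
        d = self.as_date()
        start = dt.date(d.year, 1, 1).toordinal()
        length = dt.date(d.year + 1, 1, 1).toordinal() - start
        return d.year + (d.toordinal() - start) / length

    @classmethod
    def parse(cls, text: str) -> "PubDate":
        """Parse ``YYYY``, ``YYYY-MM`` or ``YYYY-MM-DD``."""
        parts = text.strip().split("-")
        try:
            if len(parts) == 1:
                return cls(int(parts[0]))
            if len(parts) == 2:
                return cls(int(parts[0]), int(parts[1]))
            if len(parts) == 3:
                return cls(int(parts[0]), int(parts[1]), int(parts[2]))
        except ValueError as exc:
            raise CorpusFormatError(f"unparseable date {text!r}") from exc
        raise CorpusFormatError(f"unparseable date {text!r}")

    def __str__(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"


@dataclass(frozen=True)
class DocumentRecord:
    """One abstract: identifier, title, body text, substance terms, date."""

    doc_id: str
    title: str
    body: str
    substances: tuple[str, ...]
    pub_date: PubDate

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusFormatError("empty doc_id")

    @property
    def search_text(self) -> str:
        """Title, abstract body and substance terms joined by single spaces.

        This is the text the tagger scans; all three fields are searched
        uniformly.
        """
        parts = [self.title, self.body, *self.substances]
        return " ".join(p for p in parts if p)


@dataclass(frozen=True)
class Corpus:
    """An ordered, duplicate-free collection of document records."""

    documents: tuple[DocumentRecord, ...]

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self.documents)

    def __len__(self) -> int:
        return self.n_docs

    @classmethod
    def from_records(cls, records: Iterable[DocumentRecord]) -> "Corpus":
        """Build a corpus, keeping the first record for any duplicated id."""
        seen: dict[str, DocumentRecord] = {}
        n_dupes = 0
        for rec in records:
            if rec.doc_id in seen:
                n_dupes += 1
                log.warning("duplicate doc_id %s: keeping first record", rec.doc_id)
                continue
            seen[rec.doc_id] = rec
        if n_dupes:
            log.warning("%d duplicate records skipped", n_dupes)
        return cls(tuple(seen.values()))


@dataclass(frozen=True)
class Concept:
    """A biological item: category plus its typed keywords."""

    concept_id: str
    category: str
    keywords: tuple[tuple[str, str], ...]  # (text, keyword_type)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"unknown category {self.category!r} for {self.concept_id!r} "
                f"(expected one of {sorted(CATEGORIES)})"
            )
        if not self.keywords:
            raise SchemaError(f"concept {self.concept_id!r} has no keywords")
        for text, ktype in self.keywords:
            if ktype not in KEYWORD_TYPES:
                raise SchemaError(
                    f"unknown keyword_type {ktype!r} for {self.concept_id!r}"
                )
            if not text:
                raise SchemaError(f"empty keyword for {self.concept_id!r}")


# ---------------------------------------------------------------------------
# Medline-XML dialect


def _parse_pubdate_element(elem: etree._Element | None) -> PubDate | None:
    if elem is None:
        return None
    year = elem.findtext("Year")
    if year is None:
        return None
    month_text = elem.findtext("Month")
    month = None
    if month_text:
        month_text = month_text.strip()
        if month_text.isdigit():
            month = int(month_text)
        else:
            month = _MONTH_NAMES.get(month_text[:3].lower())
    day_text = elem.findtext("Day")
    day = int(day_text) if (day_text and month is not None) else None
    return PubDate(int(year), month, day)


def read_medline_xml(path: str | Path) -> Corpus:
    """Read a Medline-dialect XML file into a :class:`Corpus`.

    One record is produced per ``MedlineCitation`` element.  Citations
    without an abstract keep an empty body; citations without a PMID or a
    publication year are skipped with a logged count.

    Raises
    ------
    CorpusFormatError
        If the XML itself is malformed (the message carries the parser's
        line/column position).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"malformed XML in {path}: {exc}") from exc

    records: list[DocumentRecord] = []
    n_skipped = 0
    for cit in tree.iter("MedlineCitation"):
        pmid = cit.findtext("PMID")
        if not pmid or not pmid.strip():
            n_skipped += 1
            continue
        title = (cit.findtext(".//ArticleTitle") or "").strip()
        body = " ".join(
            t.strip() for t in
            (e.text or "" for e in cit.iter("AbstractText"))
            if t.strip()
        )
        substances = tuple(
            (e.text or "").strip()
            for e in cit.iter("NameOfSubstance")
            if (e.text or "").strip()
        )
        pub_date = _parse_pubdate_element(cit.find(".//PubDate"))
        if pub_date is None:
            n_skipped += 1
            continue
        records.append(
            DocumentRecord(pmid.strip(), title, body, substances, pub_date)
        )
    if n_skipped:
        log.warning("%d citations skipped (missing PMID or publication year)", n_skipped)
    return Corpus.from_records(records)


def write_medline_xml(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the Medline XML dialect understood by the reader."""
    root = etree.Element("MedlineCitationSet")
    for rec in corpus:
        cit = etree.SubElement(root, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.doc_id
        art = etree.SubElement(cit, "Article")
        journal = etree.SubElement(art, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pd = etree.SubElement(issue, "PubDate")
        etree.SubElement(pd, "Year").text = f"{rec.pub_date.year:04d}"
        if rec.pub_date.month is not None:
            etree.SubElement(pd, "Month").text = f"{rec.pub_date.month:02d}"
        if rec.pub_date.day is not None:
            etree.SubElement(pd, "Day").text = f"{rec.pub_date.day:02d}"
        etree.SubElement(art, "ArticleTitle").text = rec.title
        abstract = etree.SubElement(art, "Abstract")
        etree.SubElement(abstract, "AbstractText").text = rec.body
        if rec.substances:
            chems = etree.SubElement(cit, "ChemicalList")
            for s in rec.substances:
                chem = etree.SubElement(chems, "Chemical")
                etree.SubElement(chem, "NameOfSubstance").text = s
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# TSV corpus

_CORPUS_COLUMNS = ["doc_id", "year", "title", "body", "substances"]
_SUBSTANCE_SEP = "|"


def read_corpus_tsv(path: str | Path) -> Corpus:
    """Read the flat TSV corpus encoding.

    Columns: ``doc_id, year, title, body, substances``; ``year`` accepts a
    bare year or an ISO date; ``substances`` is ``|``-separated (empty for
    none).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _CORPUS_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing column {col!r}")
        records = []
        for row in reader:
            substances = tuple(
                s for s in (row["substances"] or "").split(_SUBSTANCE_SEP) if s
            )
            records.append(
                DocumentRecord(
                    doc_id=row["doc_id"],
                    title=row["title"],
                    body=row["body"],
                    substances=substances,
                    pub_date=PubDate.parse(row["year"]),
                )
            )
    return Corpus.from_records(records)


def write_corpus_tsv(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CORPUS_COLUMNS)
        for rec in corpus:
            writer.writerow(
                [
                    rec.doc_id,
                    str(rec.pub_date),
                    rec.title,
                    rec.body,
                    _SUBSTANCE_SEP.join(rec.substances),
                ]
            )


# ---------------------------------------------------------------------------
# Thesaurus TSV

_THESAURUS_COLUMNS = ["concept_id", "category", "keyword_type", "keyword"]


def read_thesaurus(path: str | Path) -> list[Concept]:
    """Read a thesaurus TSV (``concept_id, category, keyword_type, keyword``).

    Rows are grouped by concept id; a category conflict between rows of the
    same concept, an unknown category or keyword type, or a concept left
    without keywords is a :class:`SchemaError`.
    """
    path = Path(path)
    grouped: dict[str, list[tuple[str, str]]] = {}
    categories: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _THESAURUS_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing column {col!r}")
        for row in reader:
            cid = row["concept_id"]
            if not cid:
                raise SchemaError(f"{path}: empty concept_id")
            cat = row["category"]
            if cid in categories and categories[cid] != cat:
                raise SchemaError(
                    f"{path}: conflicting categories for {cid!r}: "
                    f"{categories[cid]!r} vs {cat!r}"
                )
            categories[cid] = cat
            grouped.setdefault(cid, []).append((row["keyword"], row["keyword_type"]))
    return [
        Concept(cid, categories[cid], tuple(kws)) for cid, kws in grouped.items()
    ]


def write_thesaurus(concepts: Sequence[Concept], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_THESAURUS_COLUMNS)
        for concept in concepts:
            for text, ktype in concept.keywords:
                writer.writerow([concept.concept_id, concept.category, ktype, text])
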