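"""Occurrence counting and the S / R / R-scaled association scores.

The association strength of two concepts A and B over a corpus of N
abstracts is the mutual-information ratio

    S = P_AB / (P_A * P_B),   P_X = n_X / N,  P_AB = n_AB / N,

i.e. how much more often A and B are co-mentioned than expected under
independence.  R = log10(S) makes the measure symmetric around 0, and the
R-scaled score maps R affinely onto [1, 100] using the lowest and highest R
present in the co-publication list:

    R' = 1 + 99 * (R - Rmin) / (Rmax - Rmin).

Pairs that never co-occur are unscored (S would be 0), not scored low.  An
R-scaled score above 40 is conventionally treated as biologically
significant.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .corpus_io import PubDate
from .tagger import MentionIndex

#: Default R-scaled significance threshold.
SIGNIFICANCE_THRESHOLD = 40.0


class ScoreDomainError(ValueError):
    """Raised when a score is requested outside its mathematical domain."""


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class OccurrenceCounts:
    """Document counts underlying the scores.

    ``n_pair`` only holds pairs with at least one co-occurrence; the
    supporting document ids are kept alongside so score tables can carry
    evidence trails.
    """

    N: int
    n: dict[str, int]
    n_pair: dict[tuple[str, str], int]
    pair_docs: dict[tuple[str, str], tuple[str, ...]]

    def n_ab(self, a: str, b: str) -> int:
        return self.n_pair.get(pair_key(a, b), 0)


def count_occurrences(index: MentionIndex) -> OccurrenceCounts:
    """Count per-concept and pairwise co-occurrence documents.

    N is the total number of documents in the index (including documents
    with no hits).  Pairs with zero co-occurrences are absent.
    """
    if index.n_docs == 0:
        raise ScoreDomainError("empty index: no documents to count")
    n = {c: len(ds) for c, ds in index.concept_to_docs.items()}
    pair_docs: dict[tuple[str, str], list[str]] = {}
    for doc_id in sorted(index.doc_to_concepts):
        concepts = sorted(index.doc_to_concepts[doc_id])
        for a, b in combinations(concepts, 2):
            pair_docs.setdefault((a, b), []).append(doc_id)
    return OccurrenceCounts(
        N=index.n_docs,
        n=n,
        n_pair={k: len(v) for k, v in pair_docs.items()},
        pair_docs={k: tuple(v) for k, v in pair_docs.items()},
    )


def mim_score(n_a: int, n_b: int, n_ab: int, N: int) -> float:
    """Mutual-information ratio S = (n_ab/N) / ((n_a/N) * (n_b/N))."""
    if n_a < 1 or n_b < 1 or n_ab < 1 or N < 1:
        raise ScoreDomainError(
            f"counts must be >= 1 to score a pair (n_a={n_a}, n_b={n_b}, "
            f"n_ab={n_ab}, N={N})"
        )
    return (n_ab / N) / ((n_a / N) * (n_b / N))


def log_score(s: float) -> float:
    """R = log10(S)."""
    if s <= 0:
        raise ScoreDomainError(f"S must be positive, got {s}")
    return math.log10(s)


@dataclass(frozen=True)
class ScoreScale:
    """The [Rmin, Rmax] extremes a co-publication list was scaled over."""

    r_min: float
    r_max: float
    scope: str = "global"

    def __post_init__(self) -> None:
        if self.r_min > self.r_max:
            raise ScoreDomainError(f"r_min {self.r_min} > r_max {self.r_max}")

    @property
    def degenerate(self) -> bool:
        return self.r_min == self.r_max


def rescale(r: float, scale: ScoreScale) -> float:
    """Affine map of R onto [1, 100] against the list extremes.

    A degenerate scale (a single distinct R in the list) maps everything to
    100, the documented fallback.  R outside [Rmin, Rmax] is a domain error
    (beyond a small floating-point grace margin).
    """
    if scale.degenerate:
        return 100.0
    span = scale.r_max - scale.r_min
    eps = 1e-9 * max(1.0, abs(scale.r_min), abs(scale.r_max))
    if r < scale.r_min - eps or r > scale.r_max + eps:
        raise ScoreDomainError(
            f"R={r} outside scale [{scale.r_min}, {scale.r_max}]"
        )
    r = min(max(r, scale.r_min), scale.r_max)
    if r == scale.r_min:
        return 1.0
    if r == scale.r_max:
        return 100.0
    return 1.0 + 99.0 * (r - scale.r_min) / span


@dataclass(frozen=True)
class CooccurrencePair:
    """Counts, scores and evidence for one scored concept pair."""

    a: str
    b: str
    n_a: int
    n_b: int
    n_ab: int
    s: float
    r: float
    r_scaled: float
    doc_ids: tuple[str, ...] = ()
    mean_year: float = float("nan")

    def is_significant(self, threshold: float = SIGNIFICANCE_THRESHOLD) -> bool:
        return self.r_scaled > threshold


class ScoreTable:
    """All scored pairs of a co-publication list plus their scale.

    Keeps the raw (unfiltered) co-occurrence counts so "no direct
    relationship" checks can distinguish a filtered pair from a pair that
    truly never co-occurs.
    """

    def __init__(
        self,
        entries: Sequence[CooccurrencePair],
        scale: ScoreScale,
        categories: Mapping[str, str] | None = None,
        concept_counts: Mapping[str, int] | None = None,
        raw_pair_counts: Mapping[tuple[str, str], int] | None = None,
    ) -> None:
        self.entries: list[CooccurrencePair] = list(entries)
        self.scale = scale
        self.categories: dict[str, str] = dict(categories or {})
        self.concept_counts: dict[str, int] = dict(concept_counts or {})
        if raw_pair_counts is None:
            raw_pair_counts = {pair_key(e.a, e.b): e.n_ab for e in self.entries}
        self.raw_pair_counts: dict[tuple[str, str], int] = dict(raw_pair_counts)
        self._by_pair: dict[tuple[str, str], CooccurrencePair] = {
            pair_key(e.a, e.b): e for e in self.entries
        }
        self._adjacency: dict[str, set[str]] = {}
        for e in self.entries:
            self._adjacency.setdefault(e.a, set()).add(e.b)
            self._adjacency.setdefault(e.b, set()).add(e.a)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, a: str, b: str) -> CooccurrencePair | None:
        return self._by_pair.get(pair_key(a, b))

    def partners(self, a: str) -> set[str]:
        """Concepts with a scored co-occurrence with ``a``."""
        return self._adjacency.get(a, set())

    def raw_cooccurrence(self, a: str, b: str) -> int:
        """Co-occurrence count before any min-copublication filter."""
        return self.raw_pair_counts.get(pair_key(a, b), 0)

    def known_concepts(self) -> set[str]:
        known = set(self.concept_counts) | set(self.categories)
        for e in self.entries:
            known.add(e.a)
            known.add(e.b)
        return known


def build_score_table(
    counts: OccurrenceCounts,
    min_copubs: int = 1,
    dates: Mapping[str, PubDate] | None = None,
    categories: Mapping[str, str] | None = None,
    scale_scope: str = "global",
) -> ScoreTable:
    """Score every pair with at least ``min_copubs`` co-occurrences.

    The scale extremes Rmin/Rmax are taken over the retained entries —
    globally by default, or per unordered category pair with
    ``scale_scope="per_category_pair"`` (requires ``categories``).  An empty
    retained set yields an empty table with a degenerate flagged scale.
    """
    if min_copubs < 1:
        raise ScoreDomainError("min_copubs must be >= 1")
    if scale_scope not in ("global", "per_category_pair"):
        raise ScoreDomainError(f"unknown scale_scope {scale_scope!r}")
    if scale_scope == "per_category_pair" and not categories:
        raise ScoreDomainError("per_category_pair scaling requires categories")

    retained: list[tuple[tuple[str, str], float, float]] = []  # (pair, s, r)
    for pair, n_ab in counts.n_pair.items():
        if n_ab < min_copubs:
            continue
        a, b = pair
        s = mim_score(counts.n[a], counts.n[b], n_ab, counts.N)
        retained.append((pair, s, log_score(s)))

    if not retained:
        scale = ScoreScale(0.0, 0.0, scope=f"{scale_scope} (empty list)")
        return ScoreTable([], scale, categories, counts.n, counts.n_pair)

    def scope_key(pair: tuple[str, str]):
        if scale_scope == "global":
            return "global"
        ca, cb = categories[pair[0]], categories[pair[1]]  # type: ignore[index]
        return tuple(sorted((ca, cb)))

    r_by_scope: dict[object, list[float]] = {}
    for pair, _s, r in retained:
        r_by_scope.setdefault(scope_key(pair), []).append(r)
    scales = {
        k: ScoreScale(min(rs), max(rs), scope=str(k)) for k, rs in r_by_scope.items()
    }

    entries = []
    for pair, s, r in retained:
        a, b = pair
        scale = scales[scope_key(pair)]
        docs = counts.pair_docs.get(pair, ())
        if dates:
            years = [dates[d].as_float() for d in docs if d in dates]
            mean_year = sum(years) / len(years) if years else float("nan")
        else:
            mean_year = float("nan")
        entries.append(
            CooccurrencePair(
                a=a,
                b=b,
                n_a=counts.n[a],
                n_b=counts.n[b],
                n_ab=counts.n_pair[pair],
                s=s,
                r=r,
                r_scaled=rescale(r, scale),
                doc_ids=docs,
                mean_year=mean_year,
            )
        )
    global_scale = (
        scales["global"]
        if scale_scope == "global"
        else ScoreScale(
            min(s.r_min for s in scales.values()),
            max(s.r_max for s in scales.values()),
            scope="per_category_pair (envelope)",
        )
    )
    return ScoreTable(entries, global_scale, categories, counts.n, counts.n_pair)


_TABLE_COLUMNS = [
    "a", "b", "n_a", "n_b", "n_ab", "S", "R", "R_scaled",
    "mean_year", "significant", "doc_ids",
]


def write_score_table_tsv(table: ScoreTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for e in sorted(table.entries, key=lambda e: (e.a, e.b)):
            writer.writerow(
                [
                    e.a, e.b, e.n_a, e.n_b, e.n_ab,
                    f"{e.s:.10g}", f"{e.r:.10g}", f"{e.r_scaled:.10g}",
                    "" if math.isnan(e.mean_year) else f"{e.mean_year:.4f}",
                    int(e.is_significant()),
                    ";".join(e.doc_ids),
                ]
            )


def read_score_table_tsv(path, categories: Mapping[str, str] | None = None) -> ScoreTable:
    """Read a score table export back (scale recovered from the entries)."""
    from .corpus_io import SchemaError

    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in _TABLE_COLUMNS[:8]:
            if col not in (reader.fieldnames or []):
                raise SchemaError(f"{path}: missing column {col!r}")
        for row in reader:
            entries.append(
                CooccurrencePair(
                    a=row["a"],
                    b=row["b"],
                    n_a=int(row["n_a"]),
                    n_b=int(row["n_b"]),
                    n_ab=int(row["n_ab"]),
                    s=float(row["S"]),
                    r=float(row["R"]),
                    r_scaled=float(row["R_scaled"]),
                    doc_ids=tuple(
                        d for d in (row.get("doc_ids") or "").split(";") if d
                    ),
                    mean_year=float(row["mean_year"]) if row.get("mean_year") else float("nan"),
                )
            )
    if entries:
        scale = ScoreScale(min(e.r for e in entries), max(e.r for e in entries))
    else:
        scale = ScoreScale(0.0, 0.0, scope="empty")
    counts = {}
    for e in entries:
        counts[e.a] = e.n_a
        counts[e.b] = e.n_b
    return ScoreTable(entries, scale, categories, counts)
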