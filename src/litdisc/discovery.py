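"""Open and closed ABC discovery of hidden relationships.

Two concepts A and C that are never co-mentioned may still be related if
both co-occur with shared intermediates B.  An intermediate qualifies when
both of its links (A–B and B–C) meet minimum co-publication and R-scaled
thresholds and B belongs to an allowed category (genes and biological
processes by default, which avoids bridges through uninformative terms).

The strength of the hidden relationship is the inferred R-scaled score Ri:
for each intermediate take the weakest of its two link scores, sum these
over the intermediates, and divide by the number of intermediates — the
minimum-mutual-information idea with R-scaled link scores.  Alternative
aggregations (mean of both links; mean of only the top-k weakest-link
scores) are available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .cooccur import ScoreTable

AGGREGATIONS = ("min_link", "mean_link", "top_k_mean")


@dataclass(frozen=True)
class DiscoveryConfig:
    """Inclusion criteria and scoring options for hidden relationships.

    Defaults follow the strictest published run: at least 3 co-publications
    and an R-scaled score of at least 20 on each link, genes and biological
    processes as intermediates.
    """

    min_copubs_link: int = 3
    min_rscaled_link: float = 20.0
    intermediate_categories: frozenset[str] | None = frozenset(
        {"gene", "biological_process"}
    )
    target_categories: frozenset[str] | None = None  # None = any category
    min_intermediates: int = 1
    aggregation: str = "min_link"
    top_k: int = 5
    ri_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.min_intermediates < 1:
            raise ValueError("min_intermediates must be >= 1")
        if not 1.0 <= self.ri_cutoff <= 100.0:
            raise ValueError("ri_cutoff must lie in [1, 100]")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class IntermediateLink:
    """One qualifying intermediate B with its two link scores.

    ``link_score`` is the weakest of the two R-scaled scores — the link
    that limits how strongly B can vouch for the A–C connection.
    """

    b: str
    r_ab: float
    r_bc: float
    docs_ab: tuple[str, ...] = ()
    docs_bc: tuple[str, ...] = ()

    @property
    def link_score(self) -> float:
        return min(self.r_ab, self.r_bc)

    @property
    def mean_score(self) -> float:
        return (self.r_ab + self.r_bc) / 2.0


@dataclass(frozen=True)
class HiddenRelationship:
    """An A–C pair with no direct co-occurrence, its intermediates and Ri."""

    a: str
    c: str
    intermediates: tuple[IntermediateLink, ...]
    ri: float

    @property
    def n_intermediates(self) -> int:
        return len(self.intermediates)


def infer_ri(
    links: Sequence[IntermediateLink],
    aggregation: str = "min_link",
    top_k: int = 5,
) -> float:
    """Aggregate link scores into the inferred R-scaled score Ri.

    min_link
        Sum of weakest-link scores divided by the number of intermediates.
    mean_link
        Same, with the mean of the two link scores instead of the minimum.
    top_k_mean
        min_link restricted to the k highest weakest-link scores (all links
        when fewer than k qualify).
    """
    if not links:
        raise ValueError("cannot infer Ri from an empty intermediate list")
    if aggregation == "min_link":
        scores = [ln.link_score for ln in links]
    elif aggregation == "mean_link":
        scores = [ln.mean_score for ln in links]
    elif aggregation == "top_k_mean":
        scores = sorted((ln.link_score for ln in links), reverse=True)[:top_k]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return sum(scores) / len(scores)


def find_intermediates(
    a: str,
    c: str,
    table: ScoreTable,
    config: DiscoveryConfig,
) -> list[IntermediateLink]:
    """Every B linking A and C under the inclusion criteria.

    B must belong to an allowed intermediate category and both pairs (A,B)
    and (B,C) must be present in the score table with at least
    ``min_copubs_link`` co-publications and an R-scaled score of at least
    ``min_rscaled_link``.  Result sorted by weakest-link score descending,
    then by id, for deterministic output.
    """
    if a == c:
        raise ValueError("a and c must differ")
    links: list[IntermediateLink] = []
    for b in table.partners(a) & table.partners(c):
        if b in (a, c):
            continue
        if config.intermediate_categories is not None:
            if table.categories.get(b) not in config.intermediate_categories:
                continue
        e_ab = table.get(a, b)
        e_bc = table.get(b, c)
        if e_ab is None or e_bc is None:
            continue
        if e_ab.n_ab < config.min_copubs_link or e_bc.n_ab < config.min_copubs_link:
            continue
        if (
            e_ab.r_scaled < config.min_rscaled_link
            or e_bc.r_scaled < config.min_rscaled_link
        ):
            continue
        links.append(
            IntermediateLink(
                b=b,
                r_ab=e_ab.r_scaled,
                r_bc=e_bc.r_scaled,
                docs_ab=e_ab.doc_ids,
                docs_bc=e_bc.doc_ids,
            )
        )
    links.sort(key=lambda ln: (-ln.link_score, ln.b))
    return links


def _check_known(concept_id: str, table: ScoreTable) -> None:
    if concept_id not in table.known_concepts():
        raise KeyError(f"unknown concept {concept_id!r}")


def closed_discovery(
    a: str,
    c: str,
    table: ScoreTable,
    config: DiscoveryConfig | None = None,
) -> HiddenRelationship | None:
    """Test a hypothesized A–C relationship.

    Returns ``None`` when A and C co-occur directly (any shared abstract
    disqualifies the pair as "hidden") or when fewer than
    ``min_intermediates`` intermediates qualify; otherwise the scored
    relationship.  Symmetric in its arguments.
    """
    config = config or DiscoveryConfig()
    _check_known(a, table)
    _check_known(c, table)
    if table.raw_cooccurrence(a, c) > 0:
        return None
    links = find_intermediates(a, c, table, config)
    if len(links) < config.min_intermediates:
        return None
    ri = infer_ri(links, config.aggregation, config.top_k)
    return HiddenRelationship(a=a, c=c, intermediates=tuple(links), ri=ri)


def open_discovery(
    a: str,
    table: ScoreTable,
    config: DiscoveryConfig | None = None,
) -> list[HiddenRelationship]:
    """Rank all hidden relationships starting from concept A.

    Candidate C concepts are every known concept of a target category with
    zero direct co-occurrence with A.  Relationships reaching the Ri cutoff
    are returned sorted by Ri descending, ties broken by intermediate count
    descending, then by concept id.
    """
    config = config or DiscoveryConfig()
    _check_known(a, table)
    results: list[HiddenRelationship] = []
    for c in sorted(table.known_concepts()):
        if c == a:
            continue
        if config.target_categories is not None:
            if table.categories.get(c) not in config.target_categories:
                continue
        if table.raw_cooccurrence(a, c) > 0:
            continue
        links = find_intermediates(a, c, table, config)
        if len(links) < config.min_intermediates:
            continue
        ri = infer_ri(links, config.aggregation, config.top_k)
        if ri >= config.ri_cutoff:
            results.append(
                HiddenRelationship(a=a, c=c, intermediates=tuple(links), ri=ri)
            )
    results.sort(key=lambda h: (-h.ri, -h.n_intermediates, h.c))
    return results


def relationships_to_rows(relationships: Iterable[HiddenRelationship]) -> list[dict]:
    """Flatten relationships for TSV/JSON export (one row per intermediate)."""
    rows = []
    for h in relationships:
        for ln in h.intermediates:
            rows.append(
                {
                    "a": h.a,
                    "c": h.c,
                    "ri": h.ri,
                    "n_intermediates": h.n_intermediates,
                    "b": ln.b,
                    "r_ab": ln.r_ab,
                    "r_bc": ln.r_bc,
                    "link_score": ln.link_score,
                    "docs_ab": ";".join(ln.docs_ab),
                    "docs_bc": ";".join(ln.docs_bc),
                }
            )
    return rows
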