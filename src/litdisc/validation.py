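"""Literature-partitioning evaluation of hidden-relationship predictions.

A dated corpus is split at a cutoff: relationships are inferred from the
background slice (documents strictly before the split date) and checked
against the test slice (documents from the split date up to, but not
including, an end date).  Candidate pairs are drawn from the background
under three criteria — never co-mentioned, each member in at least 10
abstracts, at least 5 shared qualifying intermediates — and labeled against
the test slice: a pair is a true positive when it gains at least 3
co-occurrences there with an R-scaled score above 40 (computed on the test
slice's own co-publication list).  Sweeping the Ri threshold over the
labeled pairs yields a ROC curve; its AUC equals the probability that a
randomly chosen true pair outranks a randomly chosen false one.

The time-lag statistic measures how far prediction precedes assertion: the
date of the first A–C co-mention minus the mean publication date of all
documents supporting the A–B and B–C links.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .cooccur import ScoreTable
from .discovery import DiscoveryConfig, HiddenRelationship, find_intermediates
from .tagger import MentionIndex

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionSpec:
    """Background/test date windows (half-open at both boundaries)."""

    split_date: dt.date
    test_end_date: dt.date

    def __post_init__(self) -> None:
        if self.split_date >= self.test_end_date:
            raise ValueError("split_date must precede test_end_date")


def partition_corpus(
    index: MentionIndex, spec: PartitionSpec
) -> tuple[MentionIndex, MentionIndex]:
    """Split a mention index into background and test slices.

    Background: documents dated strictly before ``split_date``.  Test:
    documents in ``[split_date, test_end_date)``.  Documents outside both
    windows, or without a date, are excluded (undated documents are counted
    in a warning).
    """
    background: list[str] = []
    test: list[str] = []
    n_undated = 0
    for doc_id in index.doc_to_concepts:
        pub = index.dates.get(doc_id)
        if pub is None:
            n_undated += 1
            continue
        d = pub.as_date()
        if d < spec.split_date:
            background.append(doc_id)
        elif d < spec.test_end_date:
            test.append(doc_id)
    if n_undated:
        log.warning("%d undated documents excluded from partition", n_undated)
    return index.subset(background), index.subset(test)


@dataclass(frozen=True)
class CandidateCriteria:
    """Background-set criteria a pair must meet to become a candidate."""

    min_docs_per_member: int = 10
    min_shared_intermediates: int = 5


def select_candidate_pairs(
    background_table: ScoreTable,
    background_index: MentionIndex,
    criteria: CandidateCriteria | None = None,
    discovery_config: DiscoveryConfig | None = None,
    a_categories: frozenset[str] | None = None,
    c_categories: frozenset[str] | None = None,
) -> list[tuple[str, str]]:
    """Enumerate candidate hidden pairs from the background slice.

    A pair qualifies when its members never co-occur in any background
    abstract, each occurs in at least ``min_docs_per_member`` distinct
    abstracts, and they share at least ``min_shared_intermediates``
    intermediates under the discovery inclusion criteria.  Optional category
    restrictions select e.g. disease–gene pairs.  Output is deterministic
    (lexicographic order).
    """
    criteria = criteria or CandidateCriteria()
    discovery_config = discovery_config or DiscoveryConfig()
    cats = background_table.categories

    def _eligible(categories: frozenset[str] | None) -> list[str]:
        out = []
        for cid, docs in background_index.concept_to_docs.items():
            if len(docs) < criteria.min_docs_per_member:
                continue
            if categories is not None and cats.get(cid) not in categories:
                continue
            out.append(cid)
        return sorted(out)

    if a_categories is None and c_categories is None:
        members = _eligible(None)
        candidates = list(combinations(members, 2))
    else:
        a_side = _eligible(a_categories)
        c_side = _eligible(c_categories)
        seen = set()
        candidates = []
        for a in a_side:
            for c in c_side:
                if a == c:
                    continue
                key = (a, c) if a < c else (c, a)
                if key in seen:
                    continue
                seen.add(key)
                candidates.append(key)
        candidates.sort()

    selected = []
    for a, c in candidates:
        if background_table.raw_cooccurrence(a, c) > 0:
            continue
        links = find_intermediates(a, c, background_table, discovery_config)
        if len(links) < criteria.min_shared_intermediates:
            continue
        selected.append((a, c))
    return selected


@dataclass(frozen=True)
class LabeledPair:
    """A candidate pair with its background Ri and its test-slice label."""

    a: str
    c: str
    ri: float
    label: str  # "TP" or "FP"
    n_ac_test: int
    r_scaled_test: float | None


def label_pairs(
    pairs: Sequence[tuple[str, str, float]],
    test_table: ScoreTable,
    min_test_cooccurrences: int = 3,
    min_test_rscaled: float = 40.0,
) -> list[LabeledPair]:
    """Label candidate pairs against the test-slice score table.

    ``pairs`` carries ``(a, c, ri)`` with Ri inferred from the background.
    TP iff the pair has at least ``min_test_cooccurrences`` co-occurrences
    in the test slice AND its test R-scaled score is strictly above
    ``min_test_rscaled``; every other pair — including pairs never
    co-mentioned in the test slice — is FP.  Labeling is a pure function of
    the test table: input order does not matter.
    """
    labeled = []
    for a, c, ri in pairs:
        entry = test_table.get(a, c)
        n_test = entry.n_ab if entry is not None else test_table.raw_cooccurrence(a, c)
        r_test = entry.r_scaled if entry is not None else None
        is_tp = (
            n_test >= min_test_cooccurrences
            and r_test is not None
            and r_test > min_test_rscaled
        )
        labeled.append(
            LabeledPair(a, c, ri, "TP" if is_tp else "FP", n_test, r_test)
        )
    return labeled


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    fpr: float
    tpr: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class RocCurve:
    """Threshold-swept ROC points (high threshold first) with trapezoid AUC."""

    points: tuple[RocPoint, ...]
    auc: float


class UndefinedCurveError(ValueError):
    """Raised when a ROC curve is requested for single-class input."""


def compute_roc(labeled: Sequence[LabeledPair]) -> RocCurve:
    """Exact step ROC over every distinct Ri threshold plus ±inf sentinels.

    At threshold t a pair is called positive when its Ri >= t.  The sweep
    runs from +inf (nothing called) down to -inf (everything called), so
    FPR and TPR are non-decreasing along the curve.  AUC is the trapezoid
    area, which for a step curve equals the rank statistic: the probability
    that a random TP outranks a random FP (ties counting one half).
    """
    n_tp = sum(1 for p in labeled if p.label == "TP")
    n_fp = len(labeled) - n_tp
    if n_tp == 0 or n_fp == 0:
        raise UndefinedCurveError(
            f"need both classes to sweep a curve (TP={n_tp}, FP={n_fp})"
        )
    thresholds = [math.inf] + sorted(
        {p.ri for p in labeled}, reverse=True
    ) + [-math.inf]
    points = []
    for t in thresholds:
        tp = sum(1 for p in labeled if p.label == "TP" and p.ri >= t)
        fp = sum(1 for p in labeled if p.label == "FP" and p.ri >= t)
        points.append(
            RocPoint(
                threshold=t,
                fpr=fp / n_fp,
                tpr=tp / n_tp,
                tp=tp,
                fp=fp,
                tn=n_fp - fp,
                fn=n_tp - tp,
            )
        )
    auc = 0.0
    for p0, p1 in zip(points, points[1:]):
        auc += (p1.fpr - p0.fpr) * (p0.tpr + p1.tpr) / 2.0
    return RocCurve(points=tuple(points), auc=auc)


def cutoff_at_max_fpr(curve: RocCurve, max_fpr: float) -> float:
    """Smallest Ri threshold whose FPR stays within the bound.

    Choosing the smallest qualifying threshold maximizes the TPR subject to
    FPR <= max_fpr.  The -inf sentinel is excluded (it is not an applicable
    score cutoff); the +inf sentinel guarantees a qualifying threshold
    exists for any bound, so a bound below the smallest achievable nonzero
    FPR yields a threshold above all FP scores.
    """
    if not 0.0 < max_fpr <= 1.0:
        raise ValueError("max_fpr must lie in (0, 1]")
    qualifying = [
        p.threshold
        for p in curve.points
        if p.fpr <= max_fpr and p.threshold != -math.inf
    ]
    if not qualifying:
        raise ValueError(f"no threshold achieves FPR <= {max_fpr}")
    return min(qualifying)


def empirical_rates(
    labeled: Sequence[LabeledPair], threshold: float
) -> tuple[float, float]:
    """(FPR, TPR) of calling pairs with Ri >= threshold positive."""
    n_tp = sum(1 for p in labeled if p.label == "TP")
    n_fp = len(labeled) - n_tp
    fp = sum(1 for p in labeled if p.label == "FP" and p.ri >= threshold)
    tp = sum(1 for p in labeled if p.label == "TP" and p.ri >= threshold)
    return (fp / n_fp if n_fp else 0.0, tp / n_tp if n_tp else 0.0)


def write_roc_tsv(curve: RocCurve, path) -> None:
    """Export per-cutoff TP/FP/TN/FN with TPR = TP/(TP+FN), FPR = FP/(FP+TN)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cutoff", "TP", "FP", "TN", "FN", "TPR", "FPR"])
        for p in curve.points:
            writer.writerow(
                [p.threshold, p.tp, p.fp, p.tn, p.fn,
                 f"{p.tpr:.6f}", f"{p.fpr:.6f}"]
            )


@dataclass
class PartitionEvaluation:
    """All artifacts of one literature-partitioning evaluation run."""

    background_index: MentionIndex
    test_index: MentionIndex
    background_table: ScoreTable
    test_table: ScoreTable
    candidate_pairs: list[tuple[str, str]]
    labeled: list[LabeledPair]
    curve: RocCurve


def evaluate_partition(
    index: MentionIndex,
    categories: Mapping[str, str],
    spec: PartitionSpec,
    discovery_config: DiscoveryConfig | None = None,
    criteria: CandidateCriteria | None = None,
    a_categories: frozenset[str] | None = None,
    c_categories: frozenset[str] | None = None,
    min_copubs_table: int = 3,
) -> PartitionEvaluation:
    """End-to-end literature-partitioning evaluation of a tagged corpus.

    Splits the index, scores both slices (tables restricted to pairs
    meeting the minimum co-publication criterion, which also keeps the
    R-scaled extremes off one-off chance pairs), selects candidate pairs
    from the background, infers their Ri, labels them against the test
    slice and sweeps the ROC curve.
    """
    from .cooccur import build_score_table, count_occurrences
    from .discovery import infer_ri

    discovery_config = discovery_config or DiscoveryConfig()
    background, test = partition_corpus(index, spec)
    bg_table = build_score_table(
        count_occurrences(background),
        min_copubs=min_copubs_table,
        dates=background.dates,
        categories=categories,
    )
    test_table = build_score_table(
        count_occurrences(test),
        min_copubs=min_copubs_table,
        dates=test.dates,
        categories=categories,
    )
    pairs = select_candidate_pairs(
        bg_table,
        background,
        criteria,
        discovery_config,
        a_categories=a_categories,
        c_categories=c_categories,
    )
    scored = [
        (
            a,
            c,
            infer_ri(
                find_intermediates(a, c, bg_table, discovery_config),
                discovery_config.aggregation,
                discovery_config.top_k,
            ),
        )
        for a, c in pairs
    ]
    labeled = label_pairs(scored, test_table)
    curve = compute_roc(labeled)
    return PartitionEvaluation(
        background_index=background,
        test_index=test,
        background_table=bg_table,
        test_table=test_table,
        candidate_pairs=pairs,
        labeled=labeled,
        curve=curve,
    )


class UndefinedTimeLagError(ValueError):
    """Raised when a pair is never co-mentioned anywhere in the corpus."""


def time_lag(
    a: str,
    c: str,
    relationship: HiddenRelationship,
    full_index: MentionIndex,
) -> float:
    """Years between prediction evidence and first A–C assertion.

    Returns (date of the first document co-mentioning A and C anywhere in
    the corpus) minus (mean publication date over every document supporting
    any A–B or B–C link of the relationship), in fractional years.  Negative
    when the first co-mention predates the supporting literature's mean.
    """
    docs_a = full_index.concept_to_docs.get(a, frozenset())
    docs_c = full_index.concept_to_docs.get(c, frozenset())
    joint = docs_a & docs_c
    if not joint:
        raise UndefinedTimeLagError(f"{a!r} and {c!r} never co-occur in the corpus")
    first_assertion = min(full_index.dates[d].as_float() for d in joint)
    support_years: list[float] = []
    for link in relationship.intermediates:
        for d in link.docs_ab:
            support_years.append(full_index.dates[d].as_float())
        for d in link.docs_bc:
            support_years.append(full_index.dates[d].as_float())
    if not support_years:
        raise UndefinedTimeLagError("relationship carries no supporting documents")
    return first_assertion - sum(support_years) / len(support_years)
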