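"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results by the most literal route
available (character scanning, exhaustive enumeration, rank counting) so
the package code is checked against an implementation that shares none of
its logic.
"""

from __future__ import annotations

import math
import string

import numpy as np
import pytest

from litdisc.cooccur import ScoreScale, ScoreTable, CooccurrencePair, pair_key
from litdisc.corpus_io import CATEGORIES, PubDate
from litdisc.discovery import DiscoveryConfig
from litdisc.tagger import BOUNDARY_CHARS, MentionIndex


# ---------------------------------------------------------------------------
# Naive character-by-character matcher (tagger oracle)

_WS_OR_DASH = set(" \t\n\r\x0b\x0c-")


def naive_keyword_match(text: str, keyword: str, *, case_sensitive: bool,
                        allow_plural: bool, dash_for_space: bool) -> bool:
    """Literal scan implementing the boundary contract without regexes."""
    bound = set(BOUNDARY_CHARS)

    def chars_match(tc: str, kc: str) -> bool:
        if kc == " " and dash_for_space:
            return tc in _WS_OR_DASH
        if case_sensitive:
            return tc == kc
        return tc.lower() == kc.lower()

    n, k = len(text), len(keyword)
    for start in range(n):
        if start > 0 and text[start - 1] not in bound:
            continue
        i, j = start, 0
        ok = True
        while j < k:
            if i >= n or not chars_match(text[i], keyword[j]):
                ok = False
                break
            i += 1
            j += 1
        if not ok:
            continue
        if allow_plural and i < n and text[i] in "sS":
            if i + 1 >= n or text[i + 1] in bound:
                i += 1
        if i >= n or text[i] in bound:
            return True
    return False


# ---------------------------------------------------------------------------
# Brute-force ABC enumeration (discovery oracle)


def brute_force_links(a, c, table: ScoreTable, config: DiscoveryConfig):
    links = []
    for b in sorted(table.known_concepts()):
        if b in (a, c):
            continue
        if config.intermediate_categories is not None:
            if table.categories.get(b) not in config.intermediate_categories:
                continue
        e_ab, e_bc = table.get(a, b), table.get(b, c)
        if e_ab is None or e_bc is None:
            continue
        if e_ab.n_ab < config.min_copubs_link or e_bc.n_ab < config.min_copubs_link:
            continue
        if e_ab.r_scaled < config.min_rscaled_link or e_bc.r_scaled < config.min_rscaled_link:
            continue
        links.append((b, e_ab.r_scaled, e_bc.r_scaled))
    return links


def brute_force_ri(links, aggregation: str, top_k: int = 5) -> float:
    if aggregation == "min_link":
        vals = [min(r1, r2) for _, r1, r2 in links]
    elif aggregation == "mean_link":
        vals = [(r1 + r2) / 2 for _, r1, r2 in links]
    else:
        vals = sorted((min(r1, r2) for _, r1, r2 in links), reverse=True)[:top_k]
    return sum(vals) / len(vals)


def brute_force_open(a, table: ScoreTable, config: DiscoveryConfig):
    """Exhaustive triple enumeration: every C, every B, literal criteria."""
    out = []
    for c in sorted(table.known_concepts()):
        if c == a:
            continue
        if config.target_categories is not None:
            if table.categories.get(c) not in config.target_categories:
                continue
        if table.raw_cooccurrence(a, c) > 0:
            continue
        links = brute_force_links(a, c, table, config)
        if len(links) < config.min_intermediates:
            continue
        ri = brute_force_ri(links, config.aggregation, config.top_k)
        if ri >= config.ri_cutoff:
            out.append((c, ri, len(links), sorted(b for b, _, _ in links)))
    out.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return out


# ---------------------------------------------------------------------------
# Rank-statistic AUC (ROC oracle)


def rank_pair_auc(pos_scores, neg_scores) -> float:
    """P(random positive outranks random negative), ties counting half."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


# ---------------------------------------------------------------------------
# Random score tables for oracle-equivalence sweeps


def random_mention_index(rng: np.random.Generator, max_concepts: int = 30):
    n_concepts = int(rng.integers(5, max_concepts + 1))
    n_docs = int(rng.integers(30, 90))
    cats = sorted(CATEGORIES)
    concept_ids = [f"k{i:02d}" for i in range(n_concepts)]
    categories = {cid: cats[int(rng.integers(len(cats)))] for cid in concept_ids}
    rates = rng.uniform(0.05, 0.25, size=n_concepts)
    doc_concepts = {}
    dates = {}
    for d in range(n_docs):
        doc_id = f"d{d:03d}"
        member = {cid for cid, p in zip(concept_ids, rates) if rng.random() < p}
        doc_concepts[doc_id] = member
        dates[doc_id] = PubDate(int(rng.integers(1985, 2008)))
    return MentionIndex.from_doc_concepts(doc_concepts, dates), categories


def build_manual_table(entries_spec, categories=None):
    """Construct a ScoreTable directly from (a, b, n_ab, r_scaled) tuples."""
    entries = []
    for a, b, n_ab, r_scaled in entries_spec:
        entries.append(
            CooccurrencePair(
                a=a, b=b, n_a=max(n_ab, 10), n_b=max(n_ab, 10), n_ab=n_ab,
                s=1.0, r=0.0, r_scaled=r_scaled,
            )
        )
    rs = [e.r_scaled for e in entries]
    scale = ScoreScale(min(rs, default=0.0), max(rs, default=0.0))
    return ScoreTable(entries, scale, categories)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
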