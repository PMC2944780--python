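"""Literature partitioning, TP/FP labeling, ROC machinery, time lag."""

import datetime as dt
import math

import numpy as np
import pytest

from conftest import build_manual_table, rank_pair_auc

from litdisc.cooccur import CooccurrencePair, ScoreScale, ScoreTable
from litdisc.corpus_io import PubDate
from litdisc.discovery import DiscoveryConfig, HiddenRelationship, IntermediateLink
from litdisc.tagger import MentionIndex
from litdisc.validation import (
    CandidateCriteria,
    LabeledPair,
    PartitionSpec,
    UndefinedCurveError,
    UndefinedTimeLagError,
    compute_roc,
    cutoff_at_max_fpr,
    empirical_rates,
    label_pairs,
    partition_corpus,
    select_candidate_pairs,
    time_lag,
)

SPLIT = dt.date(2000, 1, 1)
TEST_END = dt.date(2007, 5, 1)


def _index(doc_dates, doc_concepts=None):
    doc_concepts = doc_concepts or {d: set() for d in doc_dates}
    return MentionIndex.from_doc_concepts(doc_concepts, doc_dates)


class TestPartition:
    def test_window_semantics(self):
        index = _index(
            {"d98": PubDate(1998, 6, 1), "d03": PubDate(2003, 6, 1), "d08": PubDate(2008, 6, 1)}
        )
        bg, test = partition_corpus(index, PartitionSpec(SPLIT, TEST_END))
        assert set(bg.doc_to_concepts) == {"d98"}
        assert set(test.doc_to_concepts) == {"d03"}

    def test_all_pre_split_gives_empty_test(self):
        index = _index({"a": PubDate(1990), "b": PubDate(1995)})
        _, test = partition_corpus(index, PartitionSpec(SPLIT, TEST_END))
        assert test.n_docs == 0

    def test_document_on_split_date_goes_to_test(self):
        index = _index({"d": PubDate(2000, 1, 1)})
        bg, test = partition_corpus(index, PartitionSpec(SPLIT, TEST_END))
        assert set(test.doc_to_concepts) == {"d"}
        assert bg.n_docs == 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PartitionSpec(TEST_END, SPLIT)


class TestSelectCandidatePairs:
    def _background(self):
        # x and y never co-occur, both frequent, share intermediates b1..b5
        doc_concepts = {}
        dates = {}
        for i in range(10):
            doc_concepts[f"x{i}"] = {"x"} | ({f"b{i % 5}"} if True else set())
            doc_concepts[f"y{i}"] = {"y", f"b{i % 5}"}
            dates[f"x{i}"] = PubDate(1995)
            dates[f"y{i}"] = PubDate(1996)
        index = MentionIndex.from_doc_concepts(doc_concepts, dates)
        cats = {"x": "disease", "y": "gene"} | {f"b{i}": "gene" for i in range(5)}
        entries = []
        for i in range(5):
            entries.append((f"b{i}", "x", 3, 50.0))
            entries.append((f"b{i}", "y", 3, 50.0))
        table = build_manual_table(entries, cats)
        return table, index

    def test_single_qualifying_pair_found(self):
        table, index = self._background()
        pairs = select_candidate_pairs(
            table, index, CandidateCriteria(), DiscoveryConfig(min_copubs_link=3)
        )
        assert pairs == [("x", "y")]

    def test_shared_abstract_excludes_pair(self):
        table, index = self._background()
        table.raw_pair_counts[("x", "y")] = 1
        assert select_candidate_pairs(table, index, CandidateCriteria(), DiscoveryConfig()) == []

    def test_member_in_too_few_abstracts_excluded(self):
        table, index = self._background()
        criteria = CandidateCriteria(min_docs_per_member=11)
        assert select_candidate_pairs(table, index, criteria, DiscoveryConfig()) == []

    def test_too_few_shared_intermediates_excluded(self):
        table, index = self._background()
        criteria = CandidateCriteria(min_shared_intermediates=6)
        assert select_candidate_pairs(table, index, criteria, DiscoveryConfig()) == []


class TestLabelPairs:
    def _test_table(self, n_ab, r_scaled):
        return ScoreTable(
            [CooccurrencePair("a", "c", 20, 20, n_ab, 1.0, 0.0, r_scaled)],
            ScoreScale(0.0, 1.0),
        )

    @pytest.mark.parametrize(
        "n_ab, r_scaled, label",
        [(3, 41.0, "TP"), (5, 40.0, "FP"), (2, 95.0, "FP"), (3, 40.0001, "TP")],
    )
    def test_boundary_rule(self, n_ab, r_scaled, label):
        (lp,) = label_pairs([("a", "c", 50.0)], self._test_table(n_ab, r_scaled))
        assert lp.label == label
        assert lp.n_ac_test == n_ab

    def test_pair_absent_from_test_slice_is_fp(self):
        (lp,) = label_pairs([("q", "z", 80.0)], self._test_table(3, 41.0))
        assert lp.label == "FP"
        assert lp.n_ac_test == 0
        assert lp.r_scaled_test is None

    def test_labels_invariant_to_input_order(self):
        table = self._test_table(3, 41.0)
        pairs = [("a", "c", 50.0), ("q", "z", 80.0)]
        l1 = label_pairs(pairs, table)
        l2 = list(reversed(label_pairs(list(reversed(pairs)), table)))
        assert l1 == l2


def _labeled(pos, neg):
    out = [LabeledPair("a", f"p{i}", ri, "TP", 3, 50.0) for i, ri in enumerate(pos)]
    out += [LabeledPair("a", f"n{i}", ri, "FP", 0, None) for i, ri in enumerate(neg)]
    return out


class TestComputeRoc:
    def test_perfect_separation_auc_one(self):
        curve = compute_roc(_labeled([10, 9, 8], [3, 2, 1]))
        assert curve.auc == 1.0

    def test_rank_counting_example(self):
        curve = compute_roc(_labeled([3, 1], [2, 0]))
        assert math.isclose(curve.auc, 0.75, rel_tol=1e-12)

    def test_matches_rank_pair_oracle_with_ties(self, rng):
        for _ in range(60):
            n_pos = int(rng.integers(1, 15))
            n_neg = int(rng.integers(1, 15))
            # coarse grid forces ties within and across classes
            pos = list(rng.integers(0, 6, size=n_pos).astype(float))
            neg = list(rng.integers(0, 6, size=n_neg).astype(float))
            curve = compute_roc(_labeled(pos, neg))
            assert math.isclose(curve.auc, rank_pair_auc(pos, neg), rel_tol=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            pos = list(rng.normal(1, 1, size=12))
            neg = list(rng.normal(0, 1, size=20))
            curve = compute_roc(_labeled(pos, neg))
            y = [1] * 12 + [0] * 20
            assert math.isclose(
                curve.auc, roc_auc_score(y, pos + neg), rel_tol=1e-12
            )

    def test_monotone_sweep(self, rng):
        pos = list(rng.normal(1, 1, size=10))
        neg = list(rng.normal(0, 1, size=10))
        curve = compute_roc(_labeled(pos, neg))
        fprs = [p.fpr for p in curve.points]
        tprs = [p.tpr for p in curve.points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)
        assert fprs[0] == tprs[0] == 0.0 and fprs[-1] == tprs[-1] == 1.0

    def test_auc_invariant_under_monotone_transform(self, rng):
        pos = list(rng.normal(1, 1, size=10))
        neg = list(rng.normal(0, 1, size=15))
        base = compute_roc(_labeled(pos, neg)).auc
        f = lambda x: math.exp(0.3 * x) + 5
        trans = compute_roc(_labeled([f(x) for x in pos], [f(x) for x in neg])).auc
        assert math.isclose(base, trans, rel_tol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedCurveError):
            compute_roc(_labeled([1, 2], []))

    def test_shuffled_labels_give_chance_auc(self, rng):
        aucs = []
        scores = list(rng.normal(0, 1, size=40))
        for _ in range(300):
            labels = rng.permutation([1] * 15 + [0] * 25)
            pos = [s for s, l in zip(scores, labels) if l]
            neg = [s for s, l in zip(scores, labels) if not l]
            aucs.append(compute_roc(_labeled(pos, neg)).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestCutoff:
    def test_table_footnote_semantics(self):
        # constructed sweep where threshold 34 is the smallest with FPR <= 0.1
        pos = [50, 45, 40, 36, 34]
        neg = [34] + [30 - i for i in range(9)]
        curve = compute_roc(_labeled(pos, neg))
        assert cutoff_at_max_fpr(curve, 0.1) == 34

    def test_loose_bound_returns_minimum_threshold(self):
        curve = compute_roc(_labeled([5, 4], [3, 2]))
        # FPR(threshold=2) is 1.0, allowed only by a bound of exactly 1
        assert cutoff_at_max_fpr(curve, 1.0) == 2
        assert cutoff_at_max_fpr(curve, 0.999) == 3

    def test_tight_bound_sits_above_all_fp(self):
        curve = compute_roc(_labeled([10, 9], [5, 4, 3]))
        cut = cutoff_at_max_fpr(curve, 0.2)
        assert cut > 5
        fpr, tpr = empirical_rates(_labeled([10, 9], [5, 4, 3]), cut)
        assert fpr == 0.0 and tpr == 1.0

    def test_invalid_bound_rejected(self):
        curve = compute_roc(_labeled([2], [1]))
        with pytest.raises(ValueError):
            cutoff_at_max_fpr(curve, 1.5)


class TestTimeLag:
    def _relationship(self, docs_ab, docs_bc):
        link = IntermediateLink("b", 60.0, 50.0, tuple(docs_ab), tuple(docs_bc))
        return HiddenRelationship("a", "c", (link,), 50.0)

    def test_worked_example(self):
        dates = {
            "s1": PubDate(1995, 7, 1), "s2": PubDate(1996, 7, 1),
            "s3": PubDate(1995, 7, 1), "s4": PubDate(1997, 7, 1),
            "ac": PubDate(2002, 1, 1),
        }
        index = MentionIndex.from_doc_concepts(
            {"s1": {"a", "b"}, "s2": {"a", "b"}, "s3": {"b", "c"},
             "s4": {"b", "c"}, "ac": {"a", "c"}},
            dates,
        )
        rel = self._relationship(["s1", "s2"], ["s3", "s4"])
        lag = time_lag("a", "c", rel, index)
        support_mean = sum(dates[d].as_float() for d in ("s1", "s2", "s3", "s4")) / 4
        assert abs(lag - (dates["ac"].as_float() - support_mean)) < 1e-9
        assert 5.5 < lag < 6.5

    def test_negative_when_assertion_precedes_support(self):
        dates = {"s1": PubDate(2005), "ac": PubDate(2000)}
        index = MentionIndex.from_doc_concepts(
            {"s1": {"a", "b"}, "ac": {"a", "c"}}, dates
        )
        rel = self._relationship(["s1"], ["s1"])
        assert time_lag("a", "c", rel, index) < 0

    def test_zero_when_single_support_equals_first_assertion(self):
        dates = {"s": PubDate(1999, 3, 3)}
        index = MentionIndex.from_doc_concepts({"s": {"a", "b", "c"}}, dates)
        rel = self._relationship(["s"], ["s"])
        assert time_lag("a", "c", rel, index) == 0.0

    def test_never_asserted_pair_flagged(self):
        dates = {"s": PubDate(1999)}
        index = MentionIndex.from_doc_concepts({"s": {"a", "b"}}, dates)
        rel = self._relationship(["s"], ["s"])
        with pytest.raises(UndefinedTimeLagError):
            time_lag("a", "c", rel, index)
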