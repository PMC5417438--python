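import numpy as np
import pytest

from distotu.caller import (
    CallerConfig,
    OTU,
    call_otus,
    eligible_otus,
    sort_candidates,
)
from distotu.io import CountTable, SequenceRecord


def make_otu(rep_id, seq, counts):
    return OTU(rep_id=rep_id, rep_seq=seq, counts=np.array(counts), members=[rep_id])


class TestSortCandidates:
    def test_by_decreasing_total(self):
        table = CountTable.from_dict({"a": [5], "b": [10]}, ["s1"])
        assert sort_candidates(table) == ["b", "a"]

    def test_ties_broken_by_id(self):
        table = CountTable.from_dict({"b": [5], "a": [5]}, ["s1"])
        assert sort_candidates(table) == ["a", "b"]


class TestEligibleOtus:
    CONFIG = CallerConfig(genetic_threshold=0.1, abundance_fold=10.0)

    def test_no_otus(self):
        cand = SequenceRecord(id="x", seq="ACGT" * 10)
        assert eligible_otus(cand, 5, [], self.CONFIG) == []

    def test_abundance_fold_is_strict_multiple(self):
        # OTU total 100 < 10 x 11, so the candidate is not eligible
        otu = make_otu("o", "ACGT" * 10, [50, 50])
        cand = SequenceRecord(id="x", seq="ACGT" * 10)
        assert eligible_otus(cand, 11, [otu], self.CONFIG) == []
        assert len(eligible_otus(cand, 10, [otu], self.CONFIG)) == 1

    def test_sorted_by_dissimilarity(self):
        base = "ACGTACGTACGTACGTACGT"
        two_off = base[:-2] + "TA"   # 2 edits
        one_off = base[:-1] + "A"    # 1 edit
        otus = [make_otu("far", two_off, [1000]), make_otu("near", one_off, [1000])]
        cand = SequenceRecord(id="x", seq=base)
        ranked = eligible_otus(cand, 10, otus, self.CONFIG)
        assert [otu.rep_id for otu, _ in ranked] == ["near", "far"]

    def test_genetic_failure_excludes(self):
        otu = make_otu("o", "T" * 40, [1000])
        cand = SequenceRecord(id="x", seq="A" * 40)
        assert eligible_otus(cand, 10, [otu], self.CONFIG) == []


class TestCallOtus:
    def test_single_sequence(self):
        records = [SequenceRecord(id="a", seq="ACGT")]
        table = CountTable.from_dict({"a": [3, 4]}, ["s1", "s2"])
        result = call_otus(records, table)
        assert len(result.otus) == 1
        assert result.otus[0].members == ["a"]
        np.testing.assert_array_equal(result.otus[0].counts, [3, 4])

    def test_proportional_low_abundance_variant_merges(self):
        # 1 edit away, exactly proportional counts, 10-fold less abundant:
        # Lambda = 0 so p = 1 and the candidate merges
        base = "ACGTACGTACGTACGTACGT"
        records = [
            SequenceRecord(id="big", seq=base),
            SequenceRecord(id="small", seq=base[:-1] + "A"),
        ]
        table = CountTable.from_dict({"big": [100, 200], "small": [10, 20]}, ["s1", "s2"])
        result = call_otus(records, table, CallerConfig(p_threshold=0.001))
        assert len(result.otus) == 1
        assert result.otus[0].rep_id == "big"
        np.testing.assert_array_equal(result.otus[0].counts, [110, 220])
        assert result.merge_log[1].decision == "merged"

    def test_disjoint_distribution_stays_separate(self):
        # counts only where the OTU has none, with large totals -> p ~ 0
        base = "ACGTACGTACGTACGTACGT" * 3
        records = [
            SequenceRecord(id="big", seq=base),
            SequenceRecord(id="small", seq=base[:-1] + "A"),
        ]
        table = CountTable.from_dict(
            {"big": [3000, 3000, 0], "small": [0, 0, 500]}, ["s1", "s2", "s3"]
        )
        result = call_otus(records, table, CallerConfig(p_threshold=0.001))
        assert len(result.otus) == 2
        trail = result.merge_log[1].trail
        tested = [r for r in trail if r.p_value is not None]
        assert tested and tested[0].p_value < 0.001

    def test_representative_never_changes(self, synthetic_community):
        records, table, _ = synthetic_community
        result = call_otus(records, table)
        for otu in result.otus:
            assert otu.rep_id == otu.members[0]
            assert otu.total >= max(table.total(m) for m in otu.members)

    def test_counts_conserved(self, synthetic_community):
        records, table, _ = synthetic_community
        result = call_otus(records, table)
        otu_sums = np.sum([otu.counts for otu in result.otus], axis=0)
        np.testing.assert_array_equal(otu_sums, table.column_sums())

    def test_bit_deterministic(self, synthetic_community):
        records, table, _ = synthetic_community
        r1 = call_otus(records, table)
        r2 = call_otus(records, table)
        assert r1.membership() == r2.membership()
        for o1, o2 in zip(r1.otus, r2.otus):
            np.testing.assert_array_equal(o1.counts, o2.counts)

    def test_otu_count_monotone_in_p_threshold(self, synthetic_community):
        records, table, _ = synthetic_community
        counts = []
        for p in (1e-12, 1e-6, 1e-3, 0.1, 0.999999):
            cfg = CallerConfig(p_threshold=p, abundance_fold=3.0)
            counts.append(len(call_otus(records, table, cfg).otus))
        # raising the threshold makes merging harder, so OTUs can only increase
        assert counts == sorted(counts)

    def test_merge_log_has_one_entry_per_candidate(self, synthetic_community):
        records, table, _ = synthetic_community
        result = call_otus(records, table)
        assert [e.candidate_id for e in result.merge_log] == sort_candidates(table)
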