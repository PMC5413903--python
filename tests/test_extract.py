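"""Read processing: demultiplexing, trimming/filtering, cluster filters and
the dish-overlap table."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonetrace import extract
from clonetrace.extract import (
    BarcodeCluster,
    Read,
    build_overlap_table,
    cross_dish_filter,
    demultiplex,
    filter_clusters,
    trim_and_filter,
)

SIGS = ("ACGTACCAGT", "CATGGTTCAA", "GTACCAGTCG", "TGCATGACTC")
LEFT = "GTTGTAAAACGACGGCCAGT"
RIGHT = "GGTCATAGCTGTTTCCTGAC"


def make_read(bases, quality=30, rid="r"):
    return Read(rid, bases, np.full(len(bases), quality))


class TestDemultiplex:
    def test_exact_signature_assigns_dish(self):
        read = make_read(SIGS[1] + "ACGT" * 10)
        by_dish, unassigned = demultiplex([read], SIGS)
        assert [r.id for r in by_dish[2]] == ["r"]
        assert not unassigned
        assert by_dish[2][0].bases == "ACGT" * 10  # signature stripped

    def test_one_mismatch_still_assigned(self):
        sig = "T" + SIGS[0][1:]
        by_dish, unassigned = demultiplex([make_read(sig + "A" * 40)], SIGS)
        assert len(by_dish[1]) == 1 and not unassigned

    def test_distant_prefix_unassigned(self):
        by_dish, unassigned = demultiplex([make_read("A" * 50)], SIGS)
        assert all(not v for v in by_dish.values())
        assert len(unassigned) == 1

    def test_ambiguous_signature_set_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            demultiplex([], ("AAAAAAAAAA", "AAAAAAAAAT", "CCCCCCCCCC", "GGGGGGGGGG"),
                        max_mismatches=1)


class TestTrimAndFilter:
    def _read_with_barcode(self, barcode, quality=30):
        return make_read(LEFT + barcode + RIGHT, quality=quality)

    @pytest.mark.parametrize(
        "length, kept", [(25, False), (26, True), (30, True), (34, True), (35, False)]
    )
    def test_length_filter(self, length, kept):
        candidates, discards = trim_and_filter(
            [self._read_with_barcode("A" * length)], LEFT, RIGHT
        )
        assert (len(candidates) == 1) is kept

    def test_quality_filter_over_20_percent(self):
        # 7/30 (23.3%) bases below Q20 -> discard
        read = self._read_with_barcode("A" * 30)
        quals = read.qualities.copy()
        quals[len(LEFT): len(LEFT) + 7] = 10
        read = Read("r", read.bases, quals)
        candidates, discards = trim_and_filter([read], LEFT, RIGHT)
        assert not candidates and discards["low_quality"] == 1

    def test_quality_filter_exactly_20_percent_retained(self):
        read = self._read_with_barcode("A" * 30)
        quals = read.qualities.copy()
        quals[len(LEFT): len(LEFT) + 6] = 10  # exactly 20%
        candidates, _ = trim_and_filter([Read("r", read.bases, quals)], LEFT, RIGHT)
        assert list(candidates) == ["A" * 30]

    def test_clean_read_retained(self):
        candidates, _ = trim_and_filter(
            [self._read_with_barcode("ACGT" * 7 + "AC")], LEFT, RIGHT
        )
        assert candidates == {"ACGT" * 7 + "AC": 1}

    def test_missing_flank_goes_to_discard_bin(self):
        candidates, discards = trim_and_filter([make_read("A" * 70)], LEFT, RIGHT)
        assert not candidates and discards["no_flank"] == 1

    def test_reverse_complement_search_behind_flag(self):
        from clonetrace.extract import reverse_complement

        fwd = LEFT + "C" * 30 + RIGHT
        rc_read = make_read(reverse_complement(fwd))
        candidates, discards = trim_and_filter([rc_read], LEFT, RIGHT)
        assert discards["no_flank"] == 1  # off by default
        candidates, _ = trim_and_filter(
            [rc_read], LEFT, RIGHT, search_reverse_complement=True
        )
        assert list(candidates) == ["C" * 30]

    def test_flank_with_one_mismatch_still_found(self):
        left_mut = "A" + LEFT[1:]
        candidates, _ = trim_and_filter(
            [make_read(left_mut + "C" * 30 + RIGHT)], LEFT, RIGHT
        )
        assert list(candidates) == ["C" * 30]


class TestClusterFilters:
    def test_singleton_cluster_removed(self):
        clusters = [
            BarcodeCluster("A" * 30, [1, 0, 0, 0], 1),
            BarcodeCluster("C" * 30, [2, 0, 0, 0], 1),
        ]
        kept = filter_clusters(clusters)
        assert [c.centroid for c in kept] == ["C" * 30]
        assert kept[0].total_reads == 2  # untouched by the removal

    @pytest.mark.parametrize(
        "dish_counts, expected",
        [
            ([9998, 2, 0, 0], [True, False, False, False]),  # threshold 2.5
            ([399, 1, 0, 0], [True, True, False, False]),  # threshold 0.1
            ([10, 0, 0, 0], [True, False, False, False]),  # zero never counted
        ],
    )
    def test_cross_dish_rule(self, dish_counts, expected):
        flags = cross_dish_filter(BarcodeCluster("A" * 30, dish_counts, 1))
        assert flags.tolist() == expected


def _cluster(seq, counts):
    return BarcodeCluster(seq, counts, 1)


class TestOverlapTable:
    def test_enumerated_patterns(self):
        # dish contents: 1:{A,B} 2:{A,C} 3:{A,D} 4:{A}
        a, b, c, d = ("A" * 30, "C" * 30, "G" * 30, "T" * 30)
        clusters = [
            _cluster(a, [5, 5, 5, 5]),
            _cluster(b, [5, 0, 0, 0]),
            _cluster(c, [0, 5, 0, 0]),
            _cluster(d, [0, 0, 5, 0]),
        ]
        table = build_overlap_table(clusters)
        assert table.exactly == {1: 3, 2: 0, 3: 0, 4: 1}
        assert table.shared == 1
        assert table.per_dish_distinct.tolist() == [2, 2, 2, 1]

    def test_two_dish_pattern(self):
        table = build_overlap_table([_cluster("A" * 30, [5, 5, 0, 0])])
        assert table.exactly == {1: 0, 2: 1, 3: 0, 4: 0}
        assert table.shared == 1

    def test_spike_ins_reported_separately(self):
        spike = "TGCTGACCGCAGGTACGACGCCGAAGGATG"
        clusters = [_cluster(spike, [100, 50, 10, 5]), _cluster("A" * 30, [5, 5, 0, 0])]
        table = build_overlap_table(clusters, spike_in_sequences=[spike])
        assert table.total == 1  # spike excluded from overlap counting
        assert table.spike_in_report[spike].tolist() == [100, 50, 10, 5]

    @given(st.lists(st.tuples(*[st.integers(0, 50)] * 4), min_size=1, max_size=30))
    def test_partition_invariant(self, count_rows):
        """Every retained barcode lands in exactly one exactly-k bucket."""
        bases = "ACGT"
        clusters = []
        for i, counts in enumerate(count_rows):
            if sum(counts) == 0:
                continue
            seq = "".join(bases[(i >> (2 * p)) & 3] for p in range(15)) + "A" * 15
            clusters.append(_cluster(seq, list(counts)))
        table = build_overlap_table(clusters)
        assert sum(table.exactly.values()) == table.total
        assert table.total == len(clusters)
        # count(>=k) non-increasing in k
        ge = [sum(v for kk, v in table.exactly.items() if kk >= k) for k in range(1, 5)]
        assert ge == sorted(ge, reverse=True)
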