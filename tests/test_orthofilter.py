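"""Paralog classification and orthogroup filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthocoal.orthofilter import (
    ClusterSet,
    ContigRecord,
    PairwiseAlignment,
    classify_pair,
    decide_orthogroups,
    filter_clusters,
    robust_orthogroups,
    select_component_representative,
)


def contig(cid, orf_len, total=None, component="cmp1"):
    total = total or orf_len + 60
    return ContigRecord(cid, "tA", total, 0, orf_len, component)


class TestRepresentative:
    def test_singleton(self):
        assert select_component_representative([contig("x", 300)]) == "x"

    def test_longest_orf_wins(self):
        contigs = [contig("a", 300), contig("b", 900), contig("c", 450)]
        assert select_component_representative(contigs) == "b"

    def test_tie_broken_by_contig_length_then_id(self):
        contigs = [contig("a", 600, total=800), contig("b", 600, total=1200)]
        assert select_component_representative(contigs) == "b"
        contigs = [contig("b", 600, total=800), contig("a", 600, total=800)]
        assert select_component_representative(contigs) == "a"

    def test_tie_break_rule_ordering_exhaustive(self):
        """Whatever the input order, the winner maximises (orf, length) and
        minimises id, verified against a brute-force sort."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            contigs = [
                contig(f"c{i}", 3 * rng.integers(50, 60),
                       total=int(rng.integers(200, 400)))
                for i in range(5)
            ]
            want = sorted(
                contigs, key=lambda c: (-c.orf_length, -c.sequence_length, c.contig_id)
            )[0].contig_id
            order = rng.permutation(5)
            assert select_component_representative([contigs[i] for i in order]) == want

    def test_empty_component_raises(self):
        with pytest.raises(ValueError, match="empty component"):
            select_component_representative([])


def aln(row_a, row_b):
    return PairwiseAlignment.from_strings("a", "b", row_a, row_b)


def spread_mismatches(n, n_mismatch):
    """n columns of A/A with n_mismatch evenly spread A/C columns."""
    row_a = ["A"] * n
    row_b = ["A"] * n
    step = n // n_mismatch
    for i in range(n_mismatch):
        row_b[i * step] = "C"
    return "".join(row_a), "".join(row_b)


class TestClassifyPair:
    def test_identical_sequences_are_compatible(self):
        call = classify_pair(aln("A" * 1000, "A" * 1000))
        assert call.verdict == "compatible"
        assert call.mean_identity == 1.0

    def test_uniform_divergence_below_threshold_is_paralog(self):
        call = classify_pair(aln(*spread_mismatches(1000, 30)))
        assert call.mean_identity == pytest.approx(0.970)
        assert call.verdict == "paralog"

    def test_internal_low_identity_tract_flags_subgene_paralogy(self):
        """90 columns at 60% identity inside an otherwise perfect alignment:
        the mean stays above threshold but the tract rule fires."""
        row_a = ["A"] * 1000
        row_b = ["A"] * 1000
        for i in range(455, 545):  # 90 columns, 40% mismatching within
            if (i - 455) % 5 < 2:
                row_b[i] = "G"
        call = classify_pair(aln("".join(row_a), "".join(row_b)))
        assert call.mean_identity == pytest.approx(0.964)
        assert call.verdict == "paralog_subgene"
        (start, end), = call.flagged_internal_tracts
        assert start > 0 and end < 1000

    def test_terminal_tract_is_excluded_from_mean(self):
        """A badly aligned start (structural variation) does not poison the
        identity estimate."""
        row_a = "A" * 500
        row_b = "G" * 40 + "A" * 460
        call = classify_pair(aln(row_a, row_b))
        assert call.verdict == "compatible"
        assert call.mean_identity == 1.0
        assert call.excluded_terminal_columns >= 40

    def test_gap_only_overlap_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            classify_pair(aln("AAA---", "---AAA"))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(120, 400))
        row_a = "".join(rng.choice(list("ACGT-"), n, p=[0.23] * 4 + [0.08]))
        row_b = "".join(rng.choice(list("ACGT-"), n, p=[0.23] * 4 + [0.08]))
        if not any(a != "-" and b != "-" for a, b in zip(row_a, row_b)):
            return
        fwd = classify_pair(aln(row_a, row_b))
        rev = classify_pair(PairwiseAlignment.from_strings("b", "a", row_b, row_a))
        assert fwd.verdict == rev.verdict
        assert fwd.mean_identity == pytest.approx(rev.mean_identity)

    def test_raising_threshold_never_rescues_a_paralog(self):
        pair = aln(*spread_mismatches(1000, 30))
        low = classify_pair(pair, identity_threshold=0.95)
        high = classify_pair(pair, identity_threshold=0.99)
        if low.verdict != "compatible":
            assert high.verdict != "compatible"


def members(*specs):
    return tuple(specs)


class TestFilterClusters:
    TAXA = {"tA", "tB", "tC", "tD"}

    def make_clusters(self):
        good = members(("tA", "a1"), ("tB", "b1"), ("tC", "c1"), ("tD", "d1"),
                       ("out", "o1"), ("out", "o2"))
        return ClusterSet(1.5, {"good": good})

    def test_clean_cluster_retained(self):
        decisions = filter_clusters(self.make_clusters(), set(), self.TAXA, "out", 3)
        assert decisions[0].retained

    def test_paralog_pair_excludes(self):
        cs = ClusterSet(
            1.5,
            {"c": members(("tA", "a1"), ("tA", "a2"), ("tB", "b1"),
                          ("tC", "c1"), ("tD", "d1"))},
        )
        pairs = {frozenset({("tA", "a1"), ("tA", "a2")})}
        (d,) = filter_clusters(cs, pairs, self.TAXA, "out", 3)
        assert d.exclusion_reasons == {"has_paralog_pair"}

    def test_planted_toy_bookkeeping(self):
        """Six defective clusters (one violation each, one with two) plus two
        clean: exactly two survive; reason tallies match the plant."""
        pairs = {frozenset({("tA", "p1"), ("tA", "p2")})}
        clusters = {
            "pp": members(("tA", "p1"), ("tA", "p2"), ("tB", "b0"),
                          ("tC", "c0"), ("tD", "d0")),
            "miss1": members(("tA", "a1"), ("tB", "b1"), ("tC", "c1")),
            "miss2": members(("tA", "a2"), ("tB", "b2"), ("tD", "d2")),
            "bb": members(("tA", "a3"), ("tB", "b3"), ("tC", "c3"), ("tD", "d3"),
                          ("out", "o1"), ("out", "o2"), ("out", "o3"), ("out", "o4")),
            "double": members(("tA", "a4"), ("tB", "b4"),
                              ("out", "o5"), ("out", "o6"), ("out", "o7"),
                              ("out", "o8")),
            "miss3": members(("tB", "b5"), ("tC", "c5"), ("tD", "d5")),
            "ok1": members(("tA", "a6"), ("tB", "b6"), ("tC", "c6"), ("tD", "d6")),
            "ok2": members(("tA", "a7"), ("tB", "b7"), ("tC", "c7"), ("tD", "d7"),
                           ("out", "o9")),
        }
        decisions = filter_clusters(
            ClusterSet(1.5, clusters), pairs, self.TAXA, "out", 3
        )
        by_id = {d.cluster_id: d for d in decisions}
        assert {d.cluster_id for d in decisions if d.retained} == {"ok1", "ok2"}
        reason_counts = {}
        for d in decisions:
            for r in d.exclusion_reasons:
                reason_counts[r] = reason_counts.get(r, 0) + 1
        assert reason_counts == {
            "has_paralog_pair": 1, "missing_taxon": 4, "excess_backbone": 2,
        }
        # overlap allowed: the per-reason sum exceeds the number excluded
        assert by_id["double"].exclusion_reasons == {
            "missing_taxon", "excess_backbone",
        }
        excluded = sum(1 for d in decisions if not d.retained)
        assert sum(reason_counts.values()) >= excluded == 6

    def test_empty_cluster_set(self):
        assert filter_clusters(ClusterSet(1.5, {}), set(), {"tA"}, "out", 3) == []


class TestRobustness:
    def base(self, inflation=1.5):
        return ClusterSet(
            inflation,
            {
                f"c{i}": members(("tA", f"a{i}"), ("tB", f"b{i}"), ("out", f"o{i}"))
                for i in range(10)
            },
        )

    def test_identical_clusterings_all_robust(self):
        out = robust_orthogroups(
            [f"c{i}" for i in range(10)], self.base(),
            [self.base(0.5), self.base(5.0)], backbone_taxon="out",
        )
        assert out == {f"c{i}" for i in range(10)}

    def test_split_cluster_not_robust(self):
        alt = self.base(5.0)
        clusters = dict(alt.clusters)
        c0 = clusters.pop("c0")
        clusters["c0x"] = c0[:1]
        clusters["c0y"] = c0[1:]
        alt = ClusterSet(5.0, clusters)
        out = robust_orthogroups(["c0", "c1"], self.base(), [alt], "out")
        assert out == {"c1"}

    def test_three_perturbed_of_ten(self):
        alt_clusters = dict(self.base(5.0).clusters)
        for i in range(3):
            c = alt_clusters.pop(f"c{i}")
            alt_clusters[f"c{i}x"] = c[:1]
            alt_clusters[f"c{i}y"] = c[1:]
        alt = ClusterSet(5.0, alt_clusters)
        survivors = [f"c{i}" for i in range(10)]
        out = robust_orthogroups(survivors, self.base(), [alt], "out")
        assert len(out) == 7
        assert out <= set(survivors)

    def test_backbone_moves_are_ignored(self):
        alt_clusters = dict(self.base(3.0).clusters)
        # move a backbone contig between clusters: non-backbone cores unchanged
        alt_clusters["c0"] = members(("tA", "a0"), ("tB", "b0"))
        alt_clusters["c1"] = members(("tA", "a1"), ("tB", "b1"), ("out", "o1"),
                                     ("out", "o0"))
        out = robust_orthogroups(["c0", "c1"], self.base(),
                                 [ClusterSet(3.0, alt_clusters)], "out")
        assert out == {"c0", "c1"}

    def test_missing_contig_counts_as_change(self):
        alt_clusters = dict(self.base(5.0).clusters)
        alt_clusters["c0"] = members(("tB", "b0"), ("out", "o0"))  # a0 vanished
        out = robust_orthogroups(["c0"], self.base(),
                                 [ClusterSet(5.0, alt_clusters)], "out")
        assert out == set()

    def test_adding_alternates_never_enlarges(self):
        survivors = [f"c{i}" for i in range(10)]
        alt1 = self.base(0.5)
        alt_clusters = dict(self.base(5.0).clusters)
        c = alt_clusters.pop("c4")
        alt_clusters["c4x"] = c[:1]
        alt_clusters["c4y"] = c[1:]
        alt2 = ClusterSet(5.0, alt_clusters)
        with_one = robust_orthogroups(survivors, self.base(), [alt1], "out")
        with_two = robust_orthogroups(survivors, self.base(), [alt1, alt2], "out")
        assert with_two <= with_one

    def test_no_alternates_raises(self):
        with pytest.raises(ValueError):
            robust_orthogroups(["c0"], self.base(), [], "out")


def test_contig_in_two_clusters_rejected():
    with pytest.raises(ValueError, match="more than one cluster"):
        ClusterSet(1.5, {"c1": (("tA", "x"),), "c2": (("tA", "x"),)})
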