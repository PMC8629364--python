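import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sloperon.core_io import GeneModel, RepeatTrack
from sloperon.operon_inference import (adjacent_pairs, adjust_pairs,
                                       call_operons, distance_distributions,
                                       find_modes, operon_summary,
                                       repeat_adjusted_distance,
                                       summary_fractions)


def _gene(gid, strand, start, end, scaffold="scf1", ts="nonTS"):
    return GeneModel(gid, scaffold, strand, start, end, ((start, end),), ts_status=ts)


def boolean_array_coverage(gap_start, gap_end, intervals):
    """Independent per-base oracle for repeat coverage of an interval."""
    arr = np.zeros(max(0, gap_end - gap_start), dtype=bool)
    for s, e in intervals:
        lo, hi = max(s, gap_start), min(e, gap_end)
        if lo < hi:
            arr[lo - gap_start:hi - gap_start] = True
    return int(arr.sum())


class TestAdjacentPairs:
    def test_consecutive_same_strand_pairs_with_raw_distances(self):
        genes = [_gene("A", "+", 0, 100), _gene("B", "+", 300, 400), _gene("C", "+", 900, 1000)]
        pairs = adjacent_pairs(genes)
        assert [(p.upstream_gene, p.downstream_gene, p.raw_distance) for p in pairs] == \
               [("A", "B", 200), ("B", "C", 500)]

    def test_opposite_strand_gene_interrupts_pair(self):
        genes = [_gene("A", "+", 0, 100), _gene("X", "-", 150, 250), _gene("B", "+", 300, 400)]
        assert adjacent_pairs(genes) == []

    def test_minus_strand_upstream_is_rightmost_gene(self):
        genes = [_gene("B", "-", 0, 100), _gene("A", "-", 300, 400)]
        (p,) = adjacent_pairs(genes)
        assert (p.upstream_gene, p.downstream_gene, p.raw_distance) == ("A", "B", 200)

    def test_nested_genes_are_skipped_entirely(self):
        genes = [_gene("A", "+", 0, 1000), _gene("N", "+", 100, 200), _gene("B", "+", 1200, 1300)]
        pairs = adjacent_pairs(genes)
        assert [(p.upstream_gene, p.downstream_gene) for p in pairs] == [("A", "B")]

    def test_overlapping_same_strand_neighbours_get_zero_distance(self):
        genes = [_gene("A", "+", 0, 150), _gene("B", "+", 100, 300)]
        (p,) = adjacent_pairs(genes)
        assert p.raw_distance == 0

    def test_categories_follow_transcription_order(self):
        genes = [_gene("A", "+", 0, 100, ts="nonTS"), _gene("B", "+", 200, 300, ts="TS")]
        (p,) = adjacent_pairs(genes)
        assert p.category == "nonTS->TS"
        genes = [_gene("B", "-", 0, 100, ts="TS"), _gene("A", "-", 200, 300, ts="nonTS")]
        (p,) = adjacent_pairs(genes)
        assert p.category == "nonTS->TS"


class TestRepeatAdjustment:
    def test_union_coverage_is_subtracted(self):
        genes = [_gene("A", "+", 0, 100), _gene("B", "+", 600, 700)]
        (pair,) = adjacent_pairs(genes)  # gap [100, 600)
        repeats = RepeatTrack({"scf1": [(50, 200), (150, 350), (550, 700)]})
        # oracle: covered = [100,350) + [550,600) = 250 + 50 = 300
        assert boolean_array_coverage(100, 600, repeats.intervals["scf1"]) == 300
        assert repeat_adjusted_distance(pair, repeats) == 200

    def test_no_repeats_is_identity_and_full_cover_floors_at_zero(self):
        genes = [_gene("A", "+", 0, 100), _gene("B", "+", 600, 700)]
        (pair,) = adjacent_pairs(genes)
        assert repeat_adjusted_distance(pair, RepeatTrack()) == pair.raw_distance
        assert repeat_adjusted_distance(pair, RepeatTrack({"scf1": [(0, 10000)]})) == 0

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_adjustment_equals_per_base_boolean_oracle(self, seed):
        rng = random.Random(seed)
        gap_start = rng.randrange(0, 500)
        gap_end = gap_start + rng.randrange(1, 800)
        genes = [_gene("A", "+", max(0, gap_start - 100), gap_start),
                 _gene("B", "+", gap_end, gap_end + 100)]
        (pair,) = adjacent_pairs(genes)
        ivs = [(s, s + rng.randrange(1, 300))
               for s in (rng.randrange(0, 1500) for _ in range(rng.randrange(0, 12)))]
        expected = max(0, pair.raw_distance - boolean_array_coverage(gap_start, gap_end, ivs))
        assert repeat_adjusted_distance(pair, RepeatTrack({"scf1": list(ivs)})) == expected


class TestModes:
    def test_bimodal_lognormal_mixture_recovers_both_modes(self):
        rng = np.random.default_rng(42)
        short = rng.lognormal(np.log(100), 0.4, 500)
        long = rng.lognormal(np.log(5000), 0.4, 500)
        modes, valley = find_modes(np.concatenate([short, long]).astype(int))
        assert len(modes) >= 2
        assert 50 <= modes[0] <= 200
        assert 300 <= valley <= 3000

    def test_degenerate_samples(self):
        modes, valley = find_modes([100] * 50)
        assert modes == [100] and valley is None
        assert find_modes([]) == ([], None)
        assert find_modes([7]) == ([], None)

    def test_distributions_group_by_category_with_mixed_merge(self):
        genes = [_gene("A", "+", 0, 100, ts="TS"), _gene("B", "+", 200, 300, ts="nonTS"),
                 _gene("C", "+", 400, 500, ts="TS"), _gene("D", "+", 600, 700, ts="TS")]
        pairs = adjacent_pairs(genes)
        cats = {d.category: len(d.distances) for d in distance_distributions(pairs)}
        assert cats == {"mixed": 2, "TS->TS": 1}
        cats = {d.category for d in distance_distributions(pairs, merge_mixed=False)}
        assert cats == {"TS->nonTS", "nonTS->TS", "TS->TS"}


class TestOperonCalling:
    def test_ts_pair_under_threshold_forms_operon(self):
        genes = [_gene("A", "+", 0, 100, ts="TS"), _gene("B", "+", 200, 300, ts="TS")]
        (op,) = call_operons(genes)
        assert op.genes == ("A", "B") and op.size == 2 and not op.starts_nonTS
        assert op.span_length == 300

    def test_nonts_gene_can_only_start_a_chain(self):
        genes = [_gene("A", "+", 0, 100, ts="nonTS"), _gene("B", "+", 300, 400, ts="TS"),
                 _gene("C", "+", 700, 800, ts="TS")]
        (op,) = call_operons(genes)
        assert op.genes == ("A", "B", "C") and op.starts_nonTS

    def test_nonts_downstream_gene_breaks_the_chain(self):
        genes = [_gene("A", "+", 0, 100, ts="TS"), _gene("B", "+", 150, 250, ts="nonTS")]
        assert call_operons(genes) == []

    def test_distance_at_or_above_threshold_does_not_link(self):
        genes = [_gene("A", "+", 0, 100, ts="TS"), _gene("B", "+", 1100, 1200, ts="TS")]
        assert call_operons(genes, threshold=1000) == []
        assert len(call_operons(genes, threshold=1001)) == 1

    def test_repeat_adjustment_rescues_inflated_gap(self):
        genes = [_gene("A", "+", 0, 100, ts="TS"), _gene("B", "+", 2100, 2200, ts="TS")]
        repeats = RepeatTrack({"scf1": [(150, 2050)]})  # adjusted gap 100
        assert call_operons(genes, repeats=None) == []
        (op,) = call_operons(genes, repeats=repeats)
        assert op.genes == ("A", "B")

    def test_membership_invariant_under_scaffold_mirror(self, synth_genes):
        genes = [g for g in synth_genes if g.scaffold == "scaffold_1"][:400]
        length = max(g.end for g in genes) + 10
        mirrored = [GeneModel(g.gene_id, g.scaffold,
                              "-" if g.strand == "+" else "+",
                              length - g.end, length - g.start,
                              tuple(sorted((length - e, length - s) for s, e in g.exons)),
                              ts_status=g.ts_status)
                    for g in genes]
        fwd = call_operons(genes)
        rev = call_operons(mirrored)
        # mirroring flips strands, so transcription order (and hence the
        # gene tuples) must be identical
        assert {o.genes for o in fwd} == {o.genes for o in rev}
        assert len(fwd) == len(rev) > 0

    def test_raising_threshold_never_removes_genes_from_operons(self, synth_genes, synth_dataset):
        from sloperon.core_io import parse_repeat_track
        repeats = parse_repeat_track(synth_dataset.paths["repeats"])
        counts = []
        for thr in (200, 500, 1000, 5000, 20000):
            ops = call_operons(synth_genes, repeats=repeats, threshold=thr)
            counts.append(sum(o.size for o in ops))
        assert counts == sorted(counts)


def test_operon_summary_tallies_and_fractions():
    genes = [_gene("A", "+", 0, 100, ts="TS"), _gene("B", "+", 200, 300, ts="TS"),
             _gene("C", "+", 600, 700, ts="TS"), _gene("D", "+", 900, 1000, ts="TS"),
             _gene("E", "-", 5000, 5100, ts="TS", scaffold="scf2"),
             _gene("F", "-", 4800, 4900, ts="TS", scaffold="scf2")]
    ops = call_operons(genes)
    summary = operon_summary(ops, n_genes_total=10, n_ts_total=6)
    assert summary["size_histogram"] == {2: 1, 4: 1}
    assert summary["genes_in_operons"] == 6
    assert summary["pct_all_genes_in_operons"] == pytest.approx(60.0)
    assert summary["pct_ts_genes_in_operons"] == pytest.approx(100.0)
    assert summary_fractions(0, 0) == {}
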