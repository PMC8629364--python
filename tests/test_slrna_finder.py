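import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sloperon.core_io import GeneModel
from sloperon.seqtools import revcomp
from sloperon.sl_tagging import DEFAULT_SL_SEQ
from sloperon.slrna_finder import (call_slrna_genes, count_hairpins,
                                   find_sl_seed_hits, fold_max_pairs)
from sloperon.synth_data import design_slrna_construct

SL = DEFAULT_SL_SEQ

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_all_structures(seq, min_loop=3):
    """Exhaustive enumeration of every nested structure (independent oracle)."""
    seq = seq.upper().replace("T", "U")

    def rec(i, j):
        if i > j:
            yield frozenset()
            return
        yield from rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield left | right | {(i, k)}

    return max(len(s) for s in rec(0, len(seq) - 1))


class TestFold:
    def test_simple_hairpin(self):
        assert fold_max_pairs("GGGAAACCC", min_loop=3) == (3, "(((...)))")

    def test_unpairable_sequence(self):
        assert fold_max_pairs("AAAAAA") == (0, "......")

    def test_min_loop_blocks_short_hairpins(self):
        assert fold_max_pairs("GC", min_loop=3) == (0, "..")

    def test_rejects_non_nucleotides(self):
        with pytest.raises(ValueError):
            fold_max_pairs("ACGX")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_dp_equals_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 12)
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        pairs, struct = fold_max_pairs(seq)
        assert pairs == enumerate_all_structures(seq)
        assert struct.count("(") == pairs  # traceback realizes the optimum


class TestHairpins:
    @pytest.mark.parametrize("structure,expected", [
        ("(((...)))", 1),
        ("((..))..((...))", 2),
        ("......", 0),
        ("((..((...))..((...))..))", 2),
    ])
    def test_counts(self, structure, expected):
        assert count_hairpins(structure) == expected

    def test_unbalanced_raises(self):
        with pytest.raises(ValueError):
            count_hairpins("(((..)")
        with pytest.raises(ValueError):
            count_hairpins("..)(..")


class TestSeedSearch:
    def test_planted_copies_found_on_both_strands(self):
        rng = random.Random(0)
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        genome = {"s1": bg(500) + SL + bg(500) + revcomp(SL) + bg(300),
                  "s2": bg(200) + SL + bg(100)}
        hits = find_sl_seed_hits(genome, SL)
        assert [(h[0], h[1]) for h in hits] == [("s1", "+"), ("s1", "-"), ("s2", "+")]
        assert hits[0][2] == 500 and hits[1][2] == 1035

    def test_no_copies_and_one_mismatch_not_reported(self):
        rng = random.Random(1)
        bg = "".join(rng.choice("ACGT") for _ in range(2000))
        assert find_sl_seed_hits({"s": bg}, SL) == []
        mutated = SL[:10] + ("A" if SL[10] != "A" else "C") + SL[11:]
        assert find_sl_seed_hits({"s": bg + mutated + bg}, SL) == []

    def test_minus_hits_equal_plus_hits_of_reverse_complement(self):
        rng = random.Random(2)
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        genome = bg(300) + revcomp(SL) + bg(400) + SL + bg(200)
        fwd = find_sl_seed_hits({"s": genome}, SL)
        rc = find_sl_seed_hits({"s": revcomp(genome)}, SL)
        n = len(genome)
        mapped = sorted(("s", "-" if strand == "+" else "+", n - pos - len(SL))
                        for _, strand, pos in rc)
        assert sorted(fwd) == mapped


class TestCandidateCalling:
    def _embed(self, insert, strand="+", margin=400, seed=3):
        rng = random.Random(seed)
        bg = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        fwd = insert if strand == "+" else revcomp(insert)
        return {"scf": bg(margin) + fwd + bg(margin)}

    def test_designed_construct_is_accepted_on_either_strand(self):
        construct = design_slrna_construct()
        for strand in "+-":
            (c,) = call_slrna_genes(self._embed(construct, strand), SL)
            assert c.accepted and c.strand == strand
            assert c.candidate_seq == construct
            assert c.donor_ok and c.sm_site is not None and c.hairpin_count >= 3

    def test_missing_donor_is_rejected(self):
        construct = design_slrna_construct(donor="AAAAA")
        (c,) = call_slrna_genes(self._embed(construct), SL)
        assert not c.accepted and not c.donor_ok and "donor" in c.reason

    def test_missing_sm_site_is_rejected(self):
        construct = design_slrna_construct(sm_word="ACGACGACG")
        (c,) = call_slrna_genes(self._embed(construct), SL)
        assert not c.accepted and c.sm_site is None

    def test_seed_at_ts_gene_start_is_rejected_as_coding(self):
        construct = design_slrna_construct()
        genome = self._embed(construct)
        seed_start = 400
        gene = GeneModel("g1", "scf", "+", seed_start + 10, seed_start + 300,
                         ((seed_start + 10, seed_start + 300),), ts_status="TS")
        (c,) = call_slrna_genes(genome, SL, genes=[gene])
        assert not c.accepted and c.reason == "coding 5' end"
        # without the annotation the same candidate passes
        (c2,) = call_slrna_genes(genome, SL)
        assert c2.accepted

    def test_candidate_at_scaffold_edge_is_truncated(self):
        construct = design_slrna_construct()
        genome = {"scf": construct[:60]}  # seed present, tail missing
        (c,) = call_slrna_genes(genome, SL)
        assert len(c.candidate_seq) == 60 and not c.accepted
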