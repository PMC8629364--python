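import math
import random
from collections import Counter
from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sloperon.core_io import GeneModel
from sloperon.motif_finder import (dinucleotide_shuffle, discover_motifs,
                                   extract_junction_windows, fisher_enrichment)
from sloperon.seqtools import iupac_regex, revcomp


def hypergeom_tail(pos_with, pos_total, bg_with, bg_total):
    """Exact-fraction one-sided Fisher oracle via hypergeometric enumeration."""
    N, K, n = pos_total + bg_total, pos_with + bg_with, pos_total
    total = Fraction(0)
    for k in range(pos_with, min(n, K) + 1):
        if n - k <= N - K:
            total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))
    return total


class TestWindows:
    GENOME = {"scf": "".join(random.Random(0).choice("ACGT") for _ in range(2000))}

    def test_plus_strand_donor_and_acceptor_coordinates(self):
        g = GeneModel("g", "scf", "+", 100, 400, ((100, 200), (300, 400)))
        (don,) = extract_junction_windows([g], self.GENOME, 50, "cis_donor")
        (acc,) = extract_junction_windows([g], self.GENOME, 50, "cis_acceptor")
        assert don.seq == self.GENOME["scf"][150:250]
        assert acc.seq == self.GENOME["scf"][250:350]
        assert don.junction == 50

    def test_minus_strand_windows_are_reverse_complemented(self):
        g = GeneModel("g", "scf", "-", 100, 400, ((100, 200), (300, 400)))
        (don,) = extract_junction_windows([g], self.GENOME, 50, "cis_donor")
        (acc,) = extract_junction_windows([g], self.GENOME, 50, "cis_acceptor")
        assert don.seq == revcomp(self.GENOME["scf"][250:350])
        assert acc.seq == revcomp(self.GENOME["scf"][150:250])

    def test_trans_acceptor_window_at_first_exon_boundary(self):
        g = GeneModel("g", "scf", "+", 100, 200, ((100, 200),), ts_status="TS")
        (w,) = extract_junction_windows([g], self.GENOME, 50, "trans_acceptor")
        assert w.seq == self.GENOME["scf"][50:150]
        nonts = GeneModel("g2", "scf", "+", 100, 200, ((100, 200),), ts_status="nonTS")
        assert extract_junction_windows([nonts], self.GENOME, 50, "trans_acceptor") == []

    def test_single_exon_gene_has_no_cis_windows(self):
        g = GeneModel("g", "scf", "+", 100, 200, ((100, 200),))
        assert extract_junction_windows([g], self.GENOME, 50, "cis_donor") == []

    def test_edge_clipped_windows_are_dropped(self):
        g = GeneModel("g", "scf", "+", 10, 110, ((10, 110),), ts_status="TS")
        assert extract_junction_windows([g], self.GENOME, 50, "trans_acceptor") == []


class TestFisher:
    def test_textbook_values(self):
        assert fisher_enrichment(5, 5, 0, 5) == pytest.approx(1 / 252)
        assert fisher_enrichment(3, 10, 3, 10) >= 0.5
        assert fisher_enrichment(0, 10, 5, 10) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(-1, 5, 0, 5)

    def test_agrees_with_hypergeometric_enumeration_small_tables(self):
        for pos_total in range(1, 8):
            for bg_total in range(1, 8):
                for pos_with in range(pos_total + 1):
                    for bg_with in range(bg_total + 1):
                        expected = float(hypergeom_tail(pos_with, pos_total, bg_with, bg_total))
                        got = fisher_enrichment(pos_with, pos_total, bg_with, bg_total)
                        assert got == pytest.approx(expected, rel=1e-9)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_dinucleotide_shuffle_preserves_dinucleotide_multiset(seed):
    rng = random.Random(seed)
    n = rng.randint(3, 60)
    seq = "".join(rng.choice("ACGT") for _ in range(n))
    shuffled = dinucleotide_shuffle(seq, random.Random(seed + 1))
    assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


class TestDiscovery:
    @staticmethod
    def _windows(n, plant, rate, rng, length=60, offset=30):
        out = []
        for i in range(n):
            s = "".join(rng.choice("ACGT") for _ in range(length))
            if rng.random() < rate:
                s = s[:offset] + plant + s[offset + len(plant):]
            out.append(s)
        return out

    def test_planted_donor_word_is_recovered(self):
        rng = random.Random(5)
        pos = self._windows(200, "GTAAG", 0.8, rng)
        (m, *_) = discover_motifs(pos, k_range=(4, 6), max_motifs=1, seed=1)
        planted = [s for s in pos if s[30:35] == "GTAAG"]
        matched = sum(1 for s in planted if iupac_regex(m.word).search(s))
        assert matched / len(planted) >= 0.95
        assert m.e_value <= 1e-10
        assert m.positional_mode == 30
        # reported containment equals an independent scan
        assert m.pos_with == sum(1 for s in pos if iupac_regex(m.word).search(s))

    def test_null_case_reports_nothing(self):
        rng = random.Random(6)
        pos = self._windows(100, "", 0.0, rng)
        assert discover_motifs(pos, background=list(pos), k_range=(3, 5),
                               max_motifs=2, e_cutoff=0.05, seed=1) == []

    def test_planted_acceptor_word_sits_at_the_junction(self):
        rng = random.Random(7)
        # CAG immediately left of the junction point (offset 30)
        pos = self._windows(200, "CAG", 0.9, rng, offset=27)
        (m, *_) = discover_motifs(pos, k_range=(3, 4), max_motifs=1, seed=1)
        assert iupac_regex(m.word).match("CAG") or "CAG" in m.word
        assert abs(m.positional_mode - 27) <= 1

    def test_k_max_longer_than_windows_rejected(self):
        with pytest.raises(ValueError):
            discover_motifs(["ACGT"], k_range=(3, 10), seed=1)
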