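"""Splice-junction window extraction and discriminative motif enrichment.

Junction windows are genomic sequences centered on splice boundaries:
cis-donor (exon -> intron), cis-acceptor (intron -> exon), and the
trans-splice acceptor at the 5' boundary of the first exon of
trans-spliced genes, whose upstream side is the outron.  All windows are
normalized to the transcript's forward orientation.

Motif discovery is a simplified discriminative enumeration: all exact
k-mers are scored against a background (by default a per-sequence
dinucleotide shuffle of the positives) with a one-sided Fisher exact test
on per-sequence containment counts, Bonferroni-corrected by the number of
words tested; the best word is then greedily generalized one position at a
time over two-letter IUPAC codes, reported if significant, masked out, and
the search repeats.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact

from .core_io import GeneModel
from .seqtools import iupac_regex, revcomp

log = logging.getLogger(__name__)

SITE_TYPES = ("cis_donor", "cis_acceptor", "trans_acceptor")

_TWO_LETTER_CODES = ("R", "Y", "S", "W", "K", "M")


@dataclass(frozen=True)
class JunctionWindow:
    site_type: str
    seq: str        # 2*flank nt, transcript forward orientation
    gene_id: str
    junction: int   # offset of the junction point within seq (== flank)


@dataclass
class MotifResult:
    word: str       # IUPAC degenerate word
    pos_with: int   # positive sequences containing >=1 occurrence
    pos_total: int
    bg_with: int
    bg_total: int
    p_value: float
    e_value: float
    positional_mode: int  # most frequent match start offset in positives


def extract_junction_windows(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    flank: int = 50,
    site_type: str = "cis_donor",
) -> list[JunctionWindow]:
    """Windows of 2*flank nt around splice junctions of one site type.

    Minus-strand genes are reverse-complemented so the transcript 5'->3'
    direction reads left to right; windows clipped by a scaffold edge are
    dropped with a warning.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site_type {site_type!r}")
    windows: list[JunctionWindow] = []
    dropped = 0

    def grab(scaffold: str, point: int, strand: str, gene_id: str) -> None:
        nonlocal dropped
        s = genome[scaffold]
        lo, hi = point - flank, point + flank
        if lo < 0 or hi > len(s):
            dropped += 1
            return
        seq = s[lo:hi]
        if strand == "-":
            seq = revcomp(seq)
        windows.append(JunctionWindow(site_type, seq, gene_id, flank))

    for g in genes:
        if g.scaffold not in genome:
            continue
        if site_type == "trans_acceptor":
            if g.ts_status != "TS":
                continue
            grab(g.scaffold, g.start if g.strand == "+" else g.end, g.strand, g.gene_id)
            continue
        n = len(g.exons)
        if n < 2:
            continue
        if g.strand == "+":
            points = ([e for (_, e) in g.exons[:-1]] if site_type == "cis_donor"
                      else [s for (s, _) in g.exons[1:]])
        else:
            points = ([s for (s, _) in g.exons[1:]] if site_type == "cis_donor"
                      else [e for (_, e) in g.exons[:-1]])
        for point in points:
            grab(g.scaffold, point, g.strand, g.gene_id)
    if dropped:
        log.warning("%d %s windows clipped at scaffold edges were dropped", dropped, site_type)
    return windows


def write_windows_fasta(windows: Sequence[JunctionWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            fh.write(f">{w.gene_id}|{w.site_type}|{i}\n{w.seq}\n")


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle preserving the dinucleotide multiset (Euler-path method)."""
    if len(seq) <= 2:
        return seq
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    inner = [v for v in adj if v != last]
    # choose per-vertex "last edges" forming a tree into the end vertex
    while True:
        last_edges = {v: rng.choice(adj[v]) for v in inner}
        ok = True
        for v in inner:
            seen, u = set(), v
            while u != last and u in last_edges and u not in seen:
                seen.add(u)
                u = last_edges[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    remaining = {v: list(edges) for v, edges in adj.items()}
    for v, e in last_edges.items():
        remaining[v].remove(e)
    for v in remaining:
        rng.shuffle(remaining[v])
    for v, e in last_edges.items():
        remaining[v].append(e)
    out = [first]
    u = first
    while len(out) < len(seq):
        u = remaining[u].pop(0)
        out.append(u)
    return "".join(out)


def fisher_enrichment(pos_with: int, pos_total: int, bg_with: int, bg_total: int) -> float:
    """One-sided (enrichment) Fisher exact p from the 2x2 containment table."""
    for v in (pos_with, pos_total, bg_with, bg_total):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if pos_with > pos_total or bg_with > bg_total:
        raise ValueError("with-counts exceed totals")
    table = [[pos_with, pos_total - pos_with], [bg_with, bg_total - bg_with]]
    return float(fisher_exact(table, alternative="greater")[1])


def _log_fisher(pos_with: int, pos_total: int, bg_with: int, bg_total: int) -> float:
    """Natural-log one-sided Fisher p, exact in log space.

    Used for ranking candidate words whose p-values underflow double
    precision; summed from log hypergeometric pmf terms.
    """
    N = pos_total + bg_total
    K = pos_with + bg_with

    def logC(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    lo = max(pos_with, pos_total - (N - K))
    hi = min(pos_total, K)
    ks = np.arange(lo, hi + 1)
    terms = logC(K, ks) + logC(N - K, pos_total - ks) - logC(N, pos_total)
    return float(logsumexp(terms))


def _containment_counts(seqs: Sequence[str], k: int) -> Counter:
    counts: Counter = Counter()
    for s in seqs:
        counts.update({s[i:i + k] for i in range(len(s) - k + 1)})
    counts = Counter({w: c for w, c in counts.items() if "N" not in w})
    return counts


def _regex_with(seqs: Sequence[str], word: str) -> int:
    pat = iupac_regex(word)
    return sum(1 for s in seqs if pat.search(s))


def _positional_mode(seqs: Sequence[str], word: str) -> int:
    pat = iupac_regex(word)
    starts = Counter()
    for s in seqs:
        m = pat.search(s)
        if m:
            starts[m.start()] += 1
    if not starts:
        return -1
    # most frequent start; ties toward the smaller offset
    best = max(sorted(starts), key=lambda o: starts[o])
    return best


def discover_motifs(
    positives: Sequence[JunctionWindow] | Sequence[str],
    background: Sequence[JunctionWindow] | Sequence[str] | None = None,
    k_range: tuple[int, int] = (3, 8),
    max_motifs: int = 3,
    e_cutoff: float = 0.05,
    seed: int = 0,
) -> list[MotifResult]:
    """Ranked enriched degenerate words in the positive windows.

    When no background is given, one is built by a seeded per-sequence
    dinucleotide shuffle of the positives.  Counting is per-sequence
    containment (a window counts once however many occurrences it holds).
    """
    pos_seqs = [w.seq if isinstance(w, JunctionWindow) else str(w) for w in positives]
    if not pos_seqs:
        raise ValueError("positives must be non-empty")
    k_min, k_max = k_range
    if k_max > min(len(s) for s in pos_seqs):
        raise ValueError("k_max exceeds window length")
    if background is None:
        rng = random.Random(seed)
        bg_seqs = [dinucleotide_shuffle(s, rng) for s in pos_seqs]
    else:
        bg_seqs = [w.seq if isinstance(w, JunctionWindow) else str(w) for w in background]
    pos_seqs = list(pos_seqs)
    n_pos, n_bg = len(pos_seqs), len(bg_seqs)
    def score(pw: int, bw: int) -> float:
        """log p, falling back to exact log-space evaluation on underflow."""
        p = fisher_enrichment(pw, n_pos, bw, n_bg)
        if p > 1e-280:
            return float(np.log(p)) if p > 0 else _log_fisher(pw, n_pos, bw, n_bg)
        return _log_fisher(pw, n_pos, bw, n_bg)

    results: list[MotifResult] = []
    for _ in range(max_motifs):
        n_words = 0
        best_word: str | None = None
        best_logp = 1.0
        for k in range(k_min, k_max + 1):
            pos_counts = _containment_counts(pos_seqs, k)
            bg_counts = _containment_counts(bg_seqs, k)
            n_words += len(pos_counts)
            for word in sorted(pos_counts):
                logp = score(pos_counts[word], bg_counts.get(word, 0))
                if logp < best_logp:
                    best_word, best_logp = word, logp
        if best_word is None:
            break
        # greedy one-position IUPAC generalization
        word, logp = best_word, best_logp
        improved = True
        passes = 0
        while improved and passes < 3:
            improved = False
            passes += 1
            for i in range(len(word)):
                for code in _TWO_LETTER_CODES:
                    if word[i] == code:
                        continue
                    trial = word[:i] + code + word[i + 1:]
                    tl = score(_regex_with(pos_seqs, trial), _regex_with(bg_seqs, trial))
                    if tl < logp:
                        word, logp = trial, tl
                        improved = True
        pos_with = _regex_with(pos_seqs, word)
        bg_with = _regex_with(bg_seqs, word)
        p = fisher_enrichment(pos_with, n_pos, bg_with, n_bg)
        e_value = max(p, p * n_words)
        if e_value > e_cutoff:
            break
        results.append(MotifResult(
            word=word, pos_with=pos_with, pos_total=n_pos,
            bg_with=bg_with, bg_total=n_bg,
            p_value=p, e_value=e_value,
            positional_mode=_positional_mode(pos_seqs, word),
        ))
        # mask occurrences of the reported motif and continue
        pat = iupac_regex(word)
        pos_seqs = [pat.sub(lambda m: "N" * len(m.group()), s) for s in pos_seqs]
    return results


def write_motifs_tsv(motifs: Sequence[MotifResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("word\tpos_with\tpos_total\tbg_with\tbg_total\tp_value\te_value\tpositional_mode\n")
        for m in motifs:
            fh.write(f"{m.word}\t{m.pos_with}\t{m.pos_total}\t{m.bg_with}\t{m.bg_total}\t"
                     f"{m.p_value:.3e}\t{m.e_value:.3e}\t{m.positional_mode}\n")
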