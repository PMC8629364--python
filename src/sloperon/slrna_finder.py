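"""SL RNA gene discovery: exact seed search plus structural validation.

An SL RNA gene carries the 35-nt SL exon at its 5' end, a 5' donor splice
site (GTAAG) immediately after the exon, an Sm-protein binding site between
the later hairpins, and folds into the canonical three-hairpin secondary
structure.  Candidates are located by exact search for the SL sequence on
both genome strands and validated against these criteria.  The structural
check uses base-pair maximization (Nussinov-style dynamic programming with
Watson-Crick and GU wobble pairs): the acceptance criterion is the hairpin
topology, not folding free energy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from .core_io import GeneModel
from .seqtools import iupac_regex, revcomp, to_rna

log = logging.getLogger(__name__)

DEFAULT_DONOR = "GTAAG"
# Literature-standard Sm-site consensus on snRNAs (package default, configurable).
DEFAULT_SM = "RAUUUUNGR"

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@dataclass
class SLRNACandidate:
    scaffold: str
    strand: str
    seed_start: int            # forward-strand 0-based start of the exact seed match
    candidate_seq: str         # seed through seed + candidate_length, strand-oriented
    donor_ok: bool
    sm_site: tuple[int, str] | None  # (offset in candidate_seq, matched string)
    structure: str             # dot-bracket of the base-pair-maximal fold
    hairpin_count: int
    accepted: bool
    reason: str = ""
    region_start: int = 0      # forward-strand interval of the candidate
    region_end: int = 0


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold_max_pairs(seq: str, min_loop: int = 3) -> tuple[int, str]:
    """Maximum nested base pairing of an RNA (or DNA) sequence.

    Dynamic programming over Watson-Crick + GU pairs with hairpin loops of
    at least ``min_loop`` unpaired bases; deterministic traceback (leaving
    5' bases unpaired is preferred only when it costs nothing, and the
    partner index is the smallest optimal one).  Returns the pair count and
    the dot-bracket structure.
    """
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    rna = to_rna(seq)
    if not rna:
        raise ValueError("empty sequence")
    bad = set(rna) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {bad}")
    n = len(rna)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(rna[i], rna[k]):
                    cand = dp[i + 1][k - 1] + 1 + (dp[k + 1][j] if k + 1 <= j else 0)
                    if cand > best:
                        best = cand
            dp[i][j] = best
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i][j] == 0:
            continue
        if dp[i][j] == dp[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(rna[i], rna[k]):
                inner = dp[i + 1][k - 1]
                right = dp[k + 1][j] if k + 1 <= j else 0
                if dp[i][j] == inner + 1 + right:
                    struct[i], struct[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    if k + 1 <= j:
                        stack.append((k + 1, j))
                    break
    return dp[0][n - 1], "".join(struct)


def count_hairpins(structure: str) -> int:
    """Number of hairpin loops: pairs enclosing only unpaired positions."""
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced dot-bracket structure")
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket structure")
    return len(re.findall(r"\(\.*\)", structure))


def _load_genome(genome: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {k: str(v).upper() for k, v in genome.items()}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}


def find_sl_seed_hits(
    genome: str | Path | Mapping[str, str],
    sl_seq: str,
) -> list[tuple[str, str, int]]:
    """Every exact occurrence of the SL seed on either strand.

    ``seed_start`` is the forward-strand 0-based start of the matched
    region (for '-' hits this is the leftmost base of the reverse
    complement match).  Overlapping occurrences are all reported.
    """
    if len(sl_seq) < 8:
        raise ValueError("sl_seq must be at least 8 nt")
    seqs = _load_genome(genome)
    sl = sl_seq.upper()
    rc = revcomp(sl)
    hits: list[tuple[str, str, int]] = []
    for scaffold in sorted(seqs):
        s = seqs[scaffold]
        for query, strand in ((sl, "+"), (rc, "-")):
            start = s.find(query)
            while start != -1:
                hits.append((scaffold, strand, start))
                start = s.find(query, start + 1)
    hits.sort(key=lambda h: (h[0], h[2], h[1]))
    return hits


def call_slrna_genes(
    genome: str | Path | Mapping[str, str],
    sl_seq: str,
    candidate_length: int = 109,
    donor_pattern: str = DEFAULT_DONOR,
    sm_pattern: str = DEFAULT_SM,
    min_hairpins: int = 3,
    min_loop: int = 3,
    genes: Sequence[GeneModel] | None = None,
    coding_margin: int = 50,
) -> list[SLRNACandidate]:
    """Validate every exact SL-seed hit as an SL RNA gene candidate.

    A candidate is accepted iff the donor pattern sits immediately 3' of
    the seed, the Sm pattern occurs 3' of the seed within the candidate,
    the base-pair-maximal fold has at least ``min_hairpins`` hairpin
    loops, and — when a gene annotation is supplied — the seed does not
    coincide with the annotated 5' end of a trans-spliced protein-coding
    gene (within ``coding_margin`` bp), which would indicate a trans-
    spliced mRNA 5' end rather than the SL RNA gene itself.
    """
    if candidate_length < len(sl_seq) + 10:
        raise ValueError("candidate_length must be >= len(sl_seq) + 10")
    seqs = _load_genome(genome)
    sm_re = iupac_regex(sm_pattern)
    ts_starts: dict[str, list[int]] = {}
    if genes is not None:
        for g in genes:
            if g.ts_status == "TS":
                ts_starts.setdefault(g.scaffold, []).append(g.tss)
    out: list[SLRNACandidate] = []
    for scaffold, strand, seed_start in find_sl_seed_hits(seqs, sl_seq):
        s = seqs[scaffold]
        if strand == "+":
            end = seed_start + candidate_length
            if end > len(s):
                log.warning("%s:%d+ candidate truncated at scaffold end", scaffold, seed_start)
                end = len(s)
            cand = s[seed_start:end]
            seed_five_prime = seed_start
            region = (seed_start, end)
        else:
            seed_end = seed_start + len(sl_seq)
            begin = seed_end - candidate_length
            if begin < 0:
                log.warning("%s:%d- candidate truncated at scaffold start", scaffold, seed_start)
                begin = 0
            cand = revcomp(s[begin:seed_end])
            seed_five_prime = seed_end - 1
            region = (begin, seed_end)
        donor_region = cand[len(sl_seq):len(sl_seq) + len(donor_pattern)]
        donor_ok = len(donor_region) == len(donor_pattern) and bool(
            iupac_regex(donor_pattern).fullmatch(donor_region))
        m = sm_re.search(cand, len(sl_seq) + len(donor_pattern))
        sm_site = (m.start(), m.group()) if m else None
        npairs, struct = fold_max_pairs(cand, min_loop=min_loop)
        hairpins = count_hairpins(struct)
        reasons = []
        if not donor_ok:
            reasons.append("no donor site")
        if sm_site is None:
            reasons.append("no Sm site")
        if hairpins < min_hairpins:
            reasons.append(f"only {hairpins} hairpins")
        if genes is not None:
            near = any(abs(seed_five_prime - tss) <= coding_margin
                       for tss in ts_starts.get(scaffold, ()))
            if near:
                reasons.append("coding 5' end")
        out.append(SLRNACandidate(
            scaffold=scaffold, strand=strand, seed_start=seed_start,
            candidate_seq=cand, donor_ok=donor_ok, sm_site=sm_site,
            structure=struct, hairpin_count=hairpins,
            accepted=not reasons, reason="; ".join(reasons),
            region_start=region[0], region_end=region[1],
        ))
    return out


def write_candidates_tsv(cands: Sequence[SLRNACandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstrand\tseed_start\tdonor_ok\tsm_offset\thairpins\taccepted\treason\n")
        for c in cands:
            sm = c.sm_site[0] if c.sm_site else "."
            fh.write(f"{c.scaffold}\t{c.strand}\t{c.seed_start}\t{c.donor_ok}\t{sm}\t"
                     f"{c.hairpin_count}\t{c.accepted}\t{c.reason}\n")


def write_candidates_gff3(cands: Sequence[SLRNACandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(cands, start=1):
            if not c.accepted:
                continue
            fh.write(f"{c.scaffold}\tsloperon\tSL_RNA_gene\t{c.region_start + 1}\t{c.region_end}\t.\t"
                     f"{c.strand}\t.\tID=slrna_{i};hairpins={c.hairpin_count}\n")


def write_structures(cands: Sequence[SLRNACandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cands:
            fh.write(f">{c.scaffold}:{c.seed_start}:{c.strand} accepted={c.accepted}\n")
            fh.write(c.candidate_seq + "\n")
            fh.write(c.structure + "\n")
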