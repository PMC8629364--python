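"""Spliced-leader detection at read 5' ends and trans-splicing calls.

A read that begins with a suffix of the 35-nt SL exon is evidence that its
transcript was trans-spliced; trimming the SL suffix leaves the read
starting exactly at the trans-splice acceptor.  A gene is called TS when
enough trimmed-read 5' ends pile up at its annotated transcript start.
This module does not align reads: placements of trimmed reads are consumed
from SAM or a simple TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .core_io import GeneModel

log = logging.getLogger(__name__)

# 35-bp M. lignano spliced-leader exon
DEFAULT_SL_SEQ = "CGGTCTCTTACTGCGAAGACTCAATTTATTGCATG"

_VALID = set("ACGTN")


@dataclass(frozen=True)
class SLMatch:
    read_id: str
    overlap: int          # length of the SL suffix matched to the read prefix
    mismatches: int
    trimmed_seq: str


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    scaffold: str
    strand: str
    five_prime_pos: int   # 0-based genomic coordinate of the trimmed read's 5' end


def match_sl_prefix(
    read_seq: str,
    sl_seq: str = DEFAULT_SL_SEQ,
    min_overlap: int = 12,
    max_mismatch_per_12nt: int = 1,
    read_id: str = "",
) -> SLMatch | None:
    """Match the longest SL suffix to the read prefix, ungapped.

    An overlap of length L qualifies when its Hamming distance is at most
    ``floor(L/12) * max_mismatch_per_12nt``; the longest qualifying overlap
    wins.  Returns ``None`` when no suffix of length >= ``min_overlap``
    qualifies.
    """
    if not sl_seq:
        raise ValueError("sl_seq must be non-empty")
    if min_overlap > len(sl_seq):
        raise ValueError("min_overlap exceeds SL length")
    read_seq = read_seq.upper()
    if set(read_seq) - _VALID:
        raise ValueError(f"read contains non-ACGTN characters: {set(read_seq) - _VALID}")
    max_l = min(len(sl_seq), len(read_seq))
    for overlap in range(max_l, min_overlap - 1, -1):
        suffix = sl_seq[-overlap:]
        allowed = (overlap // 12) * max_mismatch_per_12nt
        mism = 0
        for a, b in zip(suffix, read_seq):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return SLMatch(read_id=read_id, overlap=overlap, mismatches=mism,
                           trimmed_seq=read_seq[overlap:])
    return None


def tag_fastq(
    in_fastq: str | Path,
    out_fastq: str | Path,
    sl_seq: str = DEFAULT_SL_SEQ,
    min_overlap: int = 12,
    max_mismatch_per_12nt: int = 1,
) -> dict[str, SLMatch]:
    """Screen a FASTQ for SL-tagged reads; write SL-trimmed reads.

    Returns {read_id: SLMatch} for the reads that carried an SL suffix.
    Reads without a match are not written (they carry no trans-splicing
    evidence).
    """
    matches: dict[str, SLMatch] = {}
    with open(out_fastq, "w") as out:
        for rec in SeqIO.parse(str(in_fastq), "fastq"):
            m = match_sl_prefix(str(rec.seq), sl_seq, min_overlap,
                                max_mismatch_per_12nt, read_id=rec.id)
            if m is None or not m.trimmed_seq:
                continue
            matches[rec.id] = m
            trimmed = rec[m.overlap:]
            trimmed.description = f"SL_overlap={m.overlap} mismatches={m.mismatches}"
            SeqIO.write(trimmed, out, "fastq")
    return matches


def read_placements_tsv(path: str | Path) -> list[ReadPlacement]:
    """4-column TSV: read_id, scaffold, strand, five_prime_pos (0-based)."""
    out: list[ReadPlacement] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["read_id", "scaffold", "strand", "five_prime_pos"]:
            raise ValueError(f"{path}: unexpected placements header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            out.append(ReadPlacement(parts[0], parts[1], parts[2], int(parts[3])))
    return out


def read_placements_sam(path: str | Path) -> list[ReadPlacement]:
    """Extract trimmed-read 5'-end placements from a SAM file.

    For a forward alignment the 5' end is the leftmost reference base; for
    a reverse alignment it is the rightmost.
    """
    out: list[ReadPlacement] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                pos = aln.reference_end - 1
                strand = "-"
            else:
                pos = aln.reference_start
                strand = "+"
            out.append(ReadPlacement(aln.query_name, aln.reference_name, strand, pos))
    return out


def call_ts_transcripts(
    placements: Iterable[ReadPlacement],
    genes: Sequence[GeneModel],
    window: int = 10,
    min_reads: int = 2,
) -> dict[str, str]:
    """Call each gene TS/nonTS from trimmed-read 5'-end placements.

    A gene is TS iff at least ``min_reads`` strand-concordant placements
    fall within +-``window`` of its annotated transcript 5' start.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    known = {g.scaffold for g in genes}
    by_scaffold: dict[tuple[str, str], list[int]] = {}
    skipped = 0
    for p in placements:
        if p.scaffold not in known:
            skipped += 1
            continue
        by_scaffold.setdefault((p.scaffold, p.strand), []).append(p.five_prime_pos)
    if skipped:
        log.warning("%d placements on unknown scaffolds skipped", skipped)
    for positions in by_scaffold.values():
        positions.sort()
    import bisect
    calls: dict[str, str] = {}
    for g in genes:
        positions = by_scaffold.get((g.scaffold, g.strand), [])
        lo = bisect.bisect_left(positions, g.tss - window)
        hi = bisect.bisect_right(positions, g.tss + window)
        calls[g.gene_id] = "TS" if hi - lo >= min_reads else "nonTS"
    return calls
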