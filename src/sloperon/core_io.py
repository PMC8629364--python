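"""Annotation, repeat-track and label-table I/O.

All genomic intervals inside the package are 0-based half-open on the
forward strand; conversions from 1-based inclusive conventions (GFF3,
RepeatMasker ``.out``) happen here and only here.  Gene spans run from the
first exon start to the last exon end of the representative transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

log = logging.getLogger(__name__)

TS_STATUSES = ("TS", "nonTS", "unknown")
CONS_CLASSES = ("conserved", "non-conserved", "non-coding", "unknown")
CELL_LABELS = ("neoblast", "germline", "none")


@dataclass(frozen=True)
class GeneModel:
    """A stranded, exon-structured transcript with analysis labels.

    ``start``/``end`` and every exon are 0-based half-open forward-strand
    coordinates.  ``ts_status`` records whether the transcript receives the
    spliced leader; ``cons_class`` the conservation class relative to human;
    ``cell_label`` the cell-type specificity call.
    """

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    ts_status: str = "unknown"
    cons_class: str = "unknown"
    cell_label: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: need 0 <= start < end, got [{self.start},{self.end})")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside span [{self.start},{self.end})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.ts_status not in TS_STATUSES:
            raise ValueError(f"{self.gene_id}: bad ts_status {self.ts_status!r}")
        if self.cons_class not in CONS_CLASSES:
            raise ValueError(f"{self.gene_id}: bad cons_class {self.cons_class!r}")
        if self.cell_label not in CELL_LABELS:
            raise ValueError(f"{self.gene_id}: bad cell_label {self.cell_label!r}")

    @property
    def tss(self) -> int:
        """0-based genomic position of the transcript 5' end."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)


@dataclass
class RepeatTrack:
    """Per-scaffold repeat intervals, possibly overlapping, 0-based half-open."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def add(self, scaffold: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"repeat interval start >= end: ({start},{end})")
        self.intervals.setdefault(scaffold, []).append((start, end))

    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())


@dataclass
class LabelTable:
    """Rows of (gene_id, ts_status, cons_class, cell_label); gene_id unique."""

    rows: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["gene_id", "ts_status", "cons_class", "cell_label"]
            if header != expected:
                raise ValueError(f"{path}: expected header {expected}, got {header}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
                gid, ts, cons, cell = parts
                if gid in table.rows:
                    raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
                table.rows[gid] = (ts, cons, cell)
        return table

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tts_status\tcons_class\tcell_label\n")
            for gid in sorted(self.rows):
                ts, cons, cell = self.rows[gid]
                fh.write(f"{gid}\t{ts}\t{cons}\t{cell}\n")


def _sort_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    return sorted(genes, key=lambda g: (g.scaffold, g.start, g.gene_id))


def _validate_gff3_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start after parsing ({start},{end})")
            if parts[6] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-'")


def _parse_gff3(path: str | Path) -> list[GeneModel]:
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")]
            break  # one representative transcript per gene
        if not exons:
            exons = [(e.start - 1, e.end) for e in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        exons.sort()
        start, end = exons[0][0], exons[-1][1]
        if not (0 <= start < end):
            raise ValueError(f"{path}: gene {gene.id}: invalid span [{start},{end}) after conversion")
        genes.append(GeneModel(
            gene_id=gene.id, scaffold=gene.seqid, strand=gene.strand,
            start=start, end=end, exons=tuple(exons),
        ))
    return _sort_genes(genes)


def _parse_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED needs >= 6 columns, got {len(parts)}")
            try:
                scaffold, start, end = parts[0], int(parts[1]), int(parts[2])
                name, strand = parts[3], parts[5]
                if len(parts) >= 12:
                    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
                else:
                    exons = ((start, end),)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED record") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            genes.append(GeneModel(
                gene_id=name, scaffold=scaffold, strand=strand,
                start=start, end=end, exons=exons,
            ))
    return _sort_genes(genes)


def parse_gene_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive on disk) or BED6/BED12.

    Returns genes sorted by (scaffold, start); labels default to
    unknown/none and are attached separately with :func:`attach_labels`.
    """
    if dialect == "gff3":
        return _parse_gff3(path)
    if dialect in ("bed", "bed6", "bed12"):
        return _parse_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def parse_repeat_track(path: str | Path, dialect: str = "bed") -> RepeatTrack:
    """Read repeat intervals from BED or RepeatMasker ``.out``.

    Intervals are kept exactly as given (no merging); RepeatMasker rows are
    converted from 1-based inclusive to 0-based half-open.
    """
    track = RepeatTrack()
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
                try:
                    track.add(parts[0], int(parts[1]), int(parts[2]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed repeat record: {exc}") from exc
        return track
    if dialect == "repeatmasker":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts or not parts[0].isdigit():
                    continue  # header / blank lines
                if len(parts) < 7:
                    raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
                try:
                    track.add(parts[4], int(parts[5]) - 1, int(parts[6]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed RepeatMasker row: {exc}") from exc
        return track
    raise ValueError(f"unknown repeat dialect {dialect!r}")


def attach_labels(genes: Sequence[GeneModel], labels: LabelTable) -> list[GeneModel]:
    """Attach ts_status / cons_class / cell_label to matching gene ids.

    Unmatched genes keep their defaults; label rows without a gene are
    reported through the module logger.
    """
    out: list[GeneModel] = []
    seen: set[str] = set()
    for g in genes:
        row = labels.rows.get(g.gene_id)
        if row is None:
            out.append(g)
        else:
            seen.add(g.gene_id)
            ts, cons, cell = row
            out.append(replace(g, ts_status=ts, cons_class=cons, cell_label=cell))
    unmatched = sorted(set(labels.rows) - seen)
    if unmatched:
        log.warning("%d label rows matched no gene (e.g. %s)", len(unmatched), unmatched[:5])
    return out


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "sloperon") -> None:
    """Write gene/mRNA/exon features, 1-based inclusive, deterministic order."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in _sort_genes(genes):
            fh.write(f"{g.scaffold}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.scaffold}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.scaffold}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={tid}.exon{i};Parent={tid}\n")


def write_repeat_bed(track: RepeatTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for scaffold in sorted(track.intervals):
            for s, e in sorted(track.intervals[scaffold]):
                fh.write(f"{scaffold}\t{s}\t{e}\trepeat\n")


def write_ts_status_tsv(ts_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tts_status\n")
        for gid in sorted(ts_map):
            fh.write(f"{gid}\t{ts_map[gid]}\n")
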