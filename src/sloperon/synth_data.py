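"""Synthetic genome generator with planted trans-splicing ground truth.

Emulates the genomic structure the analysis relies on: gene neighbourhoods
with a bimodal intergenic-gap distribution (a short ~100 bp mode inside
operons versus long gaps elsewhere), repeat blocks inserted into gaps that
inflate raw distances, SL RNA gene copies with the 35-bp SL exon, donor
site, Sm site and a three-hairpin fold, splice-site motifs written at the
junctions, and reads carrying full or truncated SL prefixes at the starts
of trans-spliced transcripts.  Every planted fact is emitted both in
standard files (FASTA/GFF3/BED/FASTQ/TSV) and in truth tables, and the
whole dataset is a deterministic function of the seed.

Repeat blocks are random-composition sequence, not realistic repeat
families; reads carry no sequencing-error model.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GeneModel, RepeatTrack, write_gff3, write_repeat_bed
from .seqtools import IUPAC, revcomp
from .sl_tagging import DEFAULT_SL_SEQ
from .slrna_finder import count_hairpins, fold_max_pairs

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SynthConfig:
    """All planting parameters of the synthetic dataset.

    Gap lengths are log-normal (natural-log mu/sigma); the intra-operon
    default puts the distribution mode at ~100 bp and the between-unit
    default keeps the mode in the multi-kb range, reproducing the bimodal
    picture that motivates the 1 kb operon threshold.  Conservation and
    cell-type labels are planted conditionally on trans-splicing status so
    the enrichment contrasts have a known truth.
    """

    seed: int
    n_scaffolds: int = 5
    n_genes: int = 2000
    ts_fraction: float = 0.30
    operon_gene_fraction: float = 0.30
    operon_size_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.75, 3: 0.18, 4: 0.05, 5: 0.02})
    operon_starts_nonts_fraction: float = 0.18
    intra_operon_gap: tuple[float, float] = (math.log(100.0) + 0.25, 0.5)  # mode ~100 bp
    inter_gene_gap: tuple[float, float] = (math.log(5000.0), 0.8)
    repeat_insertion_rate: float = 0.25
    repeat_length: tuple[float, float] = (math.log(2000.0), 0.6)
    n_slrna_copies: int = 8
    sl_seq: str = DEFAULT_SL_SEQ
    slrna_length: int = 109
    reads_per_ts_gene: int = 10
    body_reads_per_gene: int = 3
    read_length: int = 75
    sl_truncation: tuple[int, int] = (12, 35)  # uniform over matched SL nt
    donor_word: str = "GTAAG"
    acceptor_word: str = "CAG"
    outron_acceptor_pattern: str = "YTNCAG"
    p_donor: float = 0.8
    p_acceptor: float = 0.8
    p_outron: float = 0.8
    sm_word: str = "AATTTTTGG"
    cons_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"TS": (0.699, 0.243, 0.058),
                                 "nonTS": (0.369, 0.429, 0.202)})
    p_neoblast_ts_cons: float = 0.05
    p_neoblast_other: float = 0.005
    p_germline: float = 0.01
    plant_negative_controls: bool = True

    def __post_init__(self) -> None:
        for name in ("ts_fraction", "operon_gene_fraction", "operon_starts_nonts_fraction",
                     "repeat_insertion_rate", "p_donor", "p_acceptor", "p_outron"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.operon_size_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("operon_size_distribution must sum to 1")
        if any(s < 2 for s in self.operon_size_distribution):
            raise ValueError("operon sizes must be >= 2")


@dataclass
class TruthTables:
    genes: pd.DataFrame     # gene_id, coords, ts_status, operon_id, labels, planted motifs
    slrna: pd.DataFrame     # planted SL RNA loci and negative controls
    reads: pd.DataFrame     # read_id, gene_id, sl_overlap, placement
    gaps: pd.DataFrame      # kind, drawn_gap, repeat_len
    paths: dict[str, Path]


def design_slrna_construct(
    sl_seq: str = DEFAULT_SL_SEQ,
    donor: str = "GTAAG",
    sm_word: str = "AATTTTTGG",
    total_length: int = 109,
) -> str:
    """A synthetic SL RNA gene sequence with the canonical architecture.

    The SL exon sits at the 5' end, the donor site immediately after it,
    two designed GC stems form the later hairpins with the Sm word between
    them, and the base-pair-maximal fold of the result is verified to
    contain at least three hairpin loops.
    """
    if total_length < len(sl_seq) + 30:
        raise ValueError("total_length must be >= len(sl_seq) + 30")
    stem2, stem3 = "GGGGCC", "GGCCCC"
    loop = "GAAA"
    core = (sl_seq + donor + "AACAAC" + stem2 + loop + revcomp(stem2)
            + "ACAAC" + sm_word + "ACAAC" + stem3 + loop + revcomp(stem3))
    if len(core) > total_length:
        raise ValueError(
            f"cannot satisfy constraints at length {total_length}: core needs {len(core)} nt")
    construct = core + "CA" * ((total_length - len(core) + 1) // 2)
    construct = construct[:total_length]
    _, struct = fold_max_pairs(construct)
    if count_hairpins(struct) < 3:
        raise ValueError("designed construct does not fold into three hairpins")
    return construct


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASE_BYTES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _sample_word(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in pattern)


def _spliced_transcript(genome: str, gene: GeneModel) -> str:
    seq = "".join(genome[s:e] for s, e in gene.exons)
    return seq if gene.strand == "+" else revcomp(seq)


@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    ts: bool
    operon_id: str          # "." for singles
    exon_lens: list[int]
    intron_lens: list[int]
    plant_donors: list[bool]
    plant_acceptors: list[bool]
    plant_outron: bool
    outron_word: str


def _plan_genes(cfg: SynthConfig, rng: np.random.Generator) -> list[list[_GenePlan]]:
    """Units (operons and singletons) in genomic layout order per scaffold."""
    n_operon_genes = int(round(cfg.n_genes * cfg.operon_gene_fraction))
    if cfg.ts_fraction == 0:
        n_operon_genes = 0
    sizes: list[int] = []
    size_vals = sorted(cfg.operon_size_distribution)
    size_p = [cfg.operon_size_distribution[s] for s in size_vals]
    while sum(sizes) < n_operon_genes - 1:
        sizes.append(int(rng.choice(size_vals, p=size_p)))
    if sizes and sum(sizes) > n_operon_genes:
        excess = sum(sizes) - n_operon_genes
        sizes[-1] -= excess
        if sizes[-1] < 2:
            sizes.pop()
    n_operon_genes = sum(sizes)
    n_singles = cfg.n_genes - n_operon_genes

    target_ts = int(round(cfg.ts_fraction * cfg.n_genes))
    nonts_start = rng.random(len(sizes)) < cfg.operon_starts_nonts_fraction
    operon_ts = n_operon_genes - int(nonts_start.sum())
    singles_ts = target_ts - operon_ts
    if singles_ts < 0:
        raise ValueError(
            "infeasible layout: operons require more TS genes than ts_fraction allows; "
            "lower operon_gene_fraction or raise ts_fraction")
    if singles_ts > n_singles:
        raise ValueError(
            "infeasible layout: ts_fraction too high for the number of singleton genes; "
            "raise operon_gene_fraction or lower ts_fraction")

    single_is_ts = np.zeros(n_singles, dtype=bool)
    single_is_ts[rng.choice(n_singles, size=singles_ts, replace=False)] = True

    def make_plan(gene_id: str, strand: str, ts: bool, operon_id: str) -> _GenePlan:
        n_exons = int(rng.choice([1, 2, 3, 4, 5], p=[0.15, 0.30, 0.25, 0.20, 0.10]))
        exon_lens = [int(rng.integers(100, 301)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(80, 401)) for _ in range(n_exons - 1)]
        return _GenePlan(
            gene_id=gene_id, strand=strand, ts=ts, operon_id=operon_id,
            exon_lens=exon_lens, intron_lens=intron_lens,
            plant_donors=[bool(rng.random() < cfg.p_donor) for _ in intron_lens],
            plant_acceptors=[bool(rng.random() < cfg.p_acceptor) for _ in intron_lens],
            plant_outron=bool(ts and rng.random() < cfg.p_outron),
            outron_word=_sample_word(rng, cfg.outron_acceptor_pattern),
        )

    units: list[list[_GenePlan]] = []
    gid = 0
    for op_i, size in enumerate(sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        operon_id = f"true_operon_{op_i + 1}"
        members = []
        for j in range(size):
            ts = not (j == 0 and nonts_start[op_i])
            gid += 1
            members.append(make_plan(f"g{gid:05d}", strand, ts, operon_id))
        if strand == "-":
            members = members[::-1]  # genomic order; transcription runs right-to-left
        units.append(members)
    for i in range(n_singles):
        strand = "+" if rng.random() < 0.5 else "-"
        gid += 1
        units.append([make_plan(f"g{gid:05d}", strand, bool(single_is_ts[i]), ".")])
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    # round-robin across scaffolds preserves determinism and balance
    per_scaffold: list[list[list[_GenePlan]]] = [[] for _ in range(cfg.n_scaffolds)]
    for i, unit in enumerate(units):
        per_scaffold[i % cfg.n_scaffolds].append(unit)
    return per_scaffold


def _build_gene_seq(plan: _GenePlan, cfg: SynthConfig, rng: np.random.Generator
                    ) -> tuple[str, list[tuple[int, int]]]:
    """Gene sequence (forward strand) and exon intervals relative to gene start."""
    donor = cfg.donor_word
    acceptor = cfg.acceptor_word
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, elen in enumerate(plan.exon_lens):
        parts.append(_rand_seq(rng, elen))
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(plan.intron_lens):
            ilen = plan.intron_lens[i]
            intron = _rand_seq(rng, ilen)
            if plan.strand == "+":
                if plan.plant_donors[i]:
                    intron = donor + intron[len(donor):]
                if plan.plant_acceptors[i]:
                    intron = intron[:-len(acceptor)] + acceptor
            else:
                # transcription right-to-left: donor at the intron's right edge
                if plan.plant_donors[i]:
                    intron = intron[:-len(donor)] + revcomp(donor)
                if plan.plant_acceptors[i]:
                    intron = revcomp(acceptor) + intron[len(acceptor):]
            parts.append(intron)
            pos += ilen
    if plan.strand == "-":
        # intron plants above already account for orientation; exon/intron
        # content is random so no further reversal is needed
        pass
    return "".join(parts), exons


def generate_dataset(config: SynthConfig, outdir: str | Path) -> TruthTables:
    """Write the full synthetic dataset and return its truth tables.

    Deterministic given ``config.seed``: running twice with the same
    config yields byte-identical files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    per_scaffold = _plan_genes(cfg, rng)
    construct = design_slrna_construct(cfg.sl_seq, cfg.donor_word, cfg.sm_word, cfg.slrna_length)
    no_donor_construct = design_slrna_construct(
        cfg.sl_seq, "A" * len(cfg.donor_word), cfg.sm_word, cfg.slrna_length)

    # schedule SL RNA copies and the no-donor negative across scaffolds
    slrna_slots: list[tuple[int, int, str, str]] = []  # (scaffold_i, unit_i, kind, strand)
    flat_units = [(si, ui) for si, units in enumerate(per_scaffold) for ui in range(len(units))]
    n_special = cfg.n_slrna_copies + (1 if cfg.plant_negative_controls else 0)
    if n_special > 0 and flat_units:
        picks = rng.choice(len(flat_units), size=min(n_special, len(flat_units)), replace=False)
        for k, pick in enumerate(sorted(picks)):
            si, ui = flat_units[pick]
            kind = "slrna" if k < cfg.n_slrna_copies else "negative_no_donor"
            strand = "+" if rng.random() < 0.5 else "-"
            slrna_slots.append((si, ui, kind, strand))
    slot_lookup = {(si, ui): (kind, strand) for si, ui, kind, strand in slrna_slots}

    mu_intra, sd_intra = cfg.intra_operon_gap
    mu_inter, sd_inter = cfg.inter_gene_gap
    mu_rep, sd_rep = cfg.repeat_length

    genes: list[GeneModel] = []
    gene_aux: list[dict] = []
    repeats = RepeatTrack()
    gap_rows: list[dict] = []
    slrna_rows: list[dict] = []
    scaffold_parts: dict[str, list[str]] = {}

    def draw_gap(kind: str) -> tuple[int, int]:
        """(clean gap length, inserted repeat length or 0)"""
        if kind == "intra_operon":
            gap = max(40, int(rng.lognormal(mu_intra, sd_intra)))
        else:
            gap = max(150, int(rng.lognormal(mu_inter, sd_inter)))
        rep = 0
        if rng.random() < cfg.repeat_insertion_rate:
            rep = max(50, int(rng.lognormal(mu_rep, sd_rep)))
        gap_rows.append({"kind": kind, "drawn_gap": gap, "repeat_len": rep})
        return gap, rep

    for si, units in enumerate(per_scaffold):
        scaffold = f"scaffold_{si + 1}"
        parts: list[str] = []
        cursor = 0

        def append(seq: str) -> int:
            nonlocal cursor
            parts.append(seq)
            start = cursor
            cursor += len(seq)
            return start

        def append_gap(kind: str, prefix: str = "", suffix: str = "") -> None:
            gap, rep = draw_gap(kind)
            left = gap // 2 - len(prefix)
            right = gap - gap // 2 - len(suffix)
            rep_seq = _rand_seq(rng, rep)
            seq = prefix + _rand_seq(rng, left) + rep_seq + _rand_seq(rng, right) + suffix
            start = append(seq)
            if rep:
                rep_start = start + len(prefix) + left
                repeats.add(scaffold, rep_start, rep_start + rep)

        append(_rand_seq(rng, 2000))
        prev_plan: _GenePlan | None = None
        for ui, unit in enumerate(units):
            # gap before this unit (inter-unit class)
            prefix = ""
            if prev_plan is not None and prev_plan.strand == "-" and prev_plan.plant_outron:
                prefix = revcomp(prev_plan.outron_word)
            first = unit[0]
            suffix = first.outron_word if (first.strand == "+" and first.plant_outron) else ""
            append_gap("inter_gene", prefix=prefix, suffix=suffix)

            special = slot_lookup.get((si, ui))
            if special is not None:
                kind, strand = special
                ins = construct if kind == "slrna" else no_donor_construct
                ins_fwd = ins if strand == "+" else revcomp(ins)
                start = append(ins_fwd)
                seed_start = start if strand == "+" else start + len(ins) - len(cfg.sl_seq)
                slrna_rows.append({
                    "scaffold": scaffold, "strand": strand, "seed_start": seed_start,
                    "kind": kind, "expect_accepted": kind == "slrna",
                })
                append_gap("inter_gene",
                           suffix=first.outron_word if (first.strand == "+" and first.plant_outron) else "")
                # note: duplicate outron suffix is harmless (gap content only)
            for gi, plan in enumerate(unit):
                seq, rel_exons = _build_gene_seq(plan, cfg, rng)
                start = append(seq)
                genes.append(GeneModel(
                    gene_id=plan.gene_id, scaffold=scaffold, strand=plan.strand,
                    start=start, end=start + len(seq),
                    exons=tuple((start + s, start + e) for s, e in rel_exons),
                    ts_status="TS" if plan.ts else "nonTS",
                ))
                gene_aux.append({
                    "gene_id": plan.gene_id, "operon_id": plan.operon_id,
                    "plant_outron": plan.plant_outron, "outron_word": plan.outron_word,
                    "n_donors_planted": sum(plan.plant_donors),
                })
                if gi < len(unit) - 1:
                    nxt = unit[gi + 1]
                    append_gap(
                        "intra_operon",
                        prefix=(revcomp(plan.outron_word)
                                if plan.strand == "-" and plan.plant_outron else ""),
                        suffix=(nxt.outron_word
                                if nxt.strand == "+" and nxt.plant_outron else ""),
                    )
                prev_plan = plan
        # trailing outron for a final minus-strand TS gene, then margin
        tail_prefix = ""
        if prev_plan is not None and prev_plan.strand == "-" and prev_plan.plant_outron:
            tail_prefix = revcomp(prev_plan.outron_word)
        append(tail_prefix + _rand_seq(rng, 2000 - len(tail_prefix)))
        scaffold_parts[scaffold] = parts

    scaffolds = {name: "".join(parts) for name, parts in scaffold_parts.items()}

    # coding-5'-end negative: a full construct overwriting the region just
    # upstream of a plus-strand TS singleton start (seed 10 bp before the TSS)
    aux_by_id = {a["gene_id"]: a for a in gene_aux}
    if cfg.plant_negative_controls:
        target = next(
            (g for g in genes
             if g.strand == "+" and g.ts_status == "TS"
             and aux_by_id[g.gene_id]["operon_id"] == "."
             and g.start >= cfg.slrna_length + 20),
            None)
        if target is not None:
            buf = bytearray(scaffolds[target.scaffold], "ascii")
            seed_start = target.start - 10
            buf[seed_start:seed_start + len(construct)] = construct.encode("ascii")
            scaffolds[target.scaffold] = buf.decode("ascii")
            aux_by_id[target.gene_id]["plant_outron"] = False
            slrna_rows.append({
                "scaffold": target.scaffold, "strand": "+", "seed_start": seed_start,
                "kind": "negative_coding5", "expect_accepted": False,
            })

    # ---- labels -------------------------------------------------------
    cons_order = ("conserved", "non-conserved", "non-coding")
    labeled: list[GeneModel] = []
    for g in genes:
        probs = cfg.cons_probs["TS" if g.ts_status == "TS" else "nonTS"]
        cons = cons_order[int(rng.choice(3, p=np.asarray(probs) / sum(probs)))]
        if g.ts_status == "TS" and cons == "conserved":
            p_neo = cfg.p_neoblast_ts_cons
        else:
            p_neo = cfg.p_neoblast_other
        if rng.random() < p_neo:
            cell = "neoblast"
        elif rng.random() < cfg.p_germline:
            cell = "germline"
        else:
            cell = "none"
        labeled.append(dataclasses.replace(g, cons_class=cons, cell_label=cell))
    genes = labeled

    # ---- reads and placements ----------------------------------------
    read_rows: list[dict] = []
    fastq_lines: list[str] = []
    rid = 0
    lo_tr, hi_tr = cfg.sl_truncation
    for g in genes:
        genome_seq = scaffolds[g.scaffold]
        transcript = _spliced_transcript(genome_seq, g)
        if g.ts_status == "TS":
            for _ in range(cfg.reads_per_ts_gene):
                overlap = int(rng.integers(lo_tr, hi_tr + 1))
                body_len = max(20, cfg.read_length - overlap)
                body = transcript[:body_len]
                seq = cfg.sl_seq[-overlap:] + body
                rid += 1
                name = f"r{rid:07d}"
                fastq_lines.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
                read_rows.append({
                    "read_id": name, "gene_id": g.gene_id, "sl_overlap": overlap,
                    "scaffold": g.scaffold, "strand": g.strand,
                    "five_prime_pos": g.tss, "trimmed_len": len(body),
                })
        for _ in range(cfg.body_reads_per_gene):
            rl = cfg.read_length
            if g.end - g.start < rl + 50:
                continue
            if g.strand == "+":
                c = int(rng.integers(g.start + 20, g.end - rl))
                seq = genome_seq[c:c + rl]
            else:
                c = int(rng.integers(g.start + rl, g.end - 20))
                seq = revcomp(genome_seq[c - rl + 1:c + 1])
            rid += 1
            name = f"r{rid:07d}"
            fastq_lines.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            read_rows.append({
                "read_id": name, "gene_id": g.gene_id, "sl_overlap": 0,
                "scaffold": g.scaffold, "strand": g.strand,
                "five_prime_pos": c, "trimmed_len": rl,
            })

    # ---- emit files ---------------------------------------------------
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "genes.gff3",
        "repeats": outdir / "repeats.bed",
        "reads": outdir / "reads.fastq",
        "placements": outdir / "placements.tsv",
        "placements_sam": outdir / "placements.sam",
        "labels": outdir / "labels.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_slrna": outdir / "truth_slrna.tsv",
        "truth_reads": outdir / "truth_reads.tsv",
        "truth_gaps": outdir / "truth_gaps.tsv",
        "config": outdir / "config.json",
    }
    with open(paths["genome"], "w") as fh:
        for name in sorted(scaffolds):
            fh.write(f">{name}\n")
            s = scaffolds[name]
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")
    write_gff3(genes, paths["annotation"])
    write_repeat_bed(repeats, paths["repeats"])
    with open(paths["reads"], "w") as fh:
        fh.writelines(fastq_lines)
    with open(paths["placements"], "w") as fh:
        fh.write("read_id\tscaffold\tstrand\tfive_prime_pos\n")
        for r in read_rows:
            fh.write(f"{r['read_id']}\t{r['scaffold']}\t{r['strand']}\t{r['five_prime_pos']}\n")
    with open(paths["placements_sam"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in sorted(scaffolds):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(scaffolds[name])}\n")
        for r in read_rows:
            if r["strand"] == "+":
                flag, pos0 = 0, r["five_prime_pos"]
            else:
                flag, pos0 = 16, r["five_prime_pos"] - r["trimmed_len"] + 1
            fh.write(f"{r['read_id']}\t{flag}\t{r['scaffold']}\t{pos0 + 1}\t60\t"
                     f"{r['trimmed_len']}M\t*\t0\t0\t*\t*\n")
    with open(paths["labels"], "w") as fh:
        fh.write("gene_id\tts_status\tcons_class\tcell_label\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.ts_status}\t{g.cons_class}\t{g.cell_label}\n")

    truth_genes = pd.DataFrame([{
        "gene_id": g.gene_id, "scaffold": g.scaffold, "strand": g.strand,
        "start": g.start, "end": g.end,
        "ts_status": g.ts_status, "operon_id": aux_by_id[g.gene_id]["operon_id"],
        "cons_class": g.cons_class, "cell_label": g.cell_label,
        "plant_outron": aux_by_id[g.gene_id]["plant_outron"],
        "outron_word": aux_by_id[g.gene_id]["outron_word"],
        "n_donors_planted": aux_by_id[g.gene_id]["n_donors_planted"],
    } for g in genes])
    truth_slrna = pd.DataFrame(slrna_rows, columns=[
        "scaffold", "strand", "seed_start", "kind", "expect_accepted"])
    truth_reads = pd.DataFrame(read_rows)
    truth_gaps = pd.DataFrame(gap_rows, columns=["kind", "drawn_gap", "repeat_len"])
    truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth_slrna.to_csv(paths["truth_slrna"], sep="\t", index=False)
    truth_reads.to_csv(paths["truth_reads"], sep="\t", index=False)
    truth_gaps.to_csv(paths["truth_gaps"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, default=str, sort_keys=True)
        fh.write("\n")
    return TruthTables(genes=truth_genes, slrna=truth_slrna, reads=truth_reads,
                       gaps=truth_gaps, paths=paths)
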