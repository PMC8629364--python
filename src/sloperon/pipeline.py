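"""End-to-end orchestration: tag reads, call trans-splicing, infer operons,
annotate SL RNA genes, find junction motifs, compute enrichment statistics.

Produces per-stage TSV/GFF3 outputs plus a machine-readable JSON summary;
every number in the summary is recomputed from the stage outputs, and the
run configuration is echoed verbatim into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import core_io, enrichment_stats, motif_finder, operon_inference, sl_tagging, slrna_finder

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run (flat key-value file)."""

    outdir: str
    genome: str | None = None
    annotation: str | None = None
    annotation_dialect: str = "gff3"
    repeats: str | None = None
    repeats_dialect: str = "bed"
    reads: str | None = None
    placements: str | None = None
    labels: str | None = None
    sl_seq: str = sl_tagging.DEFAULT_SL_SEQ
    min_overlap: int = 12
    max_mismatch_per_12nt: int = 1
    window: int = 10
    min_reads: int = 2
    threshold: int = 1000
    use_adjusted: bool = True
    flank: int = 50
    k_min: int = 3
    k_max: int = 6
    e_cutoff: float = 0.05
    max_motifs: int = 1
    slrna_length: int = 109
    donor_pattern: str = "GTAAG"
    sm_pattern: str = slrna_finder.DEFAULT_SM
    min_hairpins: int = 3
    seed: int = 1
    config_path: str | None = None  # original file, echoed for provenance

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                try:
                    values[key] = json.loads(raw)
                except json.JSONDecodeError:
                    values[key] = raw
        cfg = cls(**values)  # type: ignore[arg-type]
        cfg.config_path = str(path)
        return cfg


def _check(cfg: RunConfig) -> None:
    for name in ("genome", "annotation", "repeats", "reads", "placements", "labels"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config path {name} = {p} does not exist")
    if cfg.annotation is None:
        raise ValueError("an annotation file is required")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return (and write) the summary dictionary."""
    _check(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.config_path:
        shutil.copyfile(cfg.config_path, outdir / "run_config.echo")
    summary: dict = {"seed": cfg.seed}

    stage = "load"
    try:
        genes = core_io.parse_gene_annotation(cfg.annotation, dialect=cfg.annotation_dialect)
        repeats = (core_io.parse_repeat_track(cfg.repeats, dialect=cfg.repeats_dialect)
                   if cfg.repeats else None)
        genome = ({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(cfg.genome, "fasta")}
                  if cfg.genome else None)
        labels = core_io.LabelTable.from_tsv(cfg.labels) if cfg.labels else None
        if labels is not None:
            genes = core_io.attach_labels(genes, labels)

        stage = "tag-reads"
        sl_matched: set[str] | None = None
        if cfg.reads:
            matches = sl_tagging.tag_fastq(
                cfg.reads, outdir / "trimmed.fastq", cfg.sl_seq,
                cfg.min_overlap, cfg.max_mismatch_per_12nt)
            sl_matched = set(matches)
            summary["sl_tagged_reads"] = len(matches)
        elif cfg.labels:
            log.info("no reads supplied: SL tagging skipped, TS status from label table")

        stage = "call-ts"
        read_calls: dict[str, str] | None = None
        if cfg.placements and sl_matched is not None:
            placements = (sl_tagging.read_placements_sam(cfg.placements)
                          if cfg.placements.endswith(".sam")
                          else sl_tagging.read_placements_tsv(cfg.placements))
            placements = [p for p in placements if p.read_id in sl_matched]
            read_calls = sl_tagging.call_ts_transcripts(placements, genes,
                                                        cfg.window, cfg.min_reads)
        if labels is not None:
            ts_map = {g.gene_id: ("TS" if g.ts_status == "TS" else "nonTS") for g in genes}
            if read_calls is not None:
                conflicts = sum(1 for gid, c in read_calls.items() if ts_map.get(gid) != c)
                log.info("label table overrides read-derived TS calls (%d conflicts)", conflicts)
                summary["ts_call_conflicts_vs_labels"] = conflicts
        elif read_calls is not None:
            ts_map = read_calls
        else:
            raise ValueError("need either labels or reads+placements to determine TS status")
        core_io.write_ts_status_tsv(ts_map, outdir / "ts_status.tsv")
        genes = [dataclasses.replace(g, ts_status=ts_map.get(g.gene_id, "nonTS")) for g in genes]
        n_ts = sum(1 for s in ts_map.values() if s == "TS")
        summary["n_genes"] = len(genes)
        summary["n_ts_genes"] = n_ts
        summary["pct_ts_genes"] = round(100.0 * n_ts / len(genes), 1) if genes else 0.0

        stage = "distances"
        pairs = operon_inference.adjust_pairs(operon_inference.adjacent_pairs(genes), repeats)
        operon_inference.write_pairs_tsv(pairs, outdir / "pairs.tsv")
        dists = operon_inference.distance_distributions(pairs, use_adjusted=cfg.use_adjusted)
        summary["distance_modes_bp"] = {
            d.category: [round(m, 1) for m in d.modes] for d in dists}
        summary["distance_valleys_bp"] = {
            d.category: (round(d.valley, 1) if d.valley is not None else None) for d in dists}

        stage = "operons"
        operons = operon_inference.call_operons(
            genes, ts_map, repeats, threshold=cfg.threshold, use_adjusted=cfg.use_adjusted)
        operon_inference.write_operons_tsv(operons, outdir / "operons.tsv")
        operon_inference.write_operons_gff3(operons, genes, outdir / "operons.gff3")
        osum = operon_inference.operon_summary(operons, n_genes_total=len(genes), n_ts_total=n_ts)
        osum.pop("span_lengths")
        osum["size_histogram"] = {str(k): v for k, v in osum["size_histogram"].items()}
        summary["operons"] = osum

        stage = "slrna"
        if genome is not None:
            cands = slrna_finder.call_slrna_genes(
                genome, cfg.sl_seq, candidate_length=cfg.slrna_length,
                donor_pattern=cfg.donor_pattern, sm_pattern=cfg.sm_pattern,
                min_hairpins=cfg.min_hairpins, genes=genes)
            slrna_finder.write_candidates_tsv(cands, outdir / "slrna_candidates.tsv")
            slrna_finder.write_candidates_gff3(cands, outdir / "slrna.gff3")
            slrna_finder.write_structures(cands, outdir / "slrna_structures.txt")
            summary["slrna"] = {
                "n_seed_hits": len(cands),
                "n_accepted": sum(1 for c in cands if c.accepted),
            }

        stage = "motifs"
        if genome is not None:
            summary["motifs"] = {}
            for site_type in motif_finder.SITE_TYPES:
                windows = motif_finder.extract_junction_windows(
                    genes, genome, flank=cfg.flank, site_type=site_type)
                if not windows:
                    summary["motifs"][site_type] = None
                    continue
                motif_finder.write_windows_fasta(windows, outdir / f"windows_{site_type}.fasta")
                motifs = motif_finder.discover_motifs(
                    windows, k_range=(cfg.k_min, cfg.k_max),
                    max_motifs=cfg.max_motifs, e_cutoff=cfg.e_cutoff, seed=cfg.seed)
                motif_finder.write_motifs_tsv(motifs, outdir / f"motifs_{site_type}.tsv")
                summary["motifs"][site_type] = (
                    {"word": motifs[0].word, "regions_with": motifs[0].pos_with,
                     "regions_total": motifs[0].pos_total,
                     "e_value": motifs[0].e_value,
                     "positional_mode": motifs[0].positional_mode}
                    if motifs else None)

        stage = "enrich"
        if labels is not None:
            tab = enrichment_stats.conservation_crosstab(genes)
            tab.to_csv(outdir / "conservation_crosstab.tsv", sep="\t")
            frac = enrichment_stats.column_fractions(tab)
            summary["conservation_pct"] = {
                ts: {c: (None if frac.loc[ts, c] != frac.loc[ts, c] else float(frac.loc[ts, c]))
                     for c in frac.columns}
                for ts in frac.index}
            n_neo_cons = sum(1 for g in genes
                             if g.cell_label == "neoblast" and g.cons_class == "conserved"
                             and g.ts_status in ("TS", "nonTS"))
            if n_neo_cons:
                enr = enrichment_stats.neoblast_conserved_ts_enrichment(genes)
                summary["neoblast_conserved_ts"] = {
                    "subset_fraction": round(enr.subset_fraction, 4),
                    "genome_fraction": round(enr.genome_fraction, 4),
                    "fold": enr.fold, "chi2": round(enr.chi2, 3), "p_value": enr.p_value,
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
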