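"""Intergenic-distance analysis and operon calling.

Eukaryotic operons leave a genomic footprint: co-oriented neighbours that
are resolved from one polycistronic pre-mRNA sit unusually close together
(the short mode of the intergenic-gap distribution, ~100 bp), while
unrelated neighbours follow a long unimodal distribution.  Repeat
insertions inflate the raw gaps, so distances are adjusted by subtracting
the bases covered by the union of repeat intervals before applying the
operon-linking threshold (default 1000 bp): a pair of adjacent co-oriented
genes joins one operon when the adjusted gap is below the threshold and
the downstream gene is SL trans-spliced; a non-trans-spliced gene may only
be the first member of a chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .core_io import GeneModel, RepeatTrack

log = logging.getLogger(__name__)

CATEGORIES = ("TS->TS", "nonTS->TS", "TS->nonTS", "nonTS->nonTS")


@dataclass
class AdjacentPair:
    """An ordered same-strand neighbour pair with raw and adjusted gap."""

    upstream_gene: str
    downstream_gene: str
    scaffold: str
    strand: str
    raw_distance: int
    adjusted_distance: int
    category: str
    gap_start: int  # forward-strand open interval between the two spans
    gap_end: int


@dataclass
class Operon:
    operon_id: str
    scaffold: str
    strand: str
    genes: tuple[str, ...]  # transcription order
    span_length: int        # putative pre-mRNA length, forward coordinates
    starts_nonTS: bool

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class DistanceDistribution:
    category: str
    distances: list[int]
    modes: list[float] = field(default_factory=list)   # bp, ascending
    valley: float | None = None                        # bp, between first two modes


def _nested_gene_ids(genes: Sequence[GeneModel]) -> set[str]:
    """Genes whose span is fully contained in another gene's span."""
    nested: set[str] = set()
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for scaf_genes in by_scaffold.values():
        ordered = sorted(scaf_genes, key=lambda g: (g.start, -g.end, g.gene_id))
        max_end = -1
        for g in ordered:
            if g.end <= max_end:
                nested.add(g.gene_id)
            max_end = max(max_end, g.end)
    return nested


def _ts(status: str) -> str:
    return "TS" if status == "TS" else "nonTS"


def adjacent_pairs(genes: Sequence[GeneModel]) -> list[AdjacentPair]:
    """Enumerate immediately adjacent same-strand gene pairs.

    Pairs interrupted by an opposite-strand gene (span intersecting the
    open inter-gene interval) are suppressed; genes fully nested inside
    another gene are skipped entirely.  Upstream/downstream are resolved
    by transcription direction; ``raw_distance`` is the forward-coordinate
    gap, floored at zero for overlapping neighbours.
    """
    nested = _nested_gene_ids(genes)
    kept = [g for g in genes if g.gene_id not in nested]
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in kept:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    pairs: list[AdjacentPair] = []
    for scaffold, scaf_genes in sorted(by_scaffold.items()):
        scaf_genes.sort(key=lambda g: g.start)
        for strand in ("+", "-"):
            strand_genes = [g for g in scaf_genes if g.strand == strand]
            others = [g for g in scaf_genes if g.strand != strand]
            for left, right in zip(strand_genes, strand_genes[1:]):
                gap_start, gap_end = left.end, right.start
                if any(o.start < gap_end and o.end > gap_start for o in others):
                    continue
                raw = max(0, gap_end - gap_start)
                if strand == "+":
                    up, down = left, right
                else:
                    up, down = right, left
                category = f"{_ts(up.ts_status)}->{_ts(down.ts_status)}"
                pairs.append(AdjacentPair(
                    upstream_gene=up.gene_id, downstream_gene=down.gene_id,
                    scaffold=scaffold, strand=strand,
                    raw_distance=raw, adjusted_distance=raw,
                    category=category,
                    gap_start=min(gap_start, gap_end), gap_end=max(gap_start, gap_end),
                ))
    pairs.sort(key=lambda p: (p.scaffold, p.gap_start, p.upstream_gene))
    return pairs


def _merged_coverage(intervals: Iterable[tuple[int, int]], lo: int, hi: int) -> int:
    """Bases of [lo,hi) covered by the union of the intervals."""
    clipped = sorted((max(s, lo), min(e, hi)) for s, e in intervals if s < hi and e > lo)
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def repeat_adjusted_distance(pair: AdjacentPair, repeats: RepeatTrack) -> int:
    """Raw gap minus repeat-union coverage of the inter-gene interval, >= 0."""
    if pair.raw_distance == 0:
        return 0
    cov = _merged_coverage(repeats.intervals.get(pair.scaffold, ()),
                           pair.gap_start, pair.gap_end)
    return max(0, pair.raw_distance - cov)


def adjust_pairs(pairs: Sequence[AdjacentPair], repeats: RepeatTrack | None) -> list[AdjacentPair]:
    if repeats is None:
        return list(pairs)
    return [replace(p, adjusted_distance=repeat_adjusted_distance(p, repeats)) for p in pairs]


def find_modes(distances: Sequence[int]) -> tuple[list[float], float | None]:
    """Mode/valley locations of a distance sample, in bp.

    Density is estimated by a Gaussian kernel with Silverman bandwidth on
    log10(d+1); local maxima are mapped back to bp.  The valley is the
    density minimum between the first two modes (None if unimodal).  Ties
    between equal-density maxima break toward the smaller distance.
    """
    if len(distances) < 2:
        return [], None
    x = np.log10(np.asarray(distances, dtype=float) + 1.0)
    if np.ptp(x) == 0:
        return [float(distances[0])], None
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min() - 0.25, x.max() + 0.25, 512)
    dens = kde(grid)
    maxima = [i for i in range(1, len(grid) - 1)
              if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1]]
    modes = [float(10 ** grid[i] - 1) for i in maxima]
    valley = None
    if len(maxima) >= 2:
        i0, i1 = maxima[0], maxima[1]
        j = i0 + int(np.argmin(dens[i0:i1 + 1]))
        valley = float(10 ** grid[j] - 1)
    return modes, valley


def distance_distributions(
    pairs: Sequence[AdjacentPair],
    use_adjusted: bool = True,
    merge_mixed: bool = True,
) -> list[DistanceDistribution]:
    """Group pair distances by category and locate distribution modes."""
    groups: dict[str, list[int]] = {}
    for p in pairs:
        cat = p.category
        if merge_mixed and cat in ("nonTS->TS", "TS->nonTS"):
            cat = "mixed"
        d = p.adjusted_distance if use_adjusted else p.raw_distance
        groups.setdefault(cat, []).append(d)
    out = []
    for cat in sorted(groups):
        modes, valley = find_modes(groups[cat])
        out.append(DistanceDistribution(cat, groups[cat], modes, valley))
    return out


def call_operons(
    genes: Sequence[GeneModel],
    ts_map: Mapping[str, str] | None = None,
    repeats: RepeatTrack | None = None,
    threshold: int = 1000,
    use_adjusted: bool = True,
) -> list[Operon]:
    """Chain co-oriented genes into operons under the distance threshold.

    Scans each scaffold per strand in transcription order; a pair extends
    the growing chain iff it survived the adjacency rules, its (adjusted)
    gap is below ``threshold``, and the downstream gene is TS.  Maximal
    chains of size >= 2 are emitted; a gene belongs to at most one operon.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if ts_map is not None:
        missing = [g.gene_id for g in genes if g.gene_id not in ts_map]
        if missing:
            log.warning("%d genes missing from ts_map treated as nonTS", len(missing))
        genes = [replace(g, ts_status=ts_map.get(g.gene_id, "nonTS")) for g in genes]
    pairs = adjust_pairs(adjacent_pairs(genes), repeats)
    pair_by_key = {(p.upstream_gene, p.downstream_gene): p for p in pairs}
    nested = _nested_gene_ids(genes)
    kept = [g for g in genes if g.gene_id not in nested]
    gene_by_id = {g.gene_id: g for g in kept}
    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for g in kept:
        by_group.setdefault((g.scaffold, g.strand), []).append(g)
    found: list[tuple[str, int, Operon]] = []
    for (scaffold, strand), group in sorted(by_group.items()):
        group.sort(key=lambda g: g.start, reverse=(strand == "-"))
        def flush(chain: list[str]) -> None:
            if len(chain) >= 2:
                members = [gene_by_id[gid] for gid in chain]
                start = min(m.start for m in members)
                found.append((scaffold, start, Operon(
                    operon_id="",  # assigned after genomic sort
                    scaffold=scaffold, strand=strand, genes=tuple(chain),
                    span_length=max(m.end for m in members) - start,
                    starts_nonTS=gene_by_id[chain[0]].ts_status != "TS",
                )))
        chain: list[str] = [group[0].gene_id] if group else []
        for g in group[1:]:
            pair = pair_by_key.get((chain[-1], g.gene_id))
            dist = None
            if pair is not None:
                dist = pair.adjusted_distance if use_adjusted else pair.raw_distance
            if pair is not None and dist < threshold and g.ts_status == "TS":
                chain.append(g.gene_id)
            else:
                flush(chain)
                chain = [g.gene_id]
        flush(chain)
    found.sort(key=lambda t: (t[0], t[1]))
    return [replace(o, operon_id=f"operon_{i + 1}") for i, (_, _, o) in enumerate(found)]


def operon_summary(
    operons: Sequence[Operon],
    n_genes_total: int | None = None,
    n_ts_total: int | None = None,
) -> dict:
    """Size histogram, span lengths and gene-level tallies.

    The fraction of TS genes in operons counts every operon member except
    the non-TS first genes.
    """
    size_hist: dict[int, int] = {}
    for o in operons:
        size_hist[o.size] = size_hist.get(o.size, 0) + 1
    genes_in_operons = sum(o.size for o in operons)
    nonts_starts = sum(1 for o in operons if o.starts_nonTS)
    out = {
        "n_operons": len(operons),
        "size_histogram": dict(sorted(size_hist.items())),
        "genes_in_operons": genes_in_operons,
        "operons_starting_nonTS": nonts_starts,
        "span_lengths": [o.span_length for o in operons],
    }
    out.update(summary_fractions(genes_in_operons, nonts_starts, n_genes_total, n_ts_total))
    return out


def summary_fractions(
    genes_in_operons: int,
    nonts_starts: int,
    n_genes_total: int | None = None,
    n_ts_total: int | None = None,
) -> dict:
    """Gene-level operon fractions (percent) from the head counts."""
    out: dict[str, float] = {}
    if n_genes_total:
        out["pct_all_genes_in_operons"] = 100.0 * genes_in_operons / n_genes_total
    if n_ts_total:
        out["pct_ts_genes_in_operons"] = 100.0 * (genes_in_operons - nonts_starts) / n_ts_total
    if genes_in_operons:
        out["pct_operons_starting_nonTS"] = 100.0 * nonts_starts / genes_in_operons
    return out


def write_pairs_tsv(pairs: Sequence[AdjacentPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("upstream_gene\tdownstream_gene\tscaffold\tstrand\tcategory\traw_distance\tadjusted_distance\n")
        for p in pairs:
            fh.write(f"{p.upstream_gene}\t{p.downstream_gene}\t{p.scaffold}\t{p.strand}\t"
                     f"{p.category}\t{p.raw_distance}\t{p.adjusted_distance}\n")


def write_operons_tsv(operons: Sequence[Operon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tscaffold\tstrand\tsize\tspan_length\tstarts_nonTS\tgenes\n")
        for o in operons:
            fh.write(f"{o.operon_id}\t{o.scaffold}\t{o.strand}\t{o.size}\t{o.span_length}\t"
                     f"{o.starts_nonTS}\t{','.join(o.genes)}\n")


def write_operons_gff3(
    operons: Sequence[Operon],
    genes: Sequence[GeneModel],
    path: str | Path,
) -> None:
    gene_by_id = {g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in operons:
            members = [gene_by_id[gid] for gid in o.genes]
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            fh.write(f"{o.scaffold}\tsloperon\toperon\t{start + 1}\t{end}\t.\t{o.strand}\t.\t"
                     f"ID={o.operon_id};genes={','.join(o.genes)}\n")


def plot_distance_densities(dists: Sequence[DistanceDistribution], path: str | Path) -> None:
    """Optional convenience: density plot of log-scaled distances per category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for dist in dists:
        if len(dist.distances) < 2:
            continue
        x = np.log10(np.asarray(dist.distances, dtype=float) + 1.0)
        if np.ptp(x) == 0:
            continue
        kde = gaussian_kde(x, bw_method="silverman")
        grid = np.linspace(x.min() - 0.25, x.max() + 0.25, 256)
        ax.plot(10 ** grid - 1, kde(grid), label=f"{dist.category} (n={len(dist.distances)})")
    ax.set_xscale("log")
    ax.set_xlabel("intergenic distance (bp)")
    ax.set_ylabel("density (log10 scale)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
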