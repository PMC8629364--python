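"""Infer operons from repeat-adjusted intergenic distances.

Distances between co-oriented neighbours are computed per category
(TS->TS, mixed, nonTS->nonTS), repeat coverage of each gap is subtracted,
and chains of adjacent genes with adjusted gaps under 1 kb whose
downstream members are all trans-spliced are emitted as operons.
"""

from sloperon import (SynthConfig, adjacent_pairs, adjust_pairs, attach_labels,
                      call_operons, distance_distributions, generate_dataset,
                      operon_summary, parse_gene_annotation, parse_repeat_track)
from sloperon.core_io import LabelTable

truth = generate_dataset(SynthConfig(seed=42, n_genes=300, n_scaffolds=2), "example_data")
genes = attach_labels(parse_gene_annotation(truth.paths["annotation"]),
                      LabelTable.from_tsv(truth.paths["labels"]))
repeats = parse_repeat_track(truth.paths["repeats"])

pairs = adjust_pairs(adjacent_pairs(genes), repeats)
for dist in distance_distributions(pairs):
    modes = ", ".join(f"{m:.0f} bp" for m in dist.modes[:2])
    print(f"{dist.category:14s} n={len(dist.distances):3d}  modes: {modes}")
# The TS->TS category is bimodal: the short mode is the intra-operon gap.

operons = call_operons(genes, repeats=repeats, threshold=1000)
n_ts = sum(1 for g in genes if g.ts_status == "TS")
summary = operon_summary(operons, n_genes_total=len(genes), n_ts_total=n_ts)
print(f"\n{summary['n_operons']} operons, size histogram {summary['size_histogram']}")
print(f"{summary['genes_in_operons']} genes in operons "
      f"({summary['pct_all_genes_in_operons']:.0f} % of all, "
      f"{summary['pct_ts_genes_in_operons']:.0f} % of TS genes); "
      f"{summary['operons_starting_nonTS']} operons start with a non-TS gene")

planted = set(truth.genes.loc[truth.genes.operon_id != '.', 'gene_id'])
called = {g for o in operons for g in o.genes}
print(f"planted operon genes recovered: {len(called & planted)}/{len(planted)}")
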