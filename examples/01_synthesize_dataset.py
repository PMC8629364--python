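"""Generate a small synthetic genome with planted trans-splicing structure.

The generator lays out genes in operons (short ~100 bp gaps) and as
singletons (multi-kb gaps), inserts repeat blocks into a quarter of the
gaps, plants SL RNA gene copies and junction motifs, and synthesizes reads
whose 5' ends carry full or truncated spliced-leader prefixes.
"""

from sloperon import SynthConfig, generate_dataset

cfg = SynthConfig(seed=42, n_genes=300, n_scaffolds=2, n_slrna_copies=3)
truth = generate_dataset(cfg, "example_data")

print(f"genes:          {len(truth.genes)} "
      f"({(truth.genes.ts_status == 'TS').sum()} trans-spliced)")
print(f"genes in operons: {(truth.genes.operon_id != '.').sum()}")
print(f"SL RNA loci:    {len(truth.slrna)} "
      f"({truth.slrna.expect_accepted.sum()} genuine, rest negative controls)")
print(f"reads:          {len(truth.reads)} "
      f"({(truth.reads.sl_overlap > 0).sum()} with an SL prefix)")
print("files:          ", ", ".join(p.name for p in truth.paths.values()))
# Every planted fact (TS status, operon membership, SL RNA positions, read
# SL overlaps) is recorded in the truth_*.tsv tables for later comparison.
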