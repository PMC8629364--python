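# sloperon

Spliced-leader (SL) trans-splicing analysis for compact animal genomes —
built around the flatworm *Macrostomum lignano*, where roughly 30 % of
genes receive the same 35-nt spliced leader
(`CGGTCTCTTACTGCGAAGACTCAATTTATTGCATG`) at the 5′ end of their mature
mRNAs. The package is for genome annotators and RNA biologists who want
to go from a genome, an annotation and RNA-seq reads to:

* **trans-spliced gene calls** — reads whose 5′ ends carry a (possibly
  truncated) suffix of the SL exon are detected and trimmed; ≥ *m* trimmed
  5′ ends within ± *w* nt of an annotated transcript start call the gene
  trans-spliced (defaults *m* = 2, *w* = 10);
* **operon inference** — intergenic distances *d* between immediately
  adjacent co-oriented transcripts are computed per category (TS→TS,
  mixed, nonTS→nonTS), repeat coverage of each gap is subtracted
  (*d*<sub>adj</sub> = *d* − |gap ∩ ∪repeats|), and maximal chains with
  *d*<sub>adj</sub> < 1 kb whose downstream members are all trans-spliced
  are emitted as operons (a non-TS gene may only lead a chain);
* **SL RNA gene annotation** — exact genomic occurrences of the SL seed
  are extended to ~109-nt candidates and validated for a GTAAG donor site
  immediately 3′ of the SL exon, an Sm-binding site, and ≥ 3 hairpin loops
  in a base-pair-maximal (Nussinov-style) fold; candidates at the 5′ ends
  of annotated trans-spliced genes are rejected as mRNA starts;
* **junction motif discovery** — ±50 bp windows around cis-donor,
  cis-acceptor and trans-splice acceptor junctions are scanned for
  degenerate words enriched over a dinucleotide-shuffled background
  (one-sided Fisher exact test on per-window containment, Bonferroni
  correction, greedy IUPAC generalization);
* **enrichment statistics** — cross-tabs of trans-splicing against
  conservation class and cell-type labels, with fractions, fold
  enrichments and chi-square statistics.

A first-class synthetic-data generator plants all of this structure
(bimodal gap distributions, repeat-inflated gaps, SL RNA copies with
negative controls, junction motifs, SL-prefixed reads) with full ground
truth, so the entire pipeline is testable without any downloads.

## Worked example

```sh
python examples/03_operon_inference.py
```

```
TS->TS         n= 53  modes: 123 bp, 4480 bp
mixed          n= 41  modes: 100 bp, 5481 bp
nonTS->nonTS   n= 83  modes: 6636 bp

37 operons, size histogram {2: 24, 3: 10, 4: 3}
90 genes in operons (30 % of all, 94 % of TS genes); 5 operons start with a non-TS gene
planted operon genes recovered: 90/90
```

On a 300-gene synthetic genome the distance distribution between
trans-spliced neighbours is bimodal — the ~100 bp mode is the intra-operon
gap, the multi-kb mode is ordinary intergenic space — while non-TS
neighbours are unimodal. Chaining under the 1 kb threshold on
repeat-adjusted distances recovers every planted operon gene. The other
`examples/` scripts demonstrate read tagging, SL RNA discovery (the
designed 109-nt gene, its dot-bracket fold, and the rejection reasons for
the planted negative controls), motif discovery (GTAAG / CAG / YTNCAG
recovered at the junctions) and the enrichment statistics.

The same stages run from the shell via the thin CLI:

```sh
sl-operon synth --seed 1 --outdir demo/
sl-operon tag-reads --reads demo/reads.fastq --out demo/trimmed.fastq
sl-operon operons --annotation demo/genes.gff3 --labels demo/labels.tsv \
    --repeats demo/repeats.bed --threshold 1000 --outdir demo/operons/
sl-operon find-slrna --genome demo/genome.fasta --outdir demo/slrna/
sl-operon run --config run.cfg   # full pipeline + JSON summary
```

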