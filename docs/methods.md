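# Methods

## Coordinate and data model

All intervals are 0-based half-open on the forward genomic strand;
conversion from 1-based inclusive conventions (GFF3, RepeatMasker `.out`)
happens only at I/O boundaries. A gene's span is its transcript span
(first exon start to last exon end); intergenic distances are measured
between these spans. Trans-splicing status, conservation class and
cell-type labels travel in side TSV tables rather than GFF3 attributes,
since in practice they come from separate studies.

## SL tagging and trans-splicing calls

A read is SL-tagged when the longest suffix of the 35-nt SL exon that
aligns ungapped to the read prefix has length ≥ `min_overlap` (default 12)
with at most `floor(overlap/12) × max_mismatch_per_12nt` mismatches
(default 1 per 12 matched nt). The 12-nt floor keeps the random-match rate
at ~4⁻¹² per position while tolerating one sequencing error per 12 nt.
These two knobs are package choices: the evidence rule in the source
analyses is qualitative ("presence of SL-containing reads at transcript
starts").

Trimmed-read placements come from SAM (POS/FLAG; the 5′ end is the
leftmost reference base for forward alignments, rightmost for reverse) or
a 4-column TSV; the package never aligns reads. A gene is called TS when
at least `min_reads` (default 2, resisting singleton artifacts)
strand-concordant placements fall within ± `window` (default 10 nt) of the
annotated transcript 5′ start.

## Operon inference

Adjacent pairs are consecutive same-strand genes on a scaffold, suppressed
when any opposite-strand gene's span intersects the open inter-gene
interval ("interrupted"), with partial overlap counting as interruption.
Genes fully nested inside another gene are skipped. Overlapping
same-strand neighbours get distance 0 and remain linkable — a zero gap is
the strongest adjacency signal. Upstream/downstream follow transcription
direction; the mixed category merges nonTS→TS and TS→nonTS for the
distance distributions, while operon extension stays strictly
order-sensitive (only a TS downstream gene extends a chain; a non-TS gene
may only be a chain's first member).

Repeat adjustment subtracts from each raw gap the number of bases covered
by the union of repeat intervals clipped to the gap, floored at 0. Mode
detection runs on log10(d+1) — distances span orders of magnitude — with a
Gaussian kernel at Silverman bandwidth on a 512-point grid; local maxima
map back to bp, ties break toward the smaller distance, and the valley is
the density minimum between the first two modes. The operon threshold
defaults to the fixed 1 kb rule on adjusted distances; the data-driven
valley is reported alongside but not used unless requested. Chains are
maximal and non-overlapping by a single scan in transcription order, so a
gene belongs to at most one operon. The fraction of TS genes in operons
counts operon members minus non-TS first genes, over all TS genes.

## SL RNA discovery

Candidates are exact occurrences of the SL seed on either strand
(overlaps included), extended to `candidate_length` (default 109 nt, the
observed gene length) in the 5′→3′ direction of the hit. Validation is
topological rather than thermodynamic: a base-pair-maximization fold
(Nussinov dynamic programming, Watson–Crick + GU pairs, hairpin loops
≥ 3 nt, deterministic traceback) must contain ≥ 3 hairpin loops. The
donor pattern defaults to the observed `GTAAG` (configurable to `GTRAG`);
the Sm pattern defaults to the literature-standard consensus `RAUUUUNGR` —
a package choice, as the authoritative Sm-site sequence is only available
as a figure. When an annotation is provided, a candidate whose seed lies
within 50 bp of a trans-spliced gene's 5′ start is rejected as a "coding
5′ end": such hits are SL-carrying mRNA starts, the failure mode that
produced a previously misassigned SL RNA.

Energy-based folding would rank alternative structures differently, but
the acceptance criterion here is hairpin architecture, not ΔG, and the
dynamic program is dependency-free and deterministic.

## Motif discovery

Junction windows are ±`flank` (default 50) bp around each junction,
normalized to transcript orientation; windows clipped by scaffold edges
are dropped. Discovery enumerates all exact k-mers (k in `k_range`)
observed in the positives, scores each by a one-sided Fisher exact test on
per-sequence containment (a window counts once regardless of occurrence
multiplicity, matching the "found in N regions" convention), and
Bonferroni-corrects by the number of words tested. Ranking uses an exact
log-space hypergeometric tail when p underflows double precision —
otherwise ties at p = 0 would resolve arbitrarily among nested words. The
best word is greedily generalized one position at a time over two-letter
IUPAC codes (kept when the p-value drops), reported when E ≤ `e_cutoff`,
masked out of the positives, and the search repeats up to `max_motifs`.
The default background is a seeded per-sequence dinucleotide shuffle
(Euler-path method, preserving each sequence's dinucleotide multiset); a
user-supplied background set is accepted. This is deliberately not a full
DREME reimplementation: no heap search over regular expressions and no
p-value refinement pass.

## Enrichment statistics

Cross-tabs count TS/nonTS × {conserved, non-conserved, non-coding};
genes with unknown labels are excluded from denominators and tallied.
Fractions print to 1 decimal and folds to 2, matching the precision of the
published figures. Fold enrichment is (subset rate)/(genome rate); both a
goodness-of-fit chi-square (subset counts against genome proportions) and
a 2×2 contingency chi-square are available, and neither is tuned to any
published p-value: the published chi-square p for the neoblast contrast is
not recoverable from the printed counts under any obvious construction, so
the statistic is implemented generically. Note also that the published
2.13-fold figure truncates: the printed counts give 2.135, which the
package reports as 2.14 at 2 decimals.

## Synthetic data

The generator emulates the study conditions: 2000 genes on 5 scaffolds,
30 % trans-spliced, 30 % of genes in operons (sizes 2:0.75, 3:0.18,
4:0.05, 5:0.02; 18 % of operons led by a non-TS gene). Intra-operon gaps
are log-normal with mode ~100 bp (µ = ln 100 + 0.25, σ = 0.5); between-
unit gaps log-normal with median 5 kb (µ = ln 5000, σ = 0.8); 25 % of gaps
receive a random-composition repeat block (log-normal, median 2 kb)
recorded in BED, so raw distances are repeat-inflated exactly as the
adjustment step assumes. Donor (`GTAAG`), acceptor (`CAG`) and
outron-acceptor (drawn from `YTNCAG`) words are planted at the
corresponding junctions with probability 0.8 each. Eight copies of a
designed 109-nt SL RNA construct (SL exon + donor + two GC stems with the
Sm word between them; its fold is asserted to contain ≥ 3 hairpins at
design time) are placed intergenically on random strands, plus two
negative controls: a copy with the donor replaced by `AAAAA`, and a full
construct overwriting the region 10 bp upstream of a TS gene start to
mimic the misassigned-SL-RNA failure mode. Each TS gene gets 10 reads with
SL prefixes truncated uniformly over 12–35 matched nt; every gene gets 3
internal body reads. Conservation classes are planted conditionally on TS
status with the published proportions (TS: 69.9/24.3/5.8 %; nonTS:
36.9/42.9/20.2 %), and neoblast labels preferentially on conserved TS
genes (5 % vs 0.5 %), giving the enrichment contrast a known direction.

What the generator does not emulate — and what passing tests therefore do
not demonstrate for real data: sequencing errors and coverage variation,
realistic repeat families and nested repeats, alternative transcription
starts, overlapping or nested real transcripts, GC/composition bias, and
assembly artifacts. The planted-truth checks validate the algorithms'
correctness under the stated generative model, not their robustness to
annotation noise.

One spec-level default is worth noting: the generator plants 30 % of genes
in operons (for statistical power of the recovery checks), while the
published estimate for the real genome is ~15 %; the published operon
fractions are reproduced separately by exact arithmetic on the published
counts.

## Numerical and design choices

* Dataset generation, shuffling and motif search are deterministic given
  the seed; the pipeline summary is byte-stable across reruns.
* `fold_max_pairs` traceback prefers leaving the 5′ base unpaired only
  when optimal, then the smallest optimal partner index, so structures are
  reproducible.
* KDE mode detection returns a single mode for zero-variance samples and
  none for samples of fewer than two values.
* Label tables with duplicate gene ids, malformed annotation records (with
  line numbers) and unbalanced dot-bracket strings raise errors rather
  than warn.
* Problem sizes in the acceptance script (2000 genes, ~12 Mb genome,
  k ≤ 6 motif search) were chosen so the full planted-truth recovery runs
  in seconds while keeping every distributional feature the analysis
  depends on.

## Known limitations

* Operon calling trusts the annotation's transcript spans; fragmented
  annotations will split operons exactly as they split transcriptional
  units in real assemblies.
* The motif search enumerates exact words before generalizing, so motifs
  whose every instantiation is rare (long words with several degenerate
  positions) are found only through their constant core.
* The Nussinov fold ignores stacking energies; it can report more, shorter
  stems than a thermodynamic fold would.
* The published chi-square p-value for the neoblast contrast and the
  2.13-fold rounding are not exactly reproducible from the printed counts
  (see Enrichment statistics above).
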