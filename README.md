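# pbmine

Mining and evolution profiling of TTAA-specific (piggyBac-like) DNA
transposons in genome sequence, plus a synthetic-genome simulator that
plants elements with known structure and divergence so every stage can be
validated against an exact truth table.

## What it does

Given a genome FASTA and a bundled set of clade-labeled reference
transposase proteins, the pipeline:

1. **Seeding** (`pbmine.seeding`) — six-frame translated homology search
   (peptide k-mer seeding + BLOSUM62 affine-gap local alignment), then
   extends hits by 2000 bp flanks and merges them into candidate loci.
2. **Boundaries** (`pbmine.boundaries`) — finds maximal terminal-inverted-
   repeat (TIR) arm pairs inside each locus and anchors element boundaries
   on target-site duplications (TSDs), preferring canonical `TTAA` flanks,
   then equal (mutated) flanks, then longer arms.
3. **Annotation** (`pbmine.annotation`) — longest-ORF transposase
   prediction on both strands, catalytic-triad (DDD) and cysteine-rich
   domain scans by alignment to the clade consensus, and classification:
   *intact* (TIR+TSD detectable and ≥ 500 aa transposase), *full*
   (TIR+TSD detectable), *truncated* (otherwise).
4. **Census** (`pbmine.census`) — seed-and-extend nucleotide copy search;
   copies counted at strict thresholds (query coverage > 40% and identity
   > 80%); majority-rule star-alignment consensus when a family exceeds
   10 copies, otherwise the longest intact copy is the query.
5. **Divergence dynamics** (`pbmine.divergence`) — Kimura 2-parameter
   distance of every copy to the family consensus, landscapes of genome
   coverage per 1% K bin, and age calls (*recent* when the majority of
   copy bp sits below K = 2%, *old* above K = 15%, wave detection for
   multiple amplification episodes).
6. **Comparative** (`pbmine.comparative`) — pairwise identity matrices
   with within/between-clade summaries, a neighbor-joining tree (exact on
   additive distances), outgroup-rooted clade assignment, and TIR
   sequence-logo matrices (position frequencies + information content).

The simulator (`pbmine.synthetic`) generates genomes with planted
elements — configurable element/TIR/TSD layout, transposase length, copy
number, truncation rate, and divergence waves drawn from an exact K2P
forward model — and emits a truth table used by `pbmine.pipeline.evaluate`
to score precision, recall and boundary-exact fraction.

## CLI

```bash
# generate a synthetic genome with 10 copies per clade (A, B, C)
pbmine simulate --genome-length 1000000 --copies 10 --seed 1 --out sim/

# run everything and score against the truth table
pbmine all --genome sim/genome.fa --truth sim/truth.tsv --out run/

# individual stages
pbmine seed --genome sim/genome.fa --out run/
pbmine boundaries --genome sim/genome.fa --loci run/loci.bed --out run/
pbmine annotate --genome sim/genome.fa --elements run/elements.bed --out run/
pbmine census   --genome sim/genome.fa --out run/
pbmine dynamics --genome sim/genome.fa --out run/
pbmine compare  --genome sim/genome.fa --out run/
pbmine evaluate --truth sim/truth.tsv --elements run/elements.bed --out ev.json
```

Outputs: BED6 (0-based half-open) for hits/loci/elements, TSV reports
(the element table is 1-based closed, flagged in its header comment),
FASTA for proteins and family queries, Newick for the tree, JSON for the
run summary and evaluation.

## Layout

```
src/pbmine/            one module per stage (see above)
src/pbmine/data/       bundled reference transposases + feature annotation
scripts/acceptance.py  acceptance report
scripts/make_reference_bundle.py  regenerates the bundled data (committed)
tests/                 pytest suite; tests/oracles.py holds independent
                       brute-force oracles (no shared code with pbmine)
```
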