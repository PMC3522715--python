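# fishprobes

Design of locus-specific DNA FISH probes with genome-wide specificity
screening — including probes for *locally repetitive* sequence that
conventional single-copy probe designers must discard.

## The problem

Fluorescence in-situ hybridization (FISH) detects a chromosomal target with
labeled DNA probes complementary to it. A probe is only informative if its
sequence is specific: if parts of it match other places in the genome it
cross-hybridizes and the signal becomes ambiguous. Repeat-rich loci such as
the immunoglobulin heavy-chain constant region are therefore hard targets —
much of the locus is similar to something else. But a repeat whose copies
all lie *inside* the locus of interest is still perfectly locus-specific: a
probe against it binds several sites, every one of them in the right place,
and the stacked signal is brighter than any single-copy probe.

`fishprobes` operationalizes this. Given a query sequence and the genome it
comes from, it:

1. **aligns** the query genome-wide (built-in seed-and-extend aligner, or
   imported 12-column tabular hits from an external aligner), keeping local
   alignments with bit score `(λ·S − ln K)/ln 2 ≥ 200` by default;
2. **classifies** every query base as `UNIQUE` (one genomic site),
   `SIMILAR_LOCAL` (several sites, all inside the query's own locus) or
   `SIMILAR_GLOBAL` (at least one site elsewhere);
3. **tiles** unique blocks exceeding 4 kb with consecutive single-copy
   amplicons (1–10 kb), maximizing covered bases;
4. **selects repetitive targets** inside nearly contiguous similar blocks by
   greedy maximum coverage, maximizing the cumulative length of predicted
   binding sites (the classic greedy gives the (1 − 1/e) guarantee and is
   exhaustively optimal on small instances, which the test suite checks);
5. **screens** every amplicon for forbidden restriction sites (ClaI
   `ATCGAT` by default), shifting or splitting amplicons so products can be
   cloned and screened by restriction digest;
6. **designs one PCR primer pair per amplicon** with a built-in
   nearest-neighbor-Tm engine, and prepends the lowercase `atcgat` linker to
   both 5' ends for clone screening.

Outputs are BED tracks (mask, blocks, BED12 targets with binding sites as
blocks), amplicon FASTA, a TSV primer table, a track figure (white = unique,
gray = globally similar, cyan = locally repetitive), a human-readable report
in 1-based coordinates, and the fully commented effective configuration.

A synthetic-genome simulator (`fishprobes.simulate`) plants unique, locally
repetitive and globally similar segments with known truth labels, and
provides the independent oracles (exhaustive maximal-scoring-segment
masking, brute-force in-silico hybridization, exhaustive subset selection)
the pipeline is validated against.

## Worked example

Simulate a ~50 kb genome whose 24.5 kb focal locus contains three long
unique stretches, a three-copy local repeat family (1.5 kb copies) and a
global repeat with copies outside the locus, then design probes for it:

```sh
fishprobes simulate --seed 1 --out-dir sim
# genome 50500 bp, query 24500 bp, locus chr1:13001-37500; outputs in sim
fishprobes report --query sim/query.fasta --genome sim/genome.fasta --out-dir design
# designed 8 probe targets (18.5 kb, binding 22.1 kb); outputs in design
```

`design/report.txt` then contains (abridged):

```
[similarity mask]
UNIQUE: 19004 bp (77.6%)
SIMILAR_GLOBAL: 999 bp (4.1%)
SIMILAR_LOCAL: 4497 bp (18.4%)

[probe targets]
A  single_copy  query:184-4901     4718 bp  binds 4718 bp
B  single_copy  query:6602-8272    1671 bp  binds 1671 bp
...
x  repetitive   query:15002-15908   907 bp  binds 4499 bp
F  single_copy  query:16547-22877  6331 bp  binds 6331 bp
```

Single-copy probes (A, B, …) each bind exactly one genomic site. The
repetitive probe `x` sits inside one copy of the local family and binds all
three copies — 4499 bp of binding from a 907 bp probe — while touching
nothing outside the locus; the globally similar kilobase (gray) yields no
probe at all. The primer table pairs every target with linker-extended
primers, e.g.

```
A  atcgatTGGGTGTGAATGGGCGCGAC  atcgatACCCACTGAGCTTCCGGCCA  product 4718 bp
```

where the lowercase `atcgat` is the ClaI linker and the uppercase core is
the genomic primer whose Tm (57–63 °C window) is computed on the core only.

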