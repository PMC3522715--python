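# Methods

## Similarity model

The unit of evidence is an ungapped local alignment ("hit") between the
query and the genome, scored +1/−2 per match/mismatch and normalized to
bits with the Karlin–Altschul parameters published for that matrix
(λ = 1.28, K = 0.46): `bits = (λ·S − ln K)/ln 2`. Hits below the
`min_bits` threshold (default 200, i.e. raw score ≈ 108) are discarded —
short chance similarities at this level are not expected to support stable
probe hybridization. The built-in aligner seeds on exact 16-mers on both
strands and extends each seed without gaps under X-drop termination
(default X = 20); gapped alignments enter only through imported tabular
hits. All subject intervals are stored on the forward strand; minus-strand
hits are first-class.

### Per-base classification

Every hit covering a query base maps that base to one genomic point — its
diagonal image. Points on the same subject within `word_size` bases of one
another merge into one *site*, so stacked or frayed alignments to one place
count once. The base's label follows from its site set:

- one site (its own locus): `UNIQUE`;
- several sites, all inside the self locus: `SIMILAR_LOCAL`;
- any site outside: `SIMILAR_GLOBAL`.

An earlier formulation counted merged *subject intervals* instead of image
points; it is degenerate, because the full-length self hit spans the whole
locus and absorbs every within-locus repeat site. The point-image rule
keeps "overlapping hits to one place are one site" without that collapse.

The *self locus* — the reference for "local" — is either declared
(coordinates in the query FASTA header or `--locus`) or detected as the
highest-scoring hit with ≥ 99% identity covering ≥ 95% of the query; ties
break to the lexicographically smallest (subject, start).

### Regions

Maximal label runs partition the query. Unique blocks must *exceed*
`min_unique_len` (default 4000 bp — strictly greater, so a 4000 bp block is
excluded and 4001 bp included). Similar blocks merge `SIMILAR_*` runs
separated by at most `max_gap` bases (default 500 bp: smaller than any
amplicon, larger than typical alignment fraying at repeat edges); block
boundaries always lie on similar-labeled bases.

## Probe design

**Single-copy tiling.** Each unique block is partitioned left-to-right into
consecutive amplicons with lengths in `[amplicon_min, amplicon_max]`
(defaults 1000–10000 bp, bracketing long-PCR practice), maximizing covered
bases: the number of pieces is the smallest that can reach full coverage,
each piece as long as possible subject to leaving at least `amplicon_min`
for the rest; when full coverage is arithmetically impossible the remainder
(< `amplicon_min`) stays uncovered at the right edge. A unit test checks
the partition against an exhaustive integer oracle.

**Repeat families.** Non-self hits mapping entirely inside the self locus
contribute two query intervals each (the aligned span and the subject span
translated to query coordinates). Intervals linked by a hit or by mutual
overlap merge transitively (union-find); members are trimmed to
`SIMILAR_LOCAL` bases. A family needs at least two members.

**Repetitive candidates and selection.** Candidate windows slide through
each similar block at step `amplicon_min/2` in both position and length.
A window qualifies if ≥ 90% of its bases are `SIMILAR_LOCAL` and none is
`SIMILAR_GLOBAL` — global contamination is banned outright because it
breaks locus specificity. A window inherits the binding sites of every
family it overlaps by ≥ `amplicon_min/2` bp. Selection is greedy maximum
coverage over the union of binding sites, with non-overlapping probe
intervals, stopping when the best marginal gain falls below `min_gain`
(default 500 bp); ties break to the smaller start, then the shorter window.
Greedy is chosen for determinism and the (1 − 1/e) worst-case guarantee;
on instances of ≤ 15 candidates the tests compare it against exhaustive
enumeration, where it attains the optimum on modular instances.

**Restriction screening.** Amplicons must not contain any configured
restriction site or its reverse complement (default ClaI `ATCGAT`, a
palindrome), because the same site serves as the cloning linker and a
clone-screening digest. In `enforce` mode (default) an amplicon containing
a full site occurrence is shifted within its block (respecting length
bounds and neighboring amplicons); if no single placement fits, the free
span is cut at each occurrence's midpoint and one part ≥ `amplicon_min` is
emitted per segment (a part may contain a *truncated* site at its edge,
which is harmless — only complete recognition sequences are cut or
screened); if nothing fits the target is dropped and logged. `verify` mode
only annotates. After enforcement a rescan of every emitted amplicon
returns no occurrence, which is asserted in the acceptance suite.

## Primer design

The built-in engine scores each candidate primer on hard windows — length
18–27 nt, Tm 57–63 °C, GC 0.2–0.8, homopolymer runs ≤ 4, self-
complementarity ≤ 8 (best ungapped antiparallel Watson–Crick pairing
count) — and a penalty of absolute deviation from the optima (20 nt,
60 °C). Tm is the unified nearest-neighbor sum (Allawi–SantaLucia
enthalpies/entropies with initiation terms), entropic monovalent-salt
correction 0.368·(N−1)·ln[Na+] at 50 mM, and duplex concentration CT/4 at
50 nM primer; the implementation is cross-checked in the tests against the
Biopython NN engine configured identically, to machine precision.

Forward 5' ends are searched within `primer_search_margin` (200 bp) of the
target start, reverse 5' ends within the margin of the target end, both
*inside* the target so the product never leaves the screened interval.
Pairs with Tm difference > 3 °C or pair complementarity > 8 are rejected;
among the rest the pair minimizing `penalty_f + penalty_r + |ΔTm|` wins,
ties going to the smaller product, then the leftmost forward primer. The
search is branch-and-bound over penalty-sorted candidates and provably
returns the exhaustive minimum (asserted against brute force at reduced
margins). The emitted target's interval is set to the product interval, so
a final amplicon can be up to 2·margin shorter than its nominal tile —
products therefore may slightly undershoot `amplicon_min`, while
tiling/selection outputs always respect the bounds. Both primers finally
receive the lowercase 5' linker (`atcgat`); Tm and coordinates refer to
the uppercase core only, since the linker is unpaired in early PCR cycles.
A target with no feasible pair (e.g. dinucleotide-repeat sequence that
cannot satisfy the GC window) is dropped and logged, never silently
omitted.

## Synthetic genomes and oracles

`GenomeSpec` concatenates segments of three kinds — unique background,
`local_repeat` (all copies inside the locus) and `global_repeat` (copies
inside *and* outside) — with per-family master sequences and per-copy
substitution divergence (≤ 10%; no indels, so per-base truth labels remain
exact). The query is the locus substring. The default "ig-like" fixture
echoes a repeat-rich immunoglobulin-locus geometry: three unique stretches
of 5–8 kb, a three-copy 1.5 kb local family at 2% per-copy divergence, and
a 1 kb global family with one copy inside and two outside, ~50 kb total.
Randomized specs keep repeat copies separated by ≥ 2.5 kb of unique
sequence so planted structure stays resolvable.

Three independent oracles validate the pipeline:

- **Masking:** on every diagonal (both strands) that shares an exact
  16-mer with the query, all maximal scoring segments are enumerated with
  the Ruzzo–Tompa algorithm, thresholded at the same bit score, and
  labeled per base by the same point-image rule — an exhaustive
  replacement for seed-and-extend heuristics.
- **Hybridization:** brute-force scan for ungapped windows of ≥ 100 bp at
  ≥ 85% identity (the scale of the 100–300 nt fragments a labeled probe is
  physically sheared into), merged into loci.
- **Selection:** exhaustive enumeration of non-overlapping candidate
  subsets (≤ 15 candidates).

Comparisons exclude a *collar* of `word_size` bases around any label
transition in either mask: exact-word seeding cannot resolve repeat
boundaries closer than one word, and both the aligner and the oracle end
segments at the score peak of the same random walk into flanking sequence.
This is a documented limitation, not hidden slack; outside collars the
acceptance suite requires exact agreement.

What passing these tests shows — and does not. The simulator emulates
repeat *geometry* (copy number, placement, point divergence), not real
genome evolution: no indels, no satellite microstructure, no GC
heterogeneity, no assembly gaps. Passing demonstrates the algorithmic
contracts (classification, coverage objective, screening soundness, primer
optimality, determinism); probe behavior on a real genome still depends on
the assembly and aligner parameters used.

## Problem sizes and determinism

Desk-scale defaults keep everything exhaustive-checkable: simulated genomes
are 25–55 kb (cap 200 kb), oracle comparisons run on 20 seeded genomes,
selection oracles on ≤ 15 candidates, and primer brute-force checks at
25–30 bp margins; the acceptance script finishes in a few minutes on one
CPU. Every random choice flows from a single integer seed through
`numpy.random.default_rng`; the pipeline itself is deterministic (sorted
orders, explicit tie-breaks), and identical seed + configuration produce
byte-identical BED, report, table and PNG outputs (figure metadata is
stripped).

## Degenerate inputs

Empty hit lists classify everything `UNIQUE`; a query absent from the
genome build raises "self locus not found" rather than guessing; N runs are
never seeded and never count as matches; blocks shorter than
`amplicon_min` are skipped with a log entry; an all-N genome yields no
hits. Configuration files reject unknown keys outright (listing them) so a
typo cannot silently revert a parameter to its default.
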