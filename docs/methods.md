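# Methods

## The model

An FNTDC (functional non-tandem-duplicated cluster) is operationally
defined here as a window of GO-BP-annotated genes in which, after
tandem-duplicate collapse, at least three genes share one GO-BP term
whose hypergeometric upper-tail probability against the genome-wide
GO-BP background falls below a threshold. The scanner makes three
modelling commitments:

* **Gene-rank geometry.** All window arithmetic is on gene order
  (ranks), never base pairs. Plant genomes differ enormously in repeat
  content, so fixed-kb windows are not comparable across species;
  fixed-gene-count windows are. Base-pair coordinates are carried only
  for span reporting and BED output.
* **GO-BP-only universe.** Both the universe (N) and the test set (n)
  count only genes with at least one GO-BP tag. Genes without GO-BP stay
  in the catalog — they contribute to span lengths, "all genes in
  cluster" counts and unknown-gene accounting — but never to window
  sizes or tests.
* **One call per master window.** Master windows of 24 GO-BP genes tile
  each chromosome without overlap; each emits at most one call (its
  lowest-P sub-window). Two true clusters inside one master window
  therefore yield one call; the synthetic-genome experiments reproduce
  exactly this failure mode, and it is the main cost of the tiling
  design. A trailing block of ≥ 6 genes is still scanned; smaller
  remainders are dropped.

## Windows

The default sub-window scheme probes, within a 24-gene master, lengths
24, 18, 12, 8 and 6 at systematic offsets
(24:[0]; 18:[0,6]; 12:[0,6,12]; 8:[0,8,16]; 6:[0,6,12,18]) — 13
sub-windows including the master itself, covering lengths 6–24. The
layout is a configuration value (`SubWindowScheme.entries`), chosen as a
uniform tiling that realizes those counts; alternative layouts can be
substituted in the run config. The exhaustive mode probes all
(offset, length) pairs down to a minimum length (253 for a full master
at minimum 3); it removes the discretization artifacts of the fixed
scheme at ~20× the testing cost. The minimum default sub-window of 6
keeps split clusters rare while bounding the number of tests.

Sub-window selection is by minimum P of the best enriched term; ties
break to the shorter sub-window, then the smaller offset (the tightest,
leftmost cluster consistent with the signal). The P threshold is applied
*after* selection, which is what makes call sets nest exactly across
thresholds (1e-8 ⊆ 1e-7 ⊆ 1e-6 ⊆ 1e-5 with identical winning
sub-windows).

## Tandem-duplicate collapse

Within each master window, proteins are compared all-against-all with a
local Smith–Waterman alignment (BLOSUM62, gap open 11, extend 1 — the
classic gapped-BLASTP parameterization) via Biopython's
`PairwiseAligner`; the highest-scoring local alignment per pair is kept.
E-values use the Karlin–Altschul formula with standard gapped BLOSUM62
constants (λ = 0.267, K = 0.041) over a q_len × s_len search space; they
gate only what is *recorded* (E ≤ 10) and reported, never the tandem
call itself, which depends solely on identity and coverage.

A pair is a tandem-duplicate link under a preset when percent identity
(matches / alignment columns, gaps included) and both coverage ratios
(alignment length / query length, alignment length / subject length)
clear the preset's thresholds: settings 1–4 at (40 %, 0.4), (70 %, 0.7),
(90 %, 0.9), (98 %, 0.98). The gap-included alignment length feeds the
ratios; gap-excluded lengths are recorded alongside in the hit dumps.
Groups are single-linkage connected components of passing pairs; each
group keeps its first member by (start, end, gene id) and drops the
rest from the tested window (idempotent, and applied per sub-window
from hits computed once per master window). Universe counts are *not*
collapsed — collapse is a per-window operation, and N / term sizes K
always describe the full genome.

Two numerical shortcuts:

* **Word prescreen.** A pair is aligned only if the two proteins share
  at least one exact 5-mer, in the spirit of BLAST's seed-and-extend.
  Unrelated ~300-aa random proteins share a 5-mer with probability
  ≈ 3 %, so almost all unrelated pairs are skipped; any pair near even
  the loosest 40 % preset shares many seeds. Pairs without a seed
  produce no hit, exactly as a seeded search would find nothing.
* **Representative isoform.** Each gene is represented by its longest
  protein isoform (ties to the lexicographically smallest isoform id),
  carrying the union of all isoforms' GO tags. Genes with no protein
  sequence are kept in the catalog but never aligned or grouped.

## The enrichment test

Per term, P(X ≥ k) for X ~ Hypergeom(N, K, n) is evaluated as an exact
big-integer/rational sum whenever min(n, N−n) ≤ 200 — always true for
≤ 24-gene windows — and by `scipy.stats.hypergeom.sf` otherwise. The
exact route is unconditional raw-P testing in the style of GOstats'
`hyperGTest` with `conditional=FALSE`; no multiple-testing correction is
applied, matching the raw-P threshold grid (1e-5…1e-8) the method is
defined over. Odds ratio k(N−K−n+k)/((n−k)(K−k)) is reported as `Inf`
when a margin is exhausted (k = n or k = K); expected count is nK/N.
The min-count prerequisite (default 3) applies to the *collapsed* count
k. Optional ancestor propagation ("true path rule", roots excluded) is
available when an OBO ontology is supplied, default off — annotation
sets that were already ontology-augmented upstream must not be
propagated twice.

## The synthetic-data generator

`synthetic_data.generate_genome` emits GFF3 + protein FASTA + annotation
TSV + a truth TSV, deterministically per seed. It emulates: gene lengths
1–6 kb and intergenic gaps 0.5–15 kb (typical compact plant-genome
spacing); 38 % of genes without GO-BP, 20 % without any GO tag
(matching the roughly one-third-unannotated reality of plant genomes);
a background GO-BP vocabulary of 500 terms assigned i.i.d. (1–4 terms
per annotated gene), so background terms cluster positionally only by
chance; ~10 % of genes with a second, truncated isoform to exercise
representative selection; random i.i.d. proteins of 150–450 aa.

Planted clusters occupy runs of consecutive GO-BP ranks and share one
dedicated term drawn from an id range disjoint from the background
vocabulary (the truth table is therefore unambiguous); their proteins
are independent random sequences, so they are non-homologous by
construction — random-protein local-alignment identity sits far below
the 40 % preset. Planted tandem arrays occupy runs of adjacent genes
whose proteins derive from one random ancestor by per-site substitution
at rate (1 − identity)/2 per copy, so the *pairwise* identity between
copies concentrates at the configured target; replacements are uniform
over the 19 alternative residues (no indel model, no codon model — the
collapse logic under test is identity/coverage-driven, and indel realism
would not change what is being exercised). `shuffle_go_labels` permutes
complete GO-BP sets across carrier genes as the null model: term
frequencies and the universe are conserved, positional signal is
destroyed.

What passing on these genomes does *not* show: performance on real
annotation error structure (correlated, ontology-shaped annotations;
shared terms among true paralogs beyond planted arrays), on nested or
overlapping real clusters, or on genomes whose GO-BP coverage differs
strongly from the simulated 62 %.

## Problem sizes and validation protocol

The validation suite (and `scripts/acceptance.py`) uses a 3,000-gene,
3-chromosome reference genome with 15 planted clusters of 4–6 genes at
generator seed 42, and a 1,000-gene two-feature fixture (one planted
4-gene cluster, one 5-copy tandem array at 95 % pairwise identity, seed
7, placed in distinct master windows so the stringency contrast is
observable). At intermediate stringency (setting 2, P ≤ 1e-6) the
reference scan recovers 14/15 planted clusters; the miss is two clusters
sharing one master window (see "One call per master window" above). The
null control — ten label-shuffled replicates of the reference genome —
yields zero calls. The hypergeometric tail is checked against exhaustive
subset enumeration in exact rational arithmetic over all feasible tables
with N ≤ 15, and against scipy independently. Determinism is checked at
byte level on full scan output trees.

## Known limitations

* Adjacent calls in consecutive master windows are never merged; very
  large clusters may appear split.
* E-values are Karlin–Altschul estimates, not a re-implementation of
  BLAST's edge-corrected statistics; they are reporting metadata only.
* The identity-matrix report replaces rendered multiple-alignment
  figures; no images are produced.
* Star-vs-single-linkage grouping is unresolved in principle for
  sparse homology graphs; single linkage is used, as an all-against-all
  analysis implies component closure.
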