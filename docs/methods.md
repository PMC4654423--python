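# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## Domain grammar

A WRKY domain is detected as two coupled motifs:

1. a **heptapeptide**, either canonical `WRKYGQK` or the degenerate
   consensus `W[RK]KY[GA].K` (capturing GQK-less second domains of
   two-domain proteins);
2. a **zinc finger** `C x(4,8) C x(22,28) H x(1,2) [HC]` whose first
   cysteine must start within a window of 60 residues after the
   heptapeptide. The terminal residue classifies the finger: H → C2H2,
   C → C2HC.

The single spacer envelope deliberately unifies the two published
consensi (CX4–5CX22–23HXH and CX5–8CX25–28HX1–2C): they overlap, and the
terminal-residue type carries the discriminating signal. The window of
60 residues is a package choice (the literature does not bound the
heptapeptide–finger gap); it is a parameter of `assemble_domains`.
Scanning is purely positional: canonical matches are collected first,
left to right and non-overlapping, then non-overlapping degenerate
matches; at a given first cysteine the lexicographically smallest
(spacer1, spacer2, spacer3) parse wins. There is no profile scoring and
no E-value — determinism and testability are the point. Degenerate
heptapeptides count as evidence only when a finger follows; on their own
they are too weak (they occur as supporting second domains in practice).

## Family classification

Group rules, applied to the assembled domain list:

| group | rule |
| --- | --- |
| I | ≥ 2 complete domains (a 3-domain protein is still group I) |
| II | exactly 1 complete domain, C2H2 finger |
| III | exactly 1 complete domain, C2HC finger |
| IV | heptapeptide evidence, no complete domain |
| none | no heptapeptide at all |

Subgroups IIa–IIe are assigned by **nearest labelled reference**: the
query's domain region ± 25 flanking residues is globally aligned
(BLOSUM62, open 10 / extend 0.5) to every reference; the closest
reference's label wins, exact ties fall back to a 3-nearest-neighbour
majority and then the lexicographically smallest label. This replaces
reading subgroup membership off phylogenetic clades: it is deterministic,
O(#refs) per query, and directly testable; the NJ route remains available
through the phylogeny module for anyone who prefers clade parsing. The
packaged default reference set consists of synthetic subgroup exemplars
generated by `generate_reference_set` (three per subgroup, fixed seed);
real labelled references (e.g. maize WRKY exemplars) can be supplied as a
FASTA with `subgroup=` tags.

## Phylogeny

* **Distances.** From an alignment: p-distance (mismatches over compared
  columns) or Poisson-corrected −ln(1−p), with *pairwise* gap deletion
  (complete deletion would discard most columns in gappy family
  alignments; the choice is switchable by preprocessing the alignment).
  From unaligned sequences: a k-mer (default k = 3) profile
  dissimilarity, d = 1 − 2·Σmin(counts)/(n₁+n₂). The survey pipeline
  uses the k-mer route when no alignment is supplied.
* **Neighbor joining.** Standard Saitou–Nei: join the pair minimising
  Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·); branch lengths by the NJ
  formulas; the final three nodes close the unrooted tree by the
  three-point formulas. Ties in Q are broken by the smallest sorted pair
  of cluster labels (a cluster is labelled by its smallest leaf), so any
  input produces exactly one tree. Negative branch lengths (possible on
  non-additive matrices) are clamped to 0 with a log message. On
  additive matrices the algorithm is exact; the test suite checks exact
  topology and branch-length recovery (tolerance 1e−9) on random trees
  with up to 12 leaves.
* **Bootstrap.** Columns are resampled with replacement by a seeded
  generator; an internal edge's support is the percentage of replicate
  trees containing its leaf bipartition. The conventional default is
  1000 replicates; the tests use far fewer (they test the machinery, not
  the precision of a support value).

## Duplication and molecular evolution

* **Paralog pairs** are all protein pairs at global-alignment identity ≥
  a threshold. The pipeline default is 0.70 for paralogy: at the
  divergence this family's duplicates actually show (Ks ≈ 0.3–0.4,
  Ka/Ks ≈ 0.1) protein identity sits near 0.90, so a 0.90 paralog cutoff
  would drop genuine duplicates; 0.90 is reserved for cross-species
  orthology, where it is the published convention.
* **Tandem**: same chromosome, at most `max_intervening` (default 1)
  genes between the pair.
* **Segmental**: within each chromosome pair, homolog pairs are chained
  by the longest strictly monotonic subsequence in (rank_a, rank_b)
  space, both orientations tried, per-step rank gap ≤ `max_rank_gap`
  (default 10) on both sides; chains of ≥ `min_block` (default 3) pairs
  become blocks; a pair joins at most one block (longest chain first,
  ties by earliest start rank). This is a deliberate simplification of
  MCScanX's DAG chaining: no E-value weighting, plain gene ranks. Note a
  combinatorial fact that shapes the tests: any 5 collinear pairs
  shuffled *within a tight window* still contain a monotone run of 3
  (Erdős–Szekeres), so a meaningful negative control must scatter ranks
  beyond the gap limit, as a genome-wide order shuffle does.
* **NG86 Ka/Ks.** Synonymous sites per codon are the fraction of the
  nine possible point changes that preserve the amino acid; changes to
  stop codons count as nonsynonymous, which keeps S + N = 3 × codons
  exactly. Observed differences average over all minimal substitution
  pathways with equal weight, excluding pathways through stops (kept
  only if every pathway is blocked). Jukes–Cantor correction
  d = −(3/4)ln(1 − 4p/3); a proportion ≥ 3/4 is reported as *saturated*
  — a flagged outcome, not an exception, because real family surveys hit
  it. Codon columns containing a gap or N are dropped. The estimator is
  symmetric in its arguments and is tested codon-exactly against an
  independent brute-force pathway-enumeration oracle.
* **Dating.** T = Ks/(2λ), λ defaulting to 6.5 × 10⁻⁹
  substitutions/site/year (the grass synonymous clock); overridable per
  run. Ks = 0.13 → 10 Mya.
* **Orthology.** Reciprocal best hits by alignment score; ties yield no
  call (logged) rather than an arbitrary winner, so the output is
  symmetric under swapping the two sets.

## Promoters, expression, enrichment

* Cis-elements are IUPAC consensus patterns (W-box `YTGACY`, the
  `TGAC` WRKY core, CAAT box, GATA box, Dof core, E-box/MYC, ARR1,
  CACTFTPPCA1, ABRE core, HSE) matched on both strands of the 2-kb
  upstream region; minus-strand hits are reported at the plus-strand
  coordinate of their leftmost base; overlaps are all reported; `N`
  never matches. This is consensus matching, not weight-matrix scoring.
* RPKM = 10⁹·C/(N·L) with N the per-sample column sum unless library
  sizes are given. The heatmap export applies log2(RPKM + 1).
* 2^(−ΔΔCt) assumes 100 % primer efficiency; technical replicates are
  averaged before differencing; the control timepoint is the calibrator,
  so its fold is 1 by construction.
* Enrichment: upper-tail hypergeometric per term (terms with no
  annotated population genes are skipped), Benjamini–Hochberg q-values
  across all tested terms.

## Protein properties

Average residue masses (plus one water) give MW; `X` uses the mean
residue mass. Net charge is the Henderson–Hasselbalch sum over termini
and D/E/C/Y/K/R/H side chains with the Bjellqvist pKa set (packaged,
swappable); pI is found by bisection on [0, 14] to |charge| < 1e−4. The
instability index is (10/L)·Σ DIWV(aa_i, aa_{i+1}) over the standard
400-entry dipeptide weight table, with the conventional threshold of 40
separating stable from unstable calls.

## Synthetic data: what it emulates, and what it does not

Generators draw all randomness from one explicit seeded generator;
identical seeds give byte-identical datasets, and every dataset carries a
truth record sufficient to score any stage exactly.

* **Proteins.** Uniform-random background over the 20 amino acids with a
  planted group-specific domain template. Template filler avoids C and W
  so accidental cysteines/heptapeptide seeds cannot shadow the planted
  grammar; each subgroup has a fixed template (distinct filler and
  spacer geometry), which is what the nearest-reference classifier keys
  on. Generation is rejection-sampled until the scanner recovers exactly
  the planted heptapeptides and group, so planted truth holds by
  construction. Optional substitution noise hits non-anchor positions
  only (anchors: heptapeptide residues and the four finger-coordinating
  residues), then revalidates.
* **CDS divergence.** `mutate_cds` applies synonymous and nonsynonymous
  point substitutions (never creating stops, nonsynonymous changes
  refused inside protected codons) until the measured NG86 proportions
  reach the inverse-JC targets; a step that would overshoot is accepted
  with probability proportional to the remaining deficit, making the
  recovered estimates unbiased around the target. Steps are constrained
  not to disturb the other channel's pathway-averaged count, which
  removes the cross-channel bias that naive interleaving produces.
* **Genomes.** Ordered gene models on multiple chromosomes with
  intergenic spacers, 1–4 exons per gene, both strands; tandem pairs
  planted at adjacent ranks and collinear runs (optionally inverted)
  across chromosome pairs, with plants spaced > the chaining gap so
  distinct plants cannot merge. The survey-shaped preset reproduces the
  survey's structure — 105 family proteins (I:10; IIa:5, IIb:8, IIc:20,
  IId:9, IIe:12; III:39; IV:2) on 9 chromosomes, 10 tandem + 8
  segmental pairs (blocks of 5 and 3 between chromosomes 3 and 5, one
  inverted), group IV on chromosome 5, group I absent from chromosomes 1
  and 4 — with duplicate CDSs diverged at Ks 0.377/Ka 0.049 (tandem) and
  Ks 0.299/Ka 0.030 (segmental), i.e. Ka/Ks ≈ 0.13 and 0.10 at ≈ 29 and
  23 Mya under the default clock. Intergenic gaps are ≥ 4.3 kb so that
  adjacent genes' 2-kb promoter windows never overlap and planted
  elements cannot collide.
* **Promoters/expression.** Planted IUPAC elements at recorded
  positions/strands (backgrounds scrubbed of accidental catalog hits
  where the catalog is non-nested; with nested patterns — a W-box
  necessarily contains a TGAC core — recall, not exactness, is the
  guaranteed property). Counts are Poisson around gene-specific
  lognormal rates scaled by planted folds; Ct values are
  baseline − log2(fold) + N(0, σ) with a flat reference gene.

What the generators do **not** emulate: real amino-acid composition and
domain-flank conservation gradients, intron-phase structure, transposon
and repeat content, alignment ambiguity (planted duplicates align
gaplessly), overdispersed RNA-seq counts, or primer-efficiency artefacts
in qPCR. Passing the planted-truth suite therefore demonstrates that the
algorithms are correct and internally consistent, not that their
thresholds are tuned for any particular real genome.

## Problem sizes and determinism in the test suite

The suite exercises: 1000 planted proteins + 500 decoys for
classification (plus 200 noisy subgroup queries), 200 random additive
matrices (n ≤ 12) for NJ, a fixed 500-case codon-pair suite against the
NG86 oracle, a 3 × 3 (Ka*, Ks*) grid × 50 replicates of 300-codon pairs
for recovery (mean within 3 standard errors), 100 random genomes for
duplication detection, and the survey-shaped preset run end to end twice
(byte-identical summaries). Hypothesis-based property tests run
derandomised. These sizes were chosen to make every recovery statement
statistically meaningful while keeping the default run quick on one CPU.

## Known limitations

* The motif grammar has no probabilistic scoring; heavily diverged real
  domains that a profile HMM would catch can be missed, and the
  degenerate heptapeptide consensus is a package choice, configurable
  but not learned.
* Subgroup assignment is only as good as the reference set; with the
  packaged synthetic exemplars it is exact on generator output but says
  nothing about real subgroup boundaries.
* The segmental detector is a rank-space simplification of MCScanX and
  does not weight anchors by similarity.
* NG86 with JC correction underestimates rates under strong
  transition/transversion bias or codon-usage skew; no Yang–Nielsen or
  ML model is provided.
* The k-mer distance used for unaligned survey phylogenies is a
  practical stand-in for an aligned distance; bootstrap support is only
  defined for the aligned route.
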