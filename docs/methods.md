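# Methods

## Scope and model

`rbcltrace` implements a metabarcoding workflow for the chloroplast rbcL
barcode in host-dominated samples (bulk milk): read preprocessing,
de-novo chimera removal, greedy centroid clustering, classification
against a local reference database with last-common-ancestor (LCA)
resolution, multi-level OTU tables, and alpha/beta diversity. Every
stage is deterministic given a seed, and a synthetic-data module
generates all inputs with known ground truth so that recovery (not just
unit behaviour) is testable.

## Pairwise alignment and identity

All identity decisions rest on one aligner: affine-gap DP with match
+1, mismatch −2, gap open −2, gap extend −1, and `N` matching nothing
(not even another `N`). Identity = identical aligned positions /
alignment columns, internal gaps counted, terminal overhangs excluded.

Two modes are exposed:

- **overlap** (default): all terminal gaps free on both sequences.
  With every prefix/suffix trimmable at zero cost this objective is
  exactly local (Smith–Waterman) alignment, which is how it is
  computed; this also handles "jagged" ends (both sequences dangling at
  the same end), which a global DP with free end-gap scoring cannot
  represent.
- **fit**: the second sequence must be aligned end-to-end while the
  first may dangle. Used to ask whether a reference could spuriously
  align inside a long decoy sequence.

Terminal `N` runs (masked primer sites) are stripped before aligning;
they carry no information and would otherwise distort the DP path.

Because terminal overhangs are excluded from identity, the identity of
a score-optimal overlap alignment of two *unrelated* sequences is high
(a short perfect overlap). Identity is therefore never used without a
companion coverage condition:

- cluster membership requires the alignment to cover ≥ 80% of the
  shorter sequence's non-N length;
- the host check requires ≥ 60 aligned columns;
- database search relies on the score-based e-value, which short
  spurious overlaps cannot pass.

A shared 12-mer inverted index prescreens candidate pairs in
clustering, chimera-parent lookup and database/decoy search. The screen
only skips pairs sharing no exact 12-mer; at the identities that matter
(≥ 95–97% over ≥ 48 bases) such pairs essentially do not occur, so
results are defined by the DP aligner alone. The clustering screen also
skips candidates whose shared-k-mer span is more than 36 bases short of
the coverage floor — a conservative bound on edge erosion by
mismatches.

## Preprocessing

Primer trimming searches the forward primer and the
reverse-complemented reverse primer (IUPAC codes in primers match their
base sets) with "anywhere" semantics: internal, 5'-overhanging and
3'-overhanging occurrences, minimum overlap 5, mismatch rate ≤ 10%
over matched bases, up to two rounds, best occurrence first (fewest
mismatches per matched base, ties to the leftmost). The default is
masking to `N` (which preserves read length); cut mode removes the
occurrence with its outer flank and discards reads shorter than 35.

Quality control trims 3' bases below phred 20, drops reads < 60 bp,
then drops reads whose expected-error rate exceeds 1% (strictly
greater — a 100-bp read at uniform q20 sits exactly on the boundary and
is kept). "Error rate" is read as the expected-error rate from phred
scores, the standard amplicon reading.

## Chimera removal

Dereplicated sequences are processed in decreasing abundance (ties:
decreasing length, then id). For each query, previously accepted
sequences with ≥ 2× its abundance are candidate parents (the standard
de-novo abundance-skew rule), subject to two eligibility conditions:

- **coverage** — the parent's match profile must span ≥ 90% of the
  query. A genuine amplification parent aligns across the whole
  product (the divergent segment still scores positively under +1/−2),
  whereas unrelated fragments that merely tile parts of a query would
  otherwise assemble spurious two-segment models in fragmented data;
- **abundant core** — the parent must reach ≥ 1/16 of the most
  abundant candidate's abundance. True parents are among the most
  abundant templates; intermediate-abundance lookalikes are
  disproportionately artifacts (duplicated chimeras, shared-error
  variants) whose presence would hide the divergence signal by posing
  as near-perfect single parents.

From per-position match profiles of the query against its closest
eligible parents (up to 8, ranked by matched bases), the best
two-segment model — parent A prefix + parent B suffix, breakpoint
free — is computed in O(L) per ordered pair. The query is flagged
chimeric when the model explains ≥ 97% of its non-N positions and
beats the best single parent by ≥ 0.8 identity points.

The two constants are externally anchored: 97% is the OTU clustering
radius (a chimera should look like a *member* of the pooled cluster
set under the model), and 0.8% is the classic de-novo minimum
divergence default. An earlier formulation requiring the best single
parent to fall below 95% identity was discarded on analysis: with
community divergence d and breakpoint fraction b, the best single
parent sits near 1 − d·min(b, 1−b), which exceeds 95% for almost every
breakpoint at d = 10%, so such a detector flags almost nothing. The
divergence-gap rule detects breakpoints anywhere in the middle ~80% of
the amplicon instead.

## Clustering

Greedy first-match centroid clustering, emulating cluster_fast-style
behaviour: sequences in decreasing abundance (ties: decreasing length,
then lexicographic id); each joins the first centroid, in creation
order, reaching 97% identity with ≥ 80% coverage of the shorter
non-N length, else founds a new centroid. Clustering is pooled across
samples (one centroid set spans the run) with per-sample counts
retained. Conservation holds exactly: flagged chimera reads plus
cluster sizes equal the dereplicated input total.

## Classification

Alignment scores against the reference database become bit scores
through the Karlin–Altschul form bit = (λS − ln K)/ln 2 with λ = 1.33,
K = 0.621 (standard constants for +1/−2 nucleotide scoring), and
e-values E = m·n·2^(−bit) with m the query length and n the total
database length. Search keeps hits with E < 0.01; the hit filter then
applies identity > 95% and E < 1e−5 (both strict), keeps the smallest
e-value per reference, and passes *all* hits tied at the minimal
e-value to the LCA. Tie equality is strict equality of the computed
e-value, i.e. of the alignment score ("same score" and "smallest
e-value" coincide here because m and n are fixed per query). The LCA of
a lineage set is the deepest rank prefix shared by all members;
tied hits of different species in one genus therefore yield a
genus-level assignment, and so on.

Centroids with no accepted hit are aligned against the host decoy;
identity ≥ 0.80 over ≥ 60 columns marks them `host`, otherwise
`unassigned`. The 0.80/60 thresholds are package choices — host reads
in the simulation align at ≥ ~98% identity over their full length, so
the margin is wide.

## OTU tables

At each level (phylum/family/genus/species), assigned clusters
contribute their per-sample counts to the taxon named at that level;
clusters whose LCA is truncated above the level, and host/unassigned
clusters, contribute to the reserved UN row. Filtering moves per-entry
counts < 5 into UN (an entry of exactly 5 is kept; the prose rule
"less than 5 reads" wins over a conflicting table-header reading
"> 5"). Dominance compares count / assigned (non-UN) reads of the
sample against 1% — strictly greater by default, with a `>=` switch
because the source material uses both conventions; UN is never
dominant. Summaries count a taxon as dominant if flagged in ≥ 1
sample. Column totals are conserved through every transformation.

## Diversity

Computed on filtered tables with UN excluded, per level. Shannon
entropy uses natural log; Simpson is reported as the Gini–Simpson
complement 1 − Σp² (the concentration Σp² is also exposed).
Rarefaction is the exact hypergeometric expectation
E[S_n] = Σ_i [1 − C(N−n_i, n)/C(N, n)] evaluated in log-gamma space,
on the grid n = 1, 1+step, … plus N (step 100 by default). Bray–Curtis
is Σ|u−v| / Σ(u+v) over the taxon union. PCoA is classical scaling
(double-centred −½ J D² J, eigendecomposition, top-k non-negative
eigenpairs scaled by √λ) with negative-eigenvalue mass reported and a
deterministic sign convention. Group comparisons use one-way
fixed-effects ANOVA (scipy) on the per-sample index values, groups
taken from the sample sheet; no multiple-testing correction across
index × level combinations.

## Synthetic data

The generator emulates the target regime: host-dominated libraries
with fragmented plant amplicons.

- **Reference database**: one amplicon per species — forward rbcL
  primer site + variable region + reverse-complemented reverse primer
  site (the real primer sequences, so trimming is exercised
  faithfully); default total length 230 bp. Species variable regions
  mutate independently from a common ancestor at divergence/2 per
  site, making any two species ~d apart (default d = 10%, comfortably
  below the 97% clustering radius and above the 95% hit floor).
  Lineages live on a fixed single-phylum tree (all dietary plants in
  the emulated study fall in one phylum): two species per genus, two
  genera per family. If realised pairwise identity between references
  crosses 0.97 the database records a warning.
- **Reads**: per read, host with probability `host_fraction`
  (default 0.8, matching libraries where only a small fraction of
  reads is plant-derived), chimera with probability
  `chimera_fraction` (0.03), else a species drawn from the community
  proportions. Plant and host reads are fragments: length uniform in
  (60, 300), start uniform; a fragment at least as long as the
  amplicon returns the whole amplicon. With a 230-bp amplicon ~30% of
  plant reads are full-length, and the error-free fraction of those
  dereplicates into high-abundance sequences — the abundance signal
  de-novo chimera detection requires. Substitution errors apply
  i.i.d. (default 0.5%); indels are not modelled. Quality strings are
  flat with q = round(−10·log10 p), so the expected-error filter is
  exercised deterministically.
- **Chimeras**: two distinct community amplicons (abundance-weighted)
  joined at a breakpoint uniform in the middle 80%, then errored like
  any read.
- **Host decoys**: random sequences (default 3 × 2000 bp),
  rejection-sampled so no reference fits inside any decoy at ≥ 70%
  identity; host reads are fragments of these.

What the simulation does **not** emulate: PCR amplification bias,
chloroplast copy-number variation, indel sequencing errors, paired-end
structure, reverse-strand reads, length-dependent quality decay, and
real rbcL sequence phylogenetics (synthetic references are star-shaped
around an ancestor). Passing recovery tests therefore demonstrates the
pipeline's logic under controlled noise, not performance on real milk
libraries with database-dependent ambiguity.

## Problem sizes and defaults

The default study is 3 samples × 10,000 reads (6 species at
proportions 0.40/0.25/0.15/0.10/0.06/0.04, 80% host, 3% chimeras,
0.5% error) — small enough to run in minutes on one CPU while leaving
hundreds of reads in the rarest species, and the configuration under
which recovery is graded: species abundances back within 3 percentage
points, ≥ 95% of host-origin centroids routed to host, ≥ 70% of
chimeras removed. Unit and property tests use smaller seeds of the
same generator.

## Numerical and degenerate-input choices

- Tie-breaks are fixed everywhere (leftmost primer occurrence,
  creation-order centroid scan, lexicographic ids) so identical runs
  are byte-identical.
- Rarefaction uses log-gamma, never factorials; terms with
  N − n_i < n are exact 1.
- ANOVA with zero within-group variance raises (degenerate) unless all
  group means coincide, in which case F = 0, p = 1.
- An all-N (fully masked) centroid cannot be searched and raises.
- PCoA with fewer positive eigenvalues than requested axes returns
  fewer axes; sample sign convention: largest-magnitude loading
  positive.
- Seeds: every stochastic stage derives a child seed from the global
  seed via `SeedSequence([seed, stream])`.

## Known limitations

- The chimera detector is a deliberate simplification of the
  full de-novo voting model; it targets clean two-parent joins, not
  multi-parent or micro-chimeras.
- Greedy first-match clustering is order-dependent by design (that is
  the emulated behaviour); a different abundance ordering would give
  slightly different centroid sets.
- E-value constants are fixed for the +1/−2 scoring; changing the
  scoring matrix without updating λ/K would miscalibrate e-values.
- The host check models genome alignment with a decoy FASTA; it does
  not implement spliced or repeat-aware genome mapping.
- Paired-end merging is out of scope; inputs are single-end or
  pre-merged reads.
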