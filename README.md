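# rbcltrace

Trace plant DNA metabarcoding for bulk milk — a tested, reusable
re-implementation of the rbcL amplicon workflow used to verify the
dietary (forage) origin of plant DNA in raw milk from protected-origin
cheese production.

## The problem

Milk from cows carries trace amounts of chloroplast DNA from the plants
the animals ate. Amplifying the chloroplast rbcL barcode from bulk milk
and classifying the reads against a curated local reference database
reveals which plant families, genera and species contributed to the
diet. The catch: milk libraries are dominated by host (bovine) DNA —
often only a few percent of reads are plant-derived — and the plant
template is degraded and fragmented, so the pipeline has to separate a
small, noisy plant signal from a large host background.

## The pipeline

1. **Preprocess** — primer removal with "anywhere" adapter semantics
   (minimum overlap 5, two rounds, 10% mismatch tolerance, mask-to-N),
   3' quality trimming, then filters: length ≥ 60 bp and expected-error
   rate E/len = Σ 10^(−q_i/10) / len ≤ 1%.
2. **Chimera removal** — de-novo two-parent test on dereplicated reads
   (abundance skew ≥ 2×): a read is chimeric when a prefix+suffix model
   built from two more-abundant sequences explains it at ≥ 97% identity
   and beats the best single parent by ≥ 0.8 identity points.
3. **Clustering** — greedy first-match centroid clustering at ≥ 97%
   identity (abundance-sorted, pooled across samples), with per-sample
   member counts.
4. **Classification** — each centroid is aligned against every
   reference (semi-global, +1/−2, gap −2/−1); scores become e-values via
   the Karlin–Altschul bit score (λ = 1.33, K = 0.621). Hits need
   e-value < 0.01 at search, then identity > 95% and e-value < 1e−5;
   all hits tied at the smallest e-value feed a last-common-ancestor
   rule, so ambiguous centroids resolve to genus/family instead of
   species. Unmatched centroids are checked against a host decoy.
5. **OTU tables** — taxa × samples counts at phylum/family/genus/species
   with a reserved UN row; entries with < 5 reads are binned to UN;
   entries above 1% of a sample's assigned reads are flagged dominant.
6. **Diversity** — Shannon (nats) and Gini–Simpson per sample with
   one-way ANOVA across groups, exact hypergeometric rarefaction
   (step 100), Bray–Curtis distances and classical MDS (PCoA).

A fully seeded synthetic-data generator produces every input with known
ground truth: an rbcL-like reference database carrying the real primer
sites, host decoy sequences, fragmented error-bearing amplicon reads,
two-parent chimeras and host contamination at realistic (80%) levels.

## Worked example

```bash
rbcltrace run-all --seed 1 --outdir demo_run
```

simulates 3 samples × 10,000 reads (80% host, 3% chimeras, 0.5%
per-base error; six plant species at proportions 0.40/0.25/0.15/0.10/
0.06/0.04), then runs every stage. `demo_run/run_report.json` ends with
an evaluation block against the simulator's ground truth; a typical run
(seed 1) reports:

```
"chimera_removal_rate":            0.837,
"host_centroid_recall":            1.0,
"species_abundance_max_abs_error": 0.022,
```

meaning ~84% of injected chimeras were removed before clustering, every
host-derived centroid was routed to the host decoy, and every species'
relative abundance (UN excluded) was recovered within 2.2 percentage
points of the simulated truth. `demo_run/tables/otu_species.tsv` holds
the species × sample count matrix; `demo_run/diversity/` holds alpha
indices, ANOVA, Bray–Curtis matrices, PCoA coordinates and rarefaction
curves. The same stages are available individually (`rbcltrace
simulate`, `preprocess`, `cluster`, `classify`, `diversity`) for use on
real demultiplexed FASTQ files plus a reference FASTA/taxonomy TSV.

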