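# Methods

`mgt` is a desk-scale metagenotyping pipeline: it calls intra-species
genetic variation of microbial species directly from shotgun
metagenomic reads aligned to reference genomes. This note describes the
models and procedures each stage implements, the parameters that
matter, the numerical conventions, and what the bundled simulator does
and does not emulate.

## Reference database

A database is built from a genome collection described by a
table-of-contents TSV (`genome_id`, `species_id`, `is_representative`,
`genome_path`, `genes_path`), with exactly one representative genome
per species. Three components are produced per species:

* **Marker genes** — universal single-copy families (the 15-family
  PhyEco panel used throughout the MIDAS lineage). Markers are declared
  by `marker_family=<label>` tags on gene FASTA description lines; an
  external HMM search (e.g. hmmer against the PhyEco profiles) can be
  used to populate the same tags, which keeps the builder free of any
  HMM dependency. Two genes tagged with the same family in one
  representative violate the single-copy assumption and abort the
  build; a species with *no* tagged genes is retained but cannot be
  screened (warned, not fatal).
* **Representative genome** — the SNV coordinate system.
* **Pangenome centroids** — greedy length-sorted centroid clustering of
  all the species' genes: genes are visited longest-first (ties broken
  lexicographically by gene id) and join the first centroid they match
  at ≥ the identity threshold (default 0.95), else found a new cluster.
  Identity is matches / alignment columns under global alignment
  (edlib). This is a single-tier stand-in for the two-tier external
  clustering used at production scale; at desk scale it reproduces the
  same contract (clusters partition the gene set, every member matches
  its centroid at threshold, the centroid is the longest member).

All sort orders are fixed, so rebuilding from identical inputs is
byte-identical (asserted via sha256 in the manifest).

## Species screening and the customized target

Reads are mapped to the marker genes; a read is assigned to at most one
marker — the hit with the most identical bases among placements with ≥
50 aligned bases and ≥ 0.90 identity. Ties within a species resolve
lexicographically by gene id; ties *across* species discard the read
(unique-best screening, trading sensitivity for specificity). Marker
coverage is mapped bases / marker length; species depth is the
**median over the full 15-family panel** with missing families counted
as 0 (robust to marker dropout), and relative abundance normalizes
these medians. Species at or above the selection threshold (default
median coverage ≥ 2×, the MIDAS-family convention) form the
sample-customized SNV target: their representatives concatenated with
contigs renamed `species|contig`.

## Alignment backend

The filter/pileup contract is backend-independent: SAM/BAM from any
aligner is accepted (for real data,
`bowtie2 -x target -1 R1 -2 R2 --no-unal` is the documented route), and
the package ships an internal exact-seed (k = 21) **gapless**
seed-and-extend aligner sufficient for substitution-only reads such as
the simulator's. Candidate placements come from exact 21-mer seeds,
are scored by identical bases over the full read/target overlap, and
the unique best placement wins (ties dropped, or resolved
lexicographically where the caller asks for it). The gapless design is
deliberate: it keeps the aligner trivially auditable, and indels are
out of scope throughout (alignment columns with insertions or deletions
contribute nothing to SNV counts).

## Single-sample SNV step

Post-alignment filters (defaults in the MIDAS lineage, all exposed):
MAPQ ≥ 10, read identity = 1 − NM/aligned columns ≥ 0.90, aligned
fraction ≥ 0.75 of read length, base quality ≥ 30, proper FR pairs only
with template ≤ 1000 bp. Each record reports the *first* failing reason
for auditability.

Mates of one fragment are resolved jointly before counting, so **a
fragment never contributes more than one observation to a site**:
overlap positions where mates agree count once at the higher quality;
disagreements take the higher-quality base; quality ties contribute
nothing. Per-site A/C/G/T counts are kept in full — no single-strain
assumption — and the per-sample call is major = argmax count, minor =
second-largest nonzero count, ties to the lexicographically smallest
base. Sites deeper than 10 000× (repeat pileups) are excluded from
calls. Coordinates are 0-based half-open internally and 1-based in all
TSVs.

## Across-samples population SNVs

Per-sample pileups are scanned site by site in **chunks** (half-open
intervals, default 100 000 sites), the unit of parallel work. A site is
*relevant* in a sample when its depth is ≥ 5 and ≤ 3× the sample's
species-wide mean depth (repeat guard); sites relevant in ≥ 80% of
samples are pooled. Pooling sums relevant samples' count vectors
("counts" method, the default) or lets each sample vote its own major
allele ("prevalence" method — both are defensible definitions of a
population allele and they differ under uneven depth, so both are
implemented and flagged; under "prevalence", a runner-up with zero
votes falls back to the pooled-count runner-up so bi-allelic sites keep
their minor allele). The outputs are per-species site info, minor-
allele frequency and depth matrices.

An allele counts toward the site's allele class (mono/bi/tri/quad) only
with pooled frequency ≥ 1% **and** pooled count ≥ 2. Either floor alone
lets a single stray error read relabel a bi-allelic site tri-allelic:
the count floor matters at low pooled depth, the frequency floor at
high pooled depth.

Chunks are self-contained (no cross-chunk state) and the merge sorts by
(species, contig, position), so the final matrices are **byte-identical
for any chunk size and any worker count** — the testable contract
behind chunk-parallel execution. Production-scale scheduler and
cache-coherence tuning are explicitly not replicated.

## Gene copy number

Reads are mapped to the species' pangenome centroids (unique-best; ties
dropped; cross-mapping between near-identical centroids is a known
limitation of centroid-only alignment). Per-centroid vertical coverage
(mapped bases / length, mate overlaps deduplicated) is divided by the
**same median marker coverage computed by the screening step on the
same sample**, putting numerator and denominator on one depth scale;
presence is called at copy number ≥ 0.35.

CNV mapping uses the SNV filters minus the proper-pair requirement and
with the aligned-fraction floor at 0.50 rather than 0.75. With 100-bp
reads on 300-bp genes this matters: requiring 75 aligned bases discards
most gene-boundary reads and depresses gene depth by ~18%, while
markers screened at a 50-base minimum lose only ~8%, which would bias
single-copy genes to ~0.89. The matched 50-base minimum on both sides
calibrates single-copy genes to ≈ 1.0 (measured: 0.99 at 200×).

Accuracy note: a single 300-bp gene at 20× carries fragment-sampling
noise of ~0.2 copies (Poisson fragment counts over a ~600-bp span), so
copy-number accuracy is assessed as the mean estimate over 6 replicate
20× aliquots — which tests estimator accuracy rather than shot noise —
and any single-sample estimate should be read with that uncertainty in
mind.

## Strain mixtures

Per species and sample, the statistic is the fraction of *eligible*
sites whose within-sample minor-allele frequency falls in an
intermediate band, default [0.10, 0.50]. Eligible sites have depth ≥ 10
and include monomorphic sites (frequency 0) in the denominator; in-band
sites additionally need ≥ 2 minor reads, because a single error read at
depth exactly 10 lands precisely on the 0.10 band edge and would put
~1% of minimum-depth sites in band at error rate 10⁻³. A sample is
called a mixture when the fraction reaches the cutoff, given ≥ 100
eligible sites.

Cutoff calibration: with a whole-genome denominator the expected
fraction for a two-strain mixture is ≈ (between-strain divergence) ×
(band-capture probability ≈ 0.93–0.98 at 20–30×), while a single
dominant strain sits at the error-driven noise floor of ~10⁻⁴
(ε = 10⁻³, Q30 filtering, 20×). The default cutoff of **0.002** sits an
order of magnitude above the noise floor and detects mixtures down to
~0.2% between-strain divergence; mixtures at 0.5% divergence (expected
fraction ≈ 0.005) are detected with a ≈ 3 SD margin. Every constant is
CLI-exposed. This statistic is this package's own operationalization of
the single-strain-vs-mixture dichotomy; it is an allele-frequency-band
heuristic, not a likelihood model, and it estimates neither the number
of strains nor their proportions.

## Simulator

The generator emulates exactly what the pipeline needs to be testable
with no downloads: i.i.d.-base genomes at a stated GC with evenly
spaced 300-bp genes (first 15 marker-tagged); strains derived by
independent per-site substitution at a stated divergence with an exact
truth list; tandem duplications/deletions with coordinate remapping;
multi-species, multi-strain communities; and paired-end reads with
uniform fragment starts (normal fragment length, default 300 ± 30),
constant per-base error rate and the matching constant Phred quality.
Read ids encode strain, coordinates and index, so every read is
traceable and a validator re-extracts error-free reads exactly.

Deliberately **not** modeled: indels, quality decay along the read, GC
bias, contamination, real inter-species sequence homology. Passing
tests therefore demonstrate the correctness of the pipeline's
contracts (filters, dedup, pooling, invariances, calibration) under a
clean substitution-only error model — not performance on real
instrument data, where divergent references, repeats and indels
dominate the error budget.

## Problem sizes in the test and acceptance runs

Scenarios use 6–10-kb genomes, 16–20 genes, 10–40 samples at 5–20×
(~1000 read pairs per 10-kb sample at 20×). These sizes keep the whole
validation suite in the tens of seconds while leaving every statistical
check with ≥ 3 SD margins under the stated error model; every
expectation scales analytically (binomial/Poisson), so nothing about
the contracts depends on scale.

## Known limitations

* Gapless internal aligner: any indel-containing read must come through
  the SAM route; the internal route is for simulated/teaching data.
* Centroid-only CNV mapping under-resolves near-identical paralogs.
* The strain-mixture statistic saturates (fraction ≈ divergence) and
  cannot separate 2-strain from k-strain mixtures.
* Species screening assumes the marker panel is present in the
  database genes; unannotated representatives are unscreenable.
* The merge loads per-sample pileups into dense per-contig arrays —
  fine for tens of Mb × tens of samples, not for production cohorts.
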