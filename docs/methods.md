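# Methods

This note documents the models and procedures implemented in `longmeta`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Two-step taxon validation

**Model.** k-mer classification (LCA-resolved, Kraken2-style) assigns each
read a taxid. For a node *n*, the validation step collects all sampled
reads assigned to *n* or its descendants and checks them against the
concatenation of the reference genomes under *n*. A read passes when the
union of its query intervals from alignments with identity ≥
`min_identity` covers ≥ `min_read_coverage` of the read; the taxon passes
when ≥ `min_taxon_rate` of its reads pass.

**Parameters** (`ValidationConfig`): `min_read_coverage` = 0.70,
`min_identity` = 0.70, `min_taxon_rate` = 0.20, `subsample_size` = 100,000
reads, `seed`. The 70/70/20 defaults are deliberately permissive toward
genuine strain-level divergence from database genomes while still
collapsing to ~0 for reads that do not belong to the claimed taxon at all.

**Numerical choices.**

- Identity is matches / alignment-block-length (PAF columns 10/11); SAM
  input converts via CIGAR + NM. This is the common minimap2 convention;
  no other definition is supported.
- Overlapping alignments on the read are merged (interval union) before
  the coverage test, so no base counts twice; all alignments of a read
  (primary, secondary, supplementary) contribute, since the per-node
  reference is a concatenation. The alternative — summing block lengths —
  would overcount and was rejected.
- Genus-level validation is independent: reads of all species under the
  genus are pooled against the pooled reference set, rather than
  inheriting species verdicts.
- A taxon with zero sampled reads is reported `validated = False` with a
  flag (conservative) rather than undefined; a taxon whose reads have no
  alignment data at all is flagged `no-alignment-data`, never silently
  validated.
- Subsampling is a seeded uniform draw without replacement; the seed is
  recorded in pipeline output headers.

## Composition tables

Species with < 5 assigned reads pool into "not enough reads"; species at
≥ 5 reads that failed validation pool into "not validated"; reads
classified above species rank are reported as "unresolved rank". Rows sum
to 1 exactly. The default denominator is classified non-human, non-plant
reads; domain-restricted renormalization is available by passing a
different `exclude_domains` set. The study data leave the exact
denominator for mixed-domain statements ambiguous, so both modes exist and
the choice is explicit in calling code.

Domain labelling walks the node's ancestry with a fixed precedence: human
before other Metazoa, fungi and Viridiplantae before the generic
"non-fungal eukaryote" fallback. Clade root taxids are configurable
(`DomainConfig`); defaults are the standard NCBI ids.

Marker tracks use exact Clopper–Pearson binomial intervals (beta
quantiles), the conservative choice among binomial CI methods.

## Community structure

- Bray–Curtis runs on validated-species vectors renormalized to sum 1
  (the post-filter compositional estimate).
- PCoA is classical scaling: double-center −½D², eigendecompose, scale
  eigenvectors by √λ. Axes with negative eigenvalues (Bray–Curtis is
  non-Euclidean) are dropped and their count reported. The implementation
  is plain numpy and is cross-checked against scikit-bio's PCoA in the
  test suite.
- The k-means scan (scikit-learn, `restarts` seeded initializations per k,
  best by inertia) scores each k ∈ [2, 6] by mean silhouette in the
  retained-axis Euclidean space; ties break toward smaller k. By default
  all positive axes enter the clustering (`n_axes` restricts this); which
  subset the original analysis used is not recoverable, so the
  all-positive-axes default was chosen and exposed.
- "Cluster space" membership of follow-up samples is operationalized as
  containment in the 2-D convex hull of the cluster's baseline samples in
  the first two PCoA axes; clusters with < 3 (or collinear) baseline
  points degrade to a distance-to-segment test at 1e-9 tolerance.
- Richness downsampling excludes Chordata and Viridiplantae reads
  *before* computing the common depth (the minimum retained read count
  over samples), then draws without replacement, seeded, and counts only
  validated taxa.

## Targeted quantification

ARG rule: block length ≥ 500 bp and < 50 'N' bases in the aligned query
segment (the N-count is carried in a `nc:i:` PAF tag; absent means 0). A
read counts once per distinct ARG in the per-ARG tallies but once in total
for the per-10,000-read burden. crAssphage: query cover is evaluated per
primary alignment (a single alignment must reach 70/70 — deliberately
different from the validation step's union semantics, since here one
contiguous phage-genome alignment is the evidence), and strain assignment
additionally requires MQ ≥ 5.

## aANI-lowFreq

For samples *a*, *b* with allele counts on a species' core-genome contigs
(depth = A+C+G+T; deletions and Ns never counted):

- *shared mask*: a contig qualifies iff ≥ 80% of its positions reach
  ≥ 10× in *a* and, independently, in *b*; a position is shared iff its
  contig qualifies and the position reaches ≥ 10× in both.
- *a-exclusive SNV*: some base has frequency ≥ 0.5 in *a* with ≥ 10
  supporting reads and frequency < 0.10 in *b*. The strict `< 0.10`
  reading is intentional: an allele observed at ≥ 10% in *b* is treated as
  present there and hence not exclusive. Positions where two bases tie at
  exactly 50% in *a* are ambiguous-majority and skipped.
- distance = exclusive SNVs / shared length; asymmetric by construction.
  Zero shared length yields an ineligible result, not an error.

Replacement calls: pairs need ≥ 50% shared core fraction; species need
≥ 10 between-patient calibration distances. The original assessment of
"falls within the between-patient distribution" was visual; here it is
operationalized as ≥ the empirical 5th-percentile order statistic
(`replacement_quantile`, configurable), preserving the false-positive-averse
stance. Within-patient intervals are consecutive same-patient samples by
collection day; when both directed distances exist the maximum is used;
`spans_event` is true iff an alloHSCT or relapse date lies in (t₁, t₂].

## Synthetic generator

The generator emulates: (i) classified long-read samples — log-normal read
lengths (median 653 bp, a realistic Nanopore gut-metagenome median),
uniform substitution errors at 5%, assignments corrupted at a configurable
misassignment rate, PAF alignments that always reflect the read's *true*
source genome; (ii) genome pairs at target ANI via independent Poisson
substitutions; (iii) short-read pileups — Poisson(coverage) depth per
position with uniform substitution errors at 0.1%, standing in for 2×100 bp
paired-end data (the pileup, not the reads, is the strain module's
contract); (iv) mock communities with decoy species — database taxa with
zero true abundance that act as landing spots for misassigned reads, the
way a k-mer classifier confuses out-of-database reads with close relatives.

It does **not** model indels, quality scores, chimeras, coverage biases,
or genuinely homologous inter-species sequence; alignments are emitted
analytically rather than by running a mapper. A green test therefore
establishes that the *rules* behave as specified on reads whose true
origin is known — not that any particular real-data validation rate will
be reproduced.

In the leave-one-out benchmark the dropped species' reads are relabeled
onto decoys (default) or uniformly onto remaining database species; their
alignment support vanishes with the dropped genome, so the benchmark
measures exactly the failure mode the filter targets. Filter metrics:
*filter precision* = fraction of rejected taxa that were truly false
positives; *FP-taxon recall* = fraction of planted false-positive taxa
rejected.

## Known limitations

- The aANI-lowFreq pileup path assumes reads were competitively mapped to
  the correct species' core genome; cross-mapping between related species
  is not simulated.
- Genus-level validation pools references by clade membership of the
  target sequence ids; it does not model inter-genus homology.
- The convex-hull cluster-space definition is a 2-D operationalization of
  a visual concept; samples marginally outside a hull are "outside"
  regardless of density.
- Statistical primitives delegate to scipy; the exact Mann–Whitney path
  is used only for tie-free groups of ≤ 8 each, matching the documented
  contract.
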