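# Methods

## Overview

`metastruct` converts 16S rRNA gene phylogenetic placements into metabolic
structure: per-edge inferred genomes, complete-pathway predictions, and
community-level pathway abundance statistics, each inference carrying a
quality score. This note documents the models, the parameter choices that
matter, the synthetic benchmark, and the numerical conventions.

## Reference packages and edge numbering

A reference package couples annotated genomes (one 16S gene each — when a
genome carries several copies the first record is used, since intra-genome
copy variation is minor relative to between-genome divergence), an aligned
16S set, and an unrooted tree over the genome ids. Placements attach to
*edges*. External placers serialize their own edge numbers, and those
numbers are not reproducible across tools, so the package numbers edges
itself: depth-first preorder over the newick as written, root-adjacent edge
first. Re-reading the same file always yields identical numbers; jplace
edge numbers are remapped by matching descendant leaf sets (a jplace edge
whose leaf set is the complement of a package clade — the root-adjacent
edge seen from the far side of the unrooted tree — maps to that clade's
edge), never by index.

Gene annotations travel as a 4-column TSV (gene id, product, semicolon-
joined EC numbers, amino-acid sequence) rather than full GenBank flat
files; this keeps a heavyweight parser out of the critical path while
carrying exactly the fields the pipeline consumes. Alignment trimming
removes columns before the latest first-non-gap position and after the
earliest last-non-gap position across sequences; `-` and `.` both count as
gaps (the Mothur/Silva dialect). Sequences shorter than the minimum
ungapped 16S length (default 1,200 nt) are discarded before trimming, in
one pass.

## Genomic plasticity (φ)

Proteome compositional vectors are frequencies of overlapping 5-amino-acid
k-mers over a genome's full CDS set; k-mers containing non-standard letters
are dropped. Raw frequency vectors feed Bray-Curtis distance directly; a
Markov-background subtraction step used by some compositional-distance
formulations is intentionally not applied by default, since the pipeline's
contract is Bray-Curtis on the frequency vectors themselves.

For large k-mer universes a reduction step ranks k-mers by PCA: components
of the centred frequency matrix (no unit-variance scaling by default —
scaling would equalise rare-k-mer noise; a flag enables it) are retained
until cumulative explained variance reaches the target (default 0.9), each
k-mer scored by Σ |loading| × component-variance-fraction, and the top
`n_keep` retained. Partial vectors are not renormalised. On the package's
synthetic sets the Pearson correlation between full-vector and
reduced-vector distance matrices exceeds 0.9 whenever the retained
components carry ≥ 50 % of the variance; desk-scale runs can skip the
reduction entirely (`n_keep=None`).

16S distances are p-distances over columns where both sequences are
non-gap. Both matrices are z-scored over the upper triangle (diagonal and
duplicate lower-triangle entries are excluded from all statistics —
self-comparisons carry no information and would bias the transform) and
then min-max scaled to [0, 1]. The relation d16 = a·exp(b·dcv) is fitted by
nonlinear least squares on upper-triangle pairs, initialised at a₀ = the
smallest positive observed d16 and b₀ = log(max d16 / a₀), with up to 10
seeded, jittered restarts (exponential fits are initialisation-sensitive).
r² is reported as 1 − SS_res/SS_tot.

φ is the min-max-scaled off-diagonal row mean of the residual matrix
(predicted − observed); with a symmetric matrix row and column means
coincide. Positive residuals mark genomes whose 16S diverged less than
their proteome composition predicts — the signature of gene gain, loss, or
duplication decoupled from the marker gene. Degenerate cases are fatal by
design: a single genome, identical row means (e.g. any 2-genome matrix),
or a zero-variance distance matrix.

Note on fit accuracy: when the fitted curve spans many decades (steep b),
the prefactor a is an extrapolation to dcv = 0 and is poorly constrained
by absolute-scale least squares under multiplicative noise; noise-free
data recover both coefficients to better than 1 %, but noisy-recovery
expectations should be calibrated on the dynamic range at hand.

## Core genomes and quality (q)

Terminal edges carry the leaf genome verbatim. For an internal edge, one
clade member is chosen as the database genome — the member with the most
genes, ties broken lexicographically, which maximises the candidate set and
is deterministic — and its CDS set is trimmed to the genes hit by every
other clade member under the similarity-search contract. Two engines
implement the contract: exact gene-family-label matching (the default for
synthetic data, and the test oracle — with it the construction provably
equals brute-force gene-set intersection), and a blastp adapter (any hit at
e-value ≤ 1, per-subject). The adapter searches amino-acid sequences
because that is what the gene-table contract stores. At the permissive
cutoff of 1, chance hits between short unrelated sequences can only widen
the retained set; the package's tests pin exact agreement at a stringent
cutoff. Pairwise hit sets are memoised per run, since clades nest and the
same (query, database) pair recurs along the tree.

Quality is q = (S_core/S_clade)·(1 − φ), clipped to [0, 1], with the size
ratio fixed at 1 on terminal edges (genome-size comparison gives no
stability signal for a single genome). φ is per-genome, so an internal
edge uses the mean φ over its clade members (a flag selects the maximum
for a conservative reading). A sample's quality is the abundance-weighted
mean q over its placed reads — reads are the sampling unit of the
community; an unweighted per-edge mean is available by flag.

## Placements, filters, rarefaction

jplace records with several placements keep the one with the highest
like-weight ratio, ties broken by the lowest jplace edge number. Read
filters mirror standard amplicon practice: minimum length (default 100 nt),
an optional alignment-region containment filter (coordinates are
alignment-specific, so the filter is generic and off by default), and
removal of reads not classified below the domain level — the rule that in
practice removes chloroplast-like sequences that classify only to
"Bacteria". Rarefaction subsamples every library to a common depth without
replacement; each sample's generator is seeded from (master seed, CRC32 of
the sample name) so adding a sample never reshuffles the others.
Rarefaction runs after filtering and before matrix construction.

## Pathway prediction

A pathway definition is an ordered list of reaction slots, each a set of
acceptable identifiers. A pathway is called present when the fraction of
covered slots reaches `completeness` (default 1.0 — a metabolism is not
predicted unless the complete pathway is accounted for; the parameter is
exposed because completeness-based calling is known to over-predict at the
EC level, e.g. two enzymes that serve unrelated bacterial processes can
jointly satisfy a eukaryote-style shuttle definition — the test suite
reproduces this as documented behaviour). Matching is EC-first with
normalised product-name fallback (lowercase, punctuation stripped); partial
EC codes match any completion, on either side.

The pathway abundance matrix distributes each edge's read count to every
pathway predicted for that edge, recording per-cell edge provenance. The
redundancy profile reports, per sample and pathway, the number of distinct
contributing edges — abundant single-edge pathways flag ecosystem functions
with no functional backup. The pooled (non-partitioned) metagenome mode
predicts on the union of all partition inventories; it is provably a
superset of the per-partition union, and the difference is exactly the set
of pathways completable only across partitions — the chimeric-pathway
hazard of unpartitioned metagenome analysis.

## Community statistics

Per-figure conventions are kept separate: pathway matrices are normalised
per-feature-maximum, edge matrices per-sample-total, and both modes are
available for either matrix. Clustering is Ward linkage on Bray-Curtis
distances with scipy's deterministic leaf ordering. PCA loading ranks use
the biplot convention — loadings scaled by the square root of each
component's explained variance before taking the two-component norm
(unweighted norm by flag). Chao1 uses S_obs + F1²/(2F2), switching to the
bias-corrected S_obs + F1(F1−1)/(2(F2+1)) when no doubletons are observed.
Mann-Whitney uses the exact null when the smaller group has ≤ 8
observations and the data are tie-free, the tie-corrected normal
approximation otherwise (threshold configurable); fully tied data return
p = 1 with a warning. The group anomaly statistic is
(mean_A − mean_B)/(mean_A + mean_B) per feature on the normalised matrix,
reported with raw Mann-Whitney p-values; a Benjamini–Hochberg column is
attached as a clearly separated convenience, not used by anything
downstream. Agreement between two community views is ordinary least
squares of one condensed distance vector on the other (a Mantel
permutation p-value would be the inferential upgrade; the regression is
the descriptive contract here).

## Synthetic benchmark

The generator evolves genomes down a tree (balanced, caterpillar, or
random topology): 16S by per-site substitution — no indels, so sequences
remain aligned; indel realism is out of scope — and gene content by churn,
replacing a binomial fraction of genes per branch with novel genes from a
global pool 5× the genome size (so churn introduces genuinely new
content). Defaults are desk-scale stand-ins chosen once: 120 genes of 60
aa per genome, 16S of 1,500 nt (the length of a real 16S gene) at 0.05
substitutions/site/branch, giving pairwise 16S distances up to ~0.3–0.4;
background churn 0.02 per branch with a plastic subset at 10× that rate on
its terminal branch; communities of 300 reads per sample drawn
multinomially from group-specific Dirichlet edge profiles (weight
1 + group_effect on each group's favoured half of the edges).

The plasticity benchmark uses a balanced topology: uniform leaf depths
remove path-length variance from the residual row means, isolating the
churn signal the index is meant to detect. With a two-level truth (10 of
30 genomes plastic) the maximum attainable Spearman correlation is 0.817;
the pipeline reaches 0.72–0.82 across seeds. What passing does and does
not show: the generator's gene churn is memoryless and uniform across the
gene pool, its 16S clock is strict, and its communities have no sequencing
error, chimeras, or copy-number variation — recovery here demonstrates the
machinery is correct and the signal identifiable under controlled
conditions, not that φ separates plastic clades at any particular strength
in real genome collections.

## Numerical conventions and degenerate inputs

Fatal by design: empty alignment overlap, all-gap sequences, zero-variance
distance matrices, identical residual row means, Bray-Curtis between two
all-zero vectors, rarefaction deeper than a library, placements on edges
without pathway predictions or quality scores, overlapping comparison
groups. Warned but tolerated: empty proteomes, degenerate PCA (identical
vectors fall back to lexicographic k-mer order), fully tied test data,
`n_keep` exceeding the k-mer universe. Ties everywhere break
deterministically (lexicographic ids, lowest edge number). All randomness
flows through explicit seeds; simulation outputs are byte-identical across
runs with the same configuration.

## Known limitations

Phenotypic plasticity is out of scope — φ sees gene content, not
regulation. Draft or incomplete genomes would inflate φ and shrink core
genomes artificially and are deliberately unsupported. The similarity
search is presence/absence with no paralog-aware orthology. Pathway
calling is only as good as the ontology and annotations supplied;
EC-completeness calling over-predicts where enzyme pairs are shared across
unrelated processes. The bundled placer is a naive identity ranker meant
for testing and demos, not a replacement for likelihood-based placement.
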