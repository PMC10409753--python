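# Methods

## Genotype model

Each site×cell element carries `r` reference and `a` alternate reads. The
variant allele frequency is modelled as Beta(a+1, r+1), the posterior under a
uniform prior with alternate reads as Bernoulli successes. A noise threshold
θ ∈ (0, 0.5) partitions the allele-frequency axis into three regions whose
masses are the genotype probabilities: [0, θ] → homozygous reference,
[1−θ, 1] → homozygous alternate, the middle → heterozygous. θ defaults to
0.3 and is a global constant: it reflects how much allelic noise (sequencing
error, allele-specific expression) is tolerated before a homozygous
interpretation is abandoned, and the package makes no attempt to estimate it
per site or per dataset.

Probabilities are evaluated with the regularized incomplete beta function
(numerically stable for all integer read counts; the test suite checks the
full 0–30 read grid against numeric quadrature at 1e-9). Zero-read elements
receive the prior masses (θ, 1−2θ, θ) so that similarity sampling and
smoothing remain defined under dropout; the MISSING state exists only in the
unsmoothed presentation of the calls.

Calls are the per-element argmax. Exact probability ties are broken with the
fixed precedence H > R > A: a tie means the reads cannot separate the
homozygous states, so the heterozygous interpretation is the conservative
one. A consequence of the interval construction worth knowing: a single-read
element can never be called heterozygous at θ = 0.3, because one read leaves
the heterozygous mass at 0.40 against 0.51 for the matching homozygous state.

## Similarity and smoothing

Cell–cell similarity is the expected fraction of sites at which two cells
draw the same genotype, estimated by sampling whole genotype profiles
(default 100 samplings). One profile per cell per sampling iteration is
drawn and shared across all pairs ("matched draws"); this has the same
expectation as drawing independently per pair, keeps the matrix symmetric by
construction, and reduces the cost from O(T·n²·m) independent draws to
one-hot matrix products. The agreement fraction is a simple matching
coefficient over all sites — dropout elements participate through their
prior, since agreement is defined over all sites rather than covered ones.

Each cell's K = 10 highest-scoring other cells (ties broken by ascending
cell index; the neighbour relation is directed and not symmetrized) define
the smoothing equation above. With δ = K/(K+1) the cell's own distribution
receives weight exactly 1/(K+1), making smoothing a plain average of the
cell with its neighbours — an algebraic identity the tests assert. K should
stay below the size of the smallest clade of interest.

## Filtering

The cascade runs in a fixed order: pseudobulk candidate support (total ≥ 20
reads, ≥ 5 alternate reads, VAF ≥ 5%), per-cell depth (≥ 10,000 total
reads), then per-site coarse filters — total reads across cells ≥ 10
("low overall coverage" is interpreted as the per-site total, consistent
with the lenient preset's "less than five reads" variant), monomorphic
fraction (a site is dropped when more than 90% of covered cells share one
called base; dropout cells are excluded from numerator and denominator,
since smoothing happens after this filter), chromosome (autosomes 1–22,
accepting both "chr1" and "1" dialects), and proximity (every member of any
cluster of sites within 5 nt on the same chromosome is removed; the boundary
is |Δpos| ≤ 5 and is configurable, as "within five nucleotides" is ambiguous
at the boundary). After smoothing, the 1000 sites with the most reads are
kept, ties at the cap broken by ascending (chrom, pos).

Preset bundles: `default`; `lenient` (per-site total ≥ 5, monomorphic 0.80)
for sparse data; `subclone` (monomorphic 0.95) so that sites private to
small clades survive.

## Sequence export and the fallback tree

Calls are encoded per cell as one base per selected site: R → reference
base, A → alternate base, H → the first base in A<C<G<T order that is
neither (made deterministic so re-runs are byte-identical; any base other
than ref/alt serves, since the encoding only needs three distinct states per
column), MISSING → N. FASTA and NEXUS outputs are intended for an external
Bayesian engine (a relaxed log-normal clock, GTR site model and Yule prior
are the recorded defaults in the JSON sidecar; chain length ≥ 1e8).

The built-in neighbor-joining tree (on mismatch fractions over jointly
non-N columns, negative NJ branch lengths clamped to zero, midpoint-rooted)
exists so that the pipeline and the tree statistics can run end-to-end at
desk scale. It is not a substitute for Bayesian inference on real data, and
λ values measured on NJ fallback trees are comparable across conditions of
one experiment but not in magnitude to values from MCMC-inferred trees.

## Tree statistics

Pagel's λ scales the off-diagonal entries of the Brownian-motion covariance
C (C_ij = root-to-MRCA path length). The mean and rate are profiled out
analytically; λ is maximized on [0, λ_max] with λ_max = max(diag C) /
max(offdiag C) — the largest value keeping the transformed matrix a valid
tree covariance — which deliberately allows estimates above 1. Significance
is a likelihood-ratio test against λ = 0 on χ²(1). Binary lineage labels
are coded 0/1 and treated as continuous; this mirrors common practice but
is a documented approximation, not a binary-trait likelihood. Blomberg's K
uses the standard MSE0/MSE ratio with the phylogenetically corrected mean,
normalized by its Brownian expectation.

SES MPD measures whether a group of tips is more (z < 0) or less (z > 0)
phylogenetically clustered than chance: the observed mean pairwise
cophenetic distance is compared to a null built by shuffling tip labels
with group sizes held fixed (999 permutations by default; the p-value is the
lower-tail permutation rank). The adjusted Rand index and Benjamini–Hochberg
FDR are thin, validated wrappers over the standard implementations.

## Synthetic data generator

The generator emulates droplet scRNA-seq genotyping of a recently diverged
tumor, defaulting to 400 cells in two equal lineages over 500 variant
sites:

- **Coverage.** Per-element read depth is negative-binomial (dispersion
  0.5) with log-normal site means (σ = 1, expression-driven) multiplied by
  log-normal cell depth factors (σ = 0.5, library-size variation), rescaled
  so the realized zero fraction hits the target sparsity (default 0.65).
  The resulting element-depth composition — about 65% dropout, 16% one
  read, 13% at 2–4 reads, 6% at ≥ 5 — matches the regime this kind of data
  shows in practice.
- **Lineage structure.** 10% of sites are lineage-informative. Because a
  homozygous-to-homozygous switch requires two independent hits, every
  informative difference involves the heterozygous state (H vs R or H vs
  A). Informative variants are subclonal within their lineage: each is
  carried by a Uniform(0.8, 1) fraction of the lineage's cells, the rest
  retaining the other state. Non-informative sites share one background
  genotype (55% R, 25% H, 20% A) across all cells.
- **Reads.** Homozygous elements draw alternate reads at the error rate ε
  (default 0.05) or 1−ε. Heterozygous elements suffer allelic bursting:
  with few mRNA molecules captured per element, the observed allele
  fraction is Beta(1, 1) around 0.5, so low-depth heterozygous elements are
  frequently monoallelic. This is the dominant reason unsmoothed genotype
  calls carry almost no lineage signal, and hence the failure mode the
  smoothing stage exists to fix.
- **Truth.** The true tree is a balanced clade tree with unit internal and
  0.1 terminal branches — sufficient for signal statistics, and a
  documented simplification (no within-clade branching structure).

What the generator does **not** emulate: correlated dropout between nearby
sites on one transcript, doublets, ambient RNA, allele-specific expression
that is consistent per cell rather than per element, copy-number variation,
and real within-clade phylogenetic structure. Passing tests on this
generator therefore show that the pipeline recovers clade structure under
realistic depth/dropout/bursting noise, not that it is robust to every
artifact of real droplet data.

## Robustness experiments

The sweep harness perturbs the synthetic data (extra sparsity, random
genotype flips, minority-subclone spike-ins, neighbour/site counts), runs
smoothing, builds the NJ fallback tree and reports Pagel's λ of lineage
membership with its LRT p-value plus the ARI of the tree's root bipartition
against truth. Sweeps run at the default 400-cell scale because λ estimates
on the NJ surrogate are unstable on smaller trees (a near-random tree has a
nearly flat λ likelihood). Subclone detection is read from λ: at desk scale
the NJ tree essentially never contains one clean edge separating a minority
subclone (scanning all edges for the best bipartition tops out near ARI 0.2
even when λ > 1), so a single-bipartition ARI would be uninformative, while
λ cleanly orders subclone sizes.

## Numerical choices and degenerate inputs

- Incomplete-beta evaluation throughout; quadrature appears only in test
  oracles.
- Smoothing requires ≥ 2 cells; K is truncated to n−1 when fewer cells
  remain.
- A tiny ridge (1e-10 of the mean depth) stabilizes Cholesky factorization
  of tree covariances with very short cherries; the λ optimizer treats
  non-positive-definite transforms as likelihood floor.
- SES MPD returns z = 0 when the permutation null is degenerate (e.g. the
  group is the whole tree).
- Constant traits, singleton groups, empty filter outputs, unlabeled tips
  and negative branch lengths raise validation errors rather than returning
  silently wrong numbers.
- All randomness flows through explicit integer seeds; fixed seeds give
  bit-identical outputs.

## Known limitations

θ is global and not estimated; the agreement score is a simple matching
coefficient (its common "Jaccard" name notwithstanding); binary traits are
scored with a continuous-trait λ; the NJ fallback is a development aid, not
an inference method; and the generator's realized λ magnitudes are specific
to the synthetic conditions — only directions and orderings transfer.
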