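# phylosmooth

Phylogenetic inference preparation from single-cell RNA-seq allele counts:
probabilistic genotype calling under a beta-binomial model, kNN smoothing of
genotype probabilities across genetically similar cells, site/cell quality
filtering, sequence export for Bayesian tree inference, and the tree
statistics used to evaluate the resulting phylogenies.

## Who this is for

Tumors contain subclones — lineages of cells with distinct genotypes and
phenotypes. scRNA-seq can in principle reveal both at once, but genotyping
single cells from RNA reads is dominated by dropout (most site×cell elements
have zero reads) and by one-read elements that cannot distinguish a
heterozygous genotype from a homozygous one. This package implements the
smoothing strategy that makes such data usable for phylogenetics: genotypes
are called probabilistically, each cell borrows strength from its K most
genetically similar neighbours, and the smoothed calls are exported as
sequences for tree inference.

## The model

For a site×cell element with `r` reference and `a` alternate reads, the
variant allele frequency `p` follows Beta(a+1, r+1). With a noise threshold
θ (default 0.3), the three genotype probabilities are the density's mass on
three intervals, via the regularized incomplete beta function `I_x`:

    P(R) = I_θ(a+1, r+1)        P(A) = 1 − I_{1−θ}(a+1, r+1)
    P(H) = 1 − P(R) − P(A)

Cell–cell similarity is the fraction of sites at which two cells draw the
same genotype, averaged over 100 sampled genotype profiles. Each cell's K
(default 10) highest-scoring neighbours define the smoothing

    p̂_ijg = (1−δ) p_ijg + δ · (Σ_k p_kjg) / K,   δ = K/(K+1) by default,

which with the default δ is exactly the plain average of the cell with its
K neighbours. Calls are the per-element argmax. Sites are filtered
(pseudobulk support, per-cell depth, coverage, monomorphic fraction,
chromosome, proximity) and the top 1000 sites by reads are encoded as
sequences (R → ref base, A → alt base, H → a deterministic surrogate base,
dropout → N) for external Bayesian inference; a neighbor-joining fallback
tree supports desk-scale evaluation. Trees are scored with Pagel's λ,
Blomberg's K, SES MPD and the adjusted Rand index.

## Worked example

```python
import phylosmooth as ps

# simulate a two-lineage experiment: 400 cells, 500 variant sites, 65% dropout
counts, truth = ps.simulate_dataset(ps.SimConfig(seed=1))
print(f"sparsity: {counts.sparsity():.3f}")

before = ps.call_unsmoothed(counts)
probs, after, neighbors = ps.smooth_genotypes(
    counts, params=ps.SmoothingParams(seed=1))

from phylosmooth.synthetic_sim import genotype_clustering_ari
print(f"ARI vs true lineages, unsmoothed: "
      f"{genotype_clustering_ari(before, truth.clade_labels, seed=1):.2f}")
print(f"ARI vs true lineages, smoothed:   "
      f"{genotype_clustering_ari(after, truth.clade_labels, seed=1):.2f}")

alignment = ps.encode_alignment(after, counts.sites, counts.cells)
tree = ps.nj_tree(ps.hamming_distance_matrix(alignment), counts.cells)
signal = ps.pagels_lambda(tree, dict(zip(counts.cells, truth.clade_labels)))
print(f"Pagel's lambda: {signal.lambda_hat:.2f} (LRT p = {signal.p_value:.2e})")
```

prints

```
sparsity: 0.650
ARI vs true lineages, unsmoothed: -0.00
ARI vs true lineages, smoothed:   0.23
Pagel's lambda: 0.68 (LRT p = 1.17e-21)
```

Unsmoothed genotype calls carry essentially no lineage information at 65%
dropout (ARI ≈ 0); after smoothing, clustering the calls recovers the two
lineages (ARI 0.23), and the fallback tree shows strong phylogenetic signal
for lineage membership (λ = 0.68, significant against λ = 0).

The same pipeline is available from the shell:

```sh
phylosmooth simulate --seed 1 --out-counts counts.tsv --out-labels labels.tsv
phylosmooth export --counts counts.tsv --seed 1 --out-fasta cells.fasta
phylosmooth tree-fallback --fasta cells.fasta --out tree.nwk
phylosmooth signal --tree tree.nwk --traits labels.tsv
```

## Layout

- `io_formats` — VCF sites, long/sparse-triplet count matrices, Newick
  trees, trait tables; strict validation.
- `genotype_model` — beta-binomial genotype probabilities, argmax calls,
  coverage-stratified change tables.
- `smoothing` — sampled-profile similarity, kNN, probability smoothing.
- `site_filter` — the filter cascade and top-N selection with
  default / lenient / subclone presets.
- `phylo_export` — sequence encoding, FASTA/NEXUS, Hamming distances, the
  NJ fallback tree.
- `phylo_stats` — Pagel's λ, Blomberg's K, SES MPD, ARI, BH-FDR.
- `synthetic_sim` — the clade-structured data generator and robustness
  sweeps.
- `cli` — composable subcommands over the above.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
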