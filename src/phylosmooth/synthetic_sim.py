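"""Clade-structured synthetic allele-count data and robustness experiments.

The generator emulates the input regime of droplet scRNA-seq genotyping:
cells belong to a small number of clades; a fraction of sites is
clade-informative (different true genotypes between clades) while the rest
share one genotype; per-element read depth is negative-binomial with
log-normal site-specific means (expression-driven uneven coverage), rescaled
so the realized zero fraction matches a target sparsity; and alternate reads
are binomial with a sequencing-error-aware allele fraction (epsilon for
Reference, 0.5 for Heterozygous, 1 - epsilon for Alternate).

Defaults mirror a two-lineage cell-line experiment: 400 cells in two equal
clades, 500 sites, ~65% dropout, 5% read error.

The sweep harness degrades or perturbs the data (extra sparsity, random
genotype flips, minority-subclone spike-ins, site/neighbour counts), runs the
smoothing pipeline, builds the neighbor-joining fallback tree, and scores
Pagel's lambda on 0/1 clade labels plus the ARI between the tree's root
bipartition and the true clades.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotype_model import A, H, MISSING, R, GenotypeModelParams, call_unsmoothed
from .io_formats import SiteCellCounts, ValidationError, VariantSite
from .phylo_export import encode_alignment, hamming_distance_matrix, nj_tree, root_bipartition_labels
from .phylo_stats import adjusted_rand_index, pagels_lambda
from .site_filter import select_top_sites
from .smoothing import SmoothingParams, smooth_genotypes

_GENOTYPES = np.array([R, H, A], dtype=np.int8)


@dataclass(frozen=True)
class SimConfig:
    n_cells: int = 400
    n_sites: int = 500
    n_clades: int = 2
    clade_proportions: tuple[float, ...] | None = None
    frac_informative_sites: float = 0.10
    informative_penetrance: tuple[float, float] = (0.8, 1.0)
    allelic_dispersion: float = 1.0
    mean_coverage: float = 2.0
    coverage_dispersion: float = 0.5
    cell_depth_sigma: float = 0.5
    seq_error_rate: float = 0.05
    target_sparsity: float | None = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.clade_proportions
        if props is None:
            props = tuple([1.0 / self.n_clades] * self.n_clades)
            object.__setattr__(self, "clade_proportions", props)
        if len(props) != self.n_clades:
            raise ValidationError("clade_proportions length must equal n_clades")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValidationError(f"clade proportions sum to {sum(props)}, not 1")
        if not (0.0 <= self.frac_informative_sites <= 1.0):
            raise ValidationError("frac_informative_sites must be in [0, 1]")
        if not (0.0 <= self.seq_error_rate <= 0.2):
            raise ValidationError("seq_error_rate must be in [0, 0.2]")
        if self.target_sparsity is not None and not (0.0 <= self.target_sparsity <= 1.0):
            raise ValidationError("target_sparsity must be in [0, 1]")


@dataclass
class SimTruth:
    clade_labels: list[str]
    genotypes: np.ndarray  # sites x cells, codes R/H/A
    tree: dendropy.Tree
    informative_sites: np.ndarray  # boolean mask over sites


def _clade_sizes(n_cells: int, proportions: tuple[float, ...]) -> list[int]:
    sizes = [int(np.floor(p * n_cells)) for p in proportions]
    # hand out the remainder to the largest fractional parts
    rema = n_cells - sum(sizes)
    fracs = np.argsort([-(p * n_cells - np.floor(p * n_cells)) for p in proportions])
    for k in range(rema):
        sizes[fracs[k % len(sizes)]] += 1
    return sizes


def _clade_tree(sizes: list[int], cells: list[str], labels: list[str]) -> dendropy.Tree:
    """Balanced clade tree: unit branch to each clade ancestor, 0.1 to tips."""
    taxa = dendropy.TaxonNamespace(cells)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    start = 0
    for size in sizes:
        anc = tree.seed_node.new_child(edge_length=1.0)
        for cell in cells[start : start + size]:
            tip = anc.new_child(edge_length=0.1)
            tip.taxon = taxa.get_taxon(cell)
        start += size
    return tree


def _nb_zero_fraction(mu: np.ndarray, r: float) -> float:
    return float(np.mean((r / (r + mu)) ** r))


def simulate_dataset(config: SimConfig | None = None) -> tuple[SiteCellCounts, SimTruth]:
    """Generate allele counts and ground truth under the configured regime."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    sizes = _clade_sizes(config.n_cells, config.clade_proportions)
    clade_names = [string.ascii_uppercase[k % 26] + (str(k // 26) if k >= 26 else "")
                   for k in range(config.n_clades)]
    clade_of_cell = np.concatenate(
        [np.full(size, k) for k, size in enumerate(sizes)]
    )
    cells = [f"cell{j:04d}" for j in range(config.n_cells)]
    labels = [clade_names[k] for k in clade_of_cell]

    # true genotypes: shared background, clade-specific at informative sites
    n_informative = int(round(config.frac_informative_sites * config.n_sites))
    informative = np.zeros(config.n_sites, dtype=bool)
    informative[rng.choice(config.n_sites, size=n_informative, replace=False)] = True
    background = rng.choice(_GENOTYPES, size=config.n_sites, p=[0.55, 0.25, 0.20])
    clade_geno = np.tile(background[:, None], (1, config.n_clades))
    for i in np.flatnonzero(informative):
        # lineage differences are het gains/losses: a hom-to-hom switch would
        # need two independent hits, so one side of every pair is H
        other = rng.choice(np.array([R, A], dtype=np.int8))
        pair = np.array([H, other], dtype=np.int8)
        if rng.random() < 0.5:
            pair = pair[::-1]
        split = rng.integers(1, config.n_clades) if config.n_clades > 2 else 1
        for k in range(config.n_clades):
            clade_geno[i, k] = pair[0] if k < split else pair[1]
    genotypes = clade_geno[:, clade_of_cell]
    # distinguishing variants are subclonal: at each informative site only a
    # random fraction of a clade's cells carry that clade's state, the rest
    # retain the other state (partial penetrance within lineages)
    lo, hi = config.informative_penetrance
    for i in np.flatnonzero(informative):
        penetrance = rng.uniform(lo, hi)
        revert = rng.random(config.n_cells) > penetrance
        states = clade_geno[i, :]
        other_state = np.where(
            genotypes[i] == states.max(), states.min(), states.max()
        )
        genotypes[i] = np.where(revert, other_state, genotypes[i])

    # read depth: NB with log-normal site means (expression-driven) times
    # log-normal cell depth factors (library-size variation), rescaled onto
    # the target zero fraction
    site_means = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_sites)
    site_means *= config.mean_coverage / site_means.mean()
    cell_factors = rng.lognormal(mean=0.0, sigma=config.cell_depth_sigma,
                                 size=config.n_cells)
    cell_factors /= cell_factors.mean()
    mu = site_means[:, None] * cell_factors[None, :]
    r = config.coverage_dispersion
    if config.target_sparsity is not None:
        target = config.target_sparsity

        def gap(scale: float) -> float:
            return _nb_zero_fraction(scale * mu, r) - target

        lo, hi = 1e-6, 1e6
        if not (gap(hi) < 0 < gap(lo)):
            raise ValidationError(
                f"target_sparsity={target} unreachable; achievable range is "
                f"({_nb_zero_fraction(hi * mu, r):.4f}, "
                f"{_nb_zero_fraction(lo * mu, r):.4f})"
            )
        mu = brentq(gap, lo, hi, xtol=1e-9) * mu

    total = rng.negative_binomial(n=r, p=r / (r + mu))

    # homozygous elements read the error-bounded allele fraction; heterozygous
    # elements suffer allelic bursting: with few mRNA molecules captured, the
    # observed fraction is overdispersed around 0.5 (Beta(a, a), small a means
    # mostly monoallelic observations)
    vaf_of = {R: config.seq_error_rate, H: 0.5, A: 1.0 - config.seq_error_rate}
    vaf = np.vectorize(vaf_of.get)(genotypes).astype(np.float64)
    het = genotypes == H
    if config.allelic_dispersion > 0 and np.isfinite(config.allelic_dispersion):
        a = config.allelic_dispersion
        vaf[het] = rng.beta(a, a, size=int(het.sum()))
    alt = rng.binomial(total, vaf)
    ref = total - alt

    sites = [
        VariantSite(chrom=str(1 + (i % 22)), pos=1000 + 100 * i, ref_allele="A",
                    alt_allele="G")
        for i in range(config.n_sites)
    ]
    counts = SiteCellCounts(sites=sites, cells=cells, ref_counts=ref, alt_counts=alt)
    truth = SimTruth(
        clade_labels=labels,
        genotypes=genotypes.astype(np.int8),
        tree=_clade_tree(sizes, cells, labels),
        informative_sites=informative,
    )
    return counts, truth


def degrade_sparsity(
    counts: SiteCellCounts, target_sparsity: float, seed: int = 0
) -> SiteCellCounts:
    """Zero random nonzero elements (both matrices jointly) up to the target."""
    total = counts.total_counts()
    n_elements = total.size
    current = int(np.sum(total == 0))
    # realized sparsity fluctuates around any nominal target, so a target
    # within half a percent below the current level is treated as "already
    # there" rather than an error
    if target_sparsity < current / n_elements - 0.005:
        raise ValidationError(
            f"target sparsity {target_sparsity:.3f} below current "
            f"{current / n_elements:.3f}"
        )
    target_zeros = max(int(round(target_sparsity * n_elements)), current)
    rng = np.random.default_rng(seed)
    nz_rows, nz_cols = np.nonzero(total)
    pick = rng.choice(nz_rows.size, size=target_zeros - current, replace=False)
    ref = counts.ref_counts.copy()
    alt = counts.alt_counts.copy()
    ref[nz_rows[pick], nz_cols[pick]] = 0
    alt[nz_rows[pick], nz_cols[pick]] = 0
    return SiteCellCounts(
        sites=list(counts.sites), cells=list(counts.cells), ref_counts=ref, alt_counts=alt
    )


def flip_genotype_calls(calls: np.ndarray, fraction: float, seed: int = 0) -> np.ndarray:
    """Reassign a random floor(fraction * n) of elements to a different genotype."""
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError("fraction must be in [0, 1]")
    calls = np.asarray(calls)
    out = calls.copy()
    rng = np.random.default_rng(seed)
    n = calls.size
    n_flip = int(np.floor(fraction * n))
    flat = rng.choice(n, size=n_flip, replace=False)
    rows, cols = np.unravel_index(flat, calls.shape)
    old = calls[rows, cols].astype(np.int64)
    # adding 1 or 2 mod 3 is a uniform draw over the two other genotypes;
    # MISSING elements (if any) get a uniform draw over all three states
    shift = rng.integers(1, 3, size=n_flip)
    new = ((np.where(old == MISSING, rng.integers(0, 3, size=n_flip), old) + shift) % 3)
    out[rows, cols] = new.astype(calls.dtype)
    return out


def spike_subclone(
    major: SiteCellCounts,
    major_labels: list[str],
    minor: SiteCellCounts,
    minor_labels: list[str],
    minor_fraction: float,
    total_cells: int,
    seed: int = 0,
) -> tuple[SiteCellCounts, list[str]]:
    """Mix a minority subclone into a majority pool at a fixed total cell count."""
    if [s.key for s in major.sites] != [s.key for s in minor.sites]:
        raise ValidationError("major and minor pools must share the same site list")
    n_minor = int(np.floor(minor_fraction * total_cells))
    n_major = total_cells - n_minor
    if n_major > major.n_cells or n_minor > minor.n_cells:
        raise ValidationError(
            f"insufficient pool: need {n_major} major of {major.n_cells}, "
            f"{n_minor} minor of {minor.n_cells}"
        )
    rng = np.random.default_rng(seed)
    maj_idx = rng.choice(major.n_cells, size=n_major, replace=False)
    min_idx = rng.choice(minor.n_cells, size=n_minor, replace=False)
    maj = major.subset_cells(np.sort(maj_idx))
    mnr = minor.subset_cells(np.sort(min_idx))
    mnr_cells = [f"minor:{c}" for c in mnr.cells]
    mixed = SiteCellCounts(
        sites=list(major.sites),
        cells=list(maj.cells) + mnr_cells,
        ref_counts=np.hstack([maj.ref_counts, mnr.ref_counts]),
        alt_counts=np.hstack([maj.alt_counts, mnr.alt_counts]),
    )
    labels = [major_labels[i] for i in np.sort(maj_idx)] + [
        minor_labels[i] for i in np.sort(min_idx)
    ]
    return mixed, labels


def genotype_clustering_ari(
    calls: np.ndarray, true_labels: list[str], n_clusters: int = 2, seed: int = 0
) -> float:
    """ARI between a k-means clustering of the genotype calls and true labels.

    Cells are one-hot encoded over {R, H, A} per site (MISSING encodes as
    all-zero), so dropout-heavy unsmoothed calls carry little clustering
    signal — the comparison before vs after smoothing quantifies how much
    structure smoothing recovers.
    """
    from sklearn.cluster import KMeans

    calls = np.asarray(calls)
    n_sites, n_cells = calls.shape
    X = np.zeros((n_cells, n_sites * 3), dtype=np.float32)
    for g in range(3):
        X[:, g::3] = (calls == g).T
    pred = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit_predict(X)
    return adjusted_rand_index(true_labels, pred)


# ---------------------------------------------------------------------------
# End-to-end evaluation and sweeps
# ---------------------------------------------------------------------------

def evaluate_pipeline(
    counts: SiteCellCounts,
    clade_labels: list[str],
    model: GenotypeModelParams | None = None,
    smoothing: SmoothingParams | None = None,
    max_sites: int = 1000,
    flip_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Smooth, select sites, build the NJ fallback tree, and score it.

    Returns Pagel's lambda (0/1 clade labels), its LRT p-value, and the ARI
    between the tree's root bipartition and the true clades.
    """
    smoothing = smoothing or SmoothingParams(seed=seed)
    _, calls, _ = smooth_genotypes(counts, model, smoothing)
    if flip_fraction > 0:
        calls = flip_genotype_calls(calls, flip_fraction, seed=seed + 1)
    selected = select_top_sites(counts, max_sites)
    site_index = {s.key: i for i, s in enumerate(counts.sites)}
    keep = np.array([site_index[s.key] for s in selected.sites])
    alignment = encode_alignment(calls[keep], selected.sites, counts.cells)
    dist = hamming_distance_matrix(alignment)
    tree = nj_tree(dist, counts.cells)
    label_of = dict(zip(counts.cells, clade_labels))
    signal = pagels_lambda(tree, {c: label_of[c] for c in counts.cells})
    split = root_bipartition_labels(tree)
    ari = adjusted_rand_index(
        [label_of[c] for c in counts.cells], [split[c] for c in counts.cells]
    )
    return {
        "lambda": signal.lambda_hat,
        "p_value": signal.p_value,
        "ari": ari,
    }


SWEEP_KINDS = ("neighbors", "n_sites", "sparsity", "flip", "subclone")


def run_robustness_sweep(
    kind: str,
    grid: list[float],
    config: SimConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run one robustness experiment across a parameter grid.

    kinds: 'neighbors' (K), 'n_sites' (site cap), 'sparsity' (degraded zero
    fraction), 'flip' (fraction of calls randomized), 'subclone' (minority
    clade fraction).  Returns one row per grid point with lambda, p, ARI.
    """
    if kind not in SWEEP_KINDS:
        raise ValidationError(f"unknown sweep kind {kind!r}; choose from {SWEEP_KINDS}")
    config = config or SimConfig()
    config = replace(config, seed=seed)
    rows = []
    if kind == "subclone":
        pool_cfg = replace(config, n_cells=2 * config.n_cells, seed=seed)
        pool_counts, pool_truth = simulate_dataset(pool_cfg)
        clades = np.array(pool_truth.clade_labels)
        major_pool = pool_counts.subset_cells(np.flatnonzero(clades == clades[0]))
        minor_pool = pool_counts.subset_cells(np.flatnonzero(clades != clades[0]))
    else:
        base_counts, base_truth = simulate_dataset(config)

    for value in grid:
        if kind == "subclone":
            counts, labels = spike_subclone(
                major_pool,
                ["major"] * major_pool.n_cells,
                minor_pool,
                ["minor"] * minor_pool.n_cells,
                minor_fraction=value,
                total_cells=config.n_cells,
                seed=seed + 17,
            )
            metrics = evaluate_pipeline(counts, labels, seed=seed)
        elif kind == "sparsity":
            counts = degrade_sparsity(base_counts, value, seed=seed + 23)
            metrics = evaluate_pipeline(counts, base_truth.clade_labels, seed=seed)
        elif kind == "flip":
            metrics = evaluate_pipeline(
                base_counts, base_truth.clade_labels, flip_fraction=value, seed=seed
            )
        elif kind == "n_sites":
            metrics = evaluate_pipeline(
                base_counts, base_truth.clade_labels, max_sites=int(value), seed=seed
            )
        else:  # neighbors
            metrics = evaluate_pipeline(
                base_counts,
                base_truth.clade_labels,
                smoothing=SmoothingParams(K=int(value), seed=seed),
                seed=seed,
            )
        rows.append({"kind": kind, "value": value, **metrics})
    return pd.DataFrame(rows)
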