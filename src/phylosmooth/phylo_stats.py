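"""Tree statistics for evaluating phylogenies against cell traits.

* Pagel's lambda — maximum-likelihood phylogenetic signal of a continuous
  (or 0/1-coded binary) trait under a Brownian-motion model whose phylogenetic
  covariance has its off-diagonal entries scaled by lambda; significance from
  a likelihood-ratio test against lambda = 0 (chi-square, 1 df).
* Blomberg's K — ratio of observed to Brownian-expected trait variance
  partitioning; K near 1 is the Brownian expectation.
* SES MPD — standardized effect size of the mean pairwise cophenetic distance
  within a group of tips, against a tip-label permutation null; negative z
  means the group is phylogenetically clustered.
* Adjusted Rand index — chance-corrected agreement between two partitions of
  the same cells.

The lambda upper bound is max(diag C)/max(offdiag C), the largest value for
which the transformed covariance remains a valid tree covariance; this allows
estimates above 1 where the data support them.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .io_formats import TraitVector, ValidationError


@dataclass
class PhyloSignalResult:
    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    p_value: float

    @property
    def lrt_statistic(self) -> float:
        return 2.0 * (self.loglik_at_hat - self.loglik_at_zero)


@dataclass
class DiversityResult:
    group: str
    mpd_obs: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------

def phylo_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: C_ij = root-to-MRCA(i, j) path length.

    Returns (tip labels, matrix).  Computed from root-to-tip depths and
    patristic distances: C_ij = (d_i + d_j - dist_ij) / 2.
    """
    if not tree.is_rooted:
        raise ValidationError("phylogenetic covariance requires a rooted tree")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    depths = np.array([leaf.root_distance for leaf in leaves], dtype=np.float64)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pdm.patristic_distance(
                leaves[i].taxon, leaves[j].taxon
            )
    C = (depths[:, None] + depths[None, :] - dist) / 2.0
    C = np.clip(C, 0.0, None)
    np.fill_diagonal(C, depths)
    return labels, C


def cophenetic_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels and pairwise patristic (cophenetic) distances."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    labels = [t.label for t in taxa]
    n = len(taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, dist


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

def _as_numeric_trait(trait: TraitVector | dict, labels: list[str]) -> np.ndarray:
    mapping = trait.labels if isinstance(trait, TraitVector) else trait
    missing = [t for t in labels if t not in mapping]
    if missing:
        raise ValidationError(f"trait missing for tips: {missing[:5]}")
    values = [mapping[t] for t in labels]
    if any(isinstance(v, str) for v in values):
        categories = sorted(set(values))
        if len(categories) != 2:
            raise ValidationError(
                "categorical traits must be binary for signal statistics; "
                f"got {len(categories)} categories"
            )
        values = [float(categories.index(v)) for v in values]
    y = np.asarray(values, dtype=np.float64)
    if np.ptp(y) == 0:
        raise ValidationError("trait is constant: phylogenetic signal undefined")
    return y


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood with the BM mean and rate profiled out analytically."""
    n = y.size
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -1e18  # finite floor keeps bounded optimization well-behaved
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ones = np.ones(n)
    Vi_y = cho_solve(cf, y)
    Vi_1 = cho_solve(cf, ones)
    mu = (ones @ Vi_y) / (ones @ Vi_1)
    resid = y - mu
    sigma2 = resid @ cho_solve(cf, resid) / n
    if sigma2 <= 0:
        return -1e18
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def lambda_loglik(
    tree_or_C: dendropy.Tree | np.ndarray,
    trait: TraitVector | dict | np.ndarray,
    lam: float,
    labels: list[str] | None = None,
) -> float:
    """Profile log-likelihood of the trait at a fixed lambda."""
    if isinstance(tree_or_C, dendropy.Tree):
        labels, C = phylo_vcv(tree_or_C)
        y = _as_numeric_trait(trait, labels)
    else:
        C = np.asarray(tree_or_C)
        y = (
            np.asarray(trait, dtype=np.float64)
            if isinstance(trait, np.ndarray)
            else _as_numeric_trait(trait, labels)
        )
    return _profile_loglik(y, _lambda_transform(C, lam))


def lambda_upper_bound(C: np.ndarray) -> float:
    off = C[~np.eye(C.shape[0], dtype=bool)]
    max_off = off.max() if off.size else 0.0
    if max_off <= 0:
        return 1.0
    return float(np.max(np.diag(C)) / max_off)


def pagels_lambda(
    tree: dendropy.Tree, trait: TraitVector | dict
) -> PhyloSignalResult:
    """ML estimate of Pagel's lambda with an LRT p-value against lambda = 0."""
    labels, C = phylo_vcv(tree)
    y = _as_numeric_trait(trait, labels)
    lam_max = lambda_upper_bound(C)

    def neg(lam: float) -> float:
        return -_profile_loglik(y, _lambda_transform(C, lam))

    res = minimize_scalar(neg, bounds=(0.0, lam_max), method="bounded",
                          options={"xatol": 1e-6})
    candidates = [(float(res.x), -res.fun), (0.0, -neg(0.0)), (lam_max, -neg(lam_max))]
    lam_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll_zero = -neg(0.0)
    if not np.isfinite(ll_hat):
        raise ValidationError("lambda likelihood is degenerate (singular covariance)")
    stat = max(0.0, 2.0 * (ll_hat - ll_zero))
    return PhyloSignalResult(
        lambda_hat=lam_hat,
        loglik_at_hat=ll_hat,
        loglik_at_zero=ll_zero,
        p_value=float(chi2.sf(stat, df=1)),
    )


def simulate_brownian_trait(
    tree: dendropy.Tree, seed: int = 0, lam: float = 1.0, sigma2: float = 1.0
) -> dict[str, float]:
    """Draw one trait vector from the (lambda-transformed) BM model on a tree."""
    labels, C = phylo_vcv(tree)
    V = sigma2 * _lambda_transform(C, lam)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
    rng = np.random.default_rng(seed)
    y = L @ rng.standard_normal(len(labels))
    return dict(zip(labels, y.tolist()))


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def blomberg_k(tree: dendropy.Tree, trait: TraitVector | dict) -> float:
    """Blomberg's K: observed vs Brownian-expected variance partitioning.

    K = (MSE0 / MSE) / E[MSE0 / MSE], with the phylogenetically corrected
    mean a_hat = (1' C^-1 y) / (1' C^-1 1), MSE0 the ordinary mean squared
    deviation from a_hat, MSE the phylogenetically corrected one, and the
    expectation (tr C - n / (1' C^-1 1)) / (n - 1).
    """
    labels, C = phylo_vcv(tree)
    y = _as_numeric_trait(trait, labels)
    n = y.size
    # tiny ridge keeps the factorization stable when cherries are very short
    C = C + 1e-10 * np.mean(np.diag(C)) * np.eye(n)
    cf = cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci_y = cho_solve(cf, y)
    Ci_1 = cho_solve(cf, ones)
    a_hat = (ones @ Ci_y) / (ones @ Ci_1)
    resid = y - a_hat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ cho_solve(cf, resid) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Ci_1)) / (n - 1)
    return float((mse0 / mse) / expected)


def binarize_reference_vs_other(calls_row: np.ndarray) -> np.ndarray:
    """Code a site's genotype calls 0 for Reference, 1 for any other state."""
    from .genotype_model import R as REF_CODE

    return (np.asarray(calls_row) != REF_CODE).astype(float)


# ---------------------------------------------------------------------------
# SES MPD
# ---------------------------------------------------------------------------

def mpd_from_matrix(dist: np.ndarray, index: np.ndarray) -> float:
    """Mean pairwise distance among the given tip indices."""
    sub = dist[np.ix_(index, index)]
    iu = np.triu_indices(len(index), k=1)
    return float(sub[iu].mean())


def ses_mpd(
    tree: dendropy.Tree,
    groups: TraitVector | dict,
    n_perm: int = 999,
    seed: int = 0,
) -> list[DiversityResult]:
    """SES of within-group mean pairwise distance vs a tip-shuffle null.

    For each group, the null holds group sizes fixed and permutes tip labels.
    z = (mpd_obs - null_mean) / null_sd (0 when the null is degenerate);
    p is the lower-tail permutation rank, so small p with negative z indicates
    phylogenetic clustering.
    """
    labels, dist = cophenetic_distance_matrix(tree)
    mapping = groups.labels if isinstance(groups, TraitVector) else groups
    missing = [t for t in labels if t not in mapping]
    if missing:
        raise ValidationError(f"group label missing for tips: {missing[:5]}")
    assignment = np.array([str(mapping[t]) for t in labels])
    rng = np.random.default_rng(seed)
    n = len(labels)
    results = []
    for group in sorted(set(assignment)):
        index = np.flatnonzero(assignment == group)
        if index.size < 2:
            raise ValidationError(f"group {group!r} has fewer than 2 tips")
        obs = mpd_from_matrix(dist, index)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = mpd_from_matrix(dist, rng.choice(n, size=index.size, replace=False))
        sd = null.std(ddof=1)
        degenerate = sd <= 1e-9 * max(1.0, abs(null.mean()))
        z = 0.0 if degenerate else (obs - null.mean()) / sd
        p = (np.sum(null <= obs) + 1) / (n_perm + 1)
        results.append(
            DiversityResult(
                group=group,
                mpd_obs=obs,
                null_mean=float(null.mean()),
                null_sd=float(sd),
                z=float(z),
                p_value=float(p),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Partition agreement and multiple testing
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement between two labelings."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValidationError(
            f"labelings differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    return float(adjusted_rand_score(labels_a, labels_b))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values for a vector of p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
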