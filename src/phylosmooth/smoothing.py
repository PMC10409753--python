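"""kNN smoothing of genotype probabilities.

Cell-cell genotype similarity is estimated by repeatedly sampling a discrete
genotype profile for every cell from its per-site (R, H, A) distributions and
scoring each pair by the fraction of sites where the two cells drew the same
genotype, averaged over samplings.  Each cell's K highest-scoring neighbours
(excluding itself) then define a convex smoothing of its probabilities:

    p_hat[i, j, g] = (1 - delta) * p[i, j, g] + delta * mean_k p[k, j, g]

With the default delta = K / (K + 1) this is exactly the plain average of the
cell with its K neighbours.  One profile per cell per sampling iteration is
drawn and reused across all pairs; this matched-draw scheme has the same
expectation as drawing per pair and keeps the similarity matrix symmetric by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import (
    GenotypeModelParams,
    call_genotypes,
    genotype_probabilities,
)
from .io_formats import SiteCellCounts, ValidationError


@dataclass(frozen=True)
class SmoothingParams:
    """K nearest neighbours, neighbour mass delta (default K/(K+1)),
    number of profile samplings, and the RNG seed."""

    K: int = 10
    delta: float | None = None
    n_samplings: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValidationError(f"K must be >= 1, got {self.K}")
        if self.n_samplings < 1:
            raise ValidationError(f"n_samplings must be >= 1, got {self.n_samplings}")
        if self.delta is not None and not (0.0 <= self.delta <= 1.0):
            raise ValidationError(f"delta must be in [0, 1], got {self.delta}")

    @property
    def effective_delta(self) -> float:
        return self.K / (self.K + 1.0) if self.delta is None else self.delta


@dataclass
class NeighborMap:
    """Per-cell K nearest neighbours: (n_cells, K) index and score arrays,
    scores non-increasing along each row."""

    indices: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.indices.shape != self.scores.shape:
            raise ValidationError("neighbor index and score arrays differ in shape")
        if any(
            i in set(row) for i, row in enumerate(np.atleast_2d(self.indices))
        ):
            raise ValidationError("a cell appears in its own neighbor list")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    @property
    def K(self) -> int:
        return self.indices.shape[1]

    def to_dataframe(self, cells: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for i in range(self.n_cells):
            for rank in range(self.K):
                j = int(self.indices[i, rank])
                rows.append(
                    (
                        cells[i] if cells else i,
                        rank + 1,
                        cells[j] if cells else j,
                        float(self.scores[i, rank]),
                    )
                )
        return pd.DataFrame(rows, columns=["cell", "rank", "neighbor", "score"])


def sample_profiles(
    probs: np.ndarray, n_samplings: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw genotype profiles from per-element (R, H, A) distributions.

    Returns an int8 array of shape (n_samplings, n_sites, n_cells) holding
    genotype codes.  Reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(size=(n_samplings,) + probs.shape[:-1] + (1,))
    return (u > cum[None, ...]).sum(axis=-1).astype(np.int8)


def pairwise_similarity(
    probs: np.ndarray, params: SmoothingParams | None = None
) -> np.ndarray:
    """Cells x cells matched-draw agreement matrix.

    s[i, j] = mean over samplings of the fraction of sites at which cells i
    and j drew the same genotype.  Symmetric, unit diagonal, values in [0, 1].
    """
    params = params or SmoothingParams()
    n_sites, n_cells = probs.shape[0], probs.shape[1]
    if n_sites < 1:
        raise ValidationError("similarity requires at least one site")
    if n_cells < 2:
        raise ValidationError("similarity requires at least two cells")
    rng = np.random.default_rng(params.seed)
    agree = np.zeros((n_cells, n_cells), dtype=np.float64)
    # one sampling at a time keeps memory flat; agreement counts come from
    # one-hot matmuls per genotype state
    for _ in range(params.n_samplings):
        draw = sample_profiles(probs, 1, rng)[0]  # (sites, cells)
        for g in range(3):
            onehot = (draw == g).astype(np.float32)
            agree += (onehot.T @ onehot).astype(np.float64)
    sim = agree / (params.n_samplings * n_sites)
    np.fill_diagonal(sim, 1.0)
    return sim


def build_knn(similarity: np.ndarray, K: int) -> NeighborMap:
    """K highest-scoring other cells per cell; ties broken by ascending index."""
    similarity = np.asarray(similarity)
    n = similarity.shape[0]
    if similarity.shape != (n, n):
        raise ValidationError("similarity matrix must be square")
    if K >= n:
        raise ValidationError(f"K={K} must be < n_cells={n}")
    indices = np.empty((n, K), dtype=np.int64)
    scores = np.empty((n, K), dtype=np.float64)
    order_idx = np.arange(n)
    for i in range(n):
        others = order_idx[order_idx != i]
        # stable sort on descending score keeps ascending-index tie order
        order = others[np.argsort(-similarity[i, others], kind="stable")]
        indices[i] = order[:K]
        scores[i] = similarity[i, indices[i]]
    return NeighborMap(indices=indices, scores=scores)


def smooth_probabilities(
    probs: np.ndarray, neighbors: NeighborMap, delta: float
) -> np.ndarray:
    """Convex combination of each cell's probabilities with its neighbour mean."""
    if not (0.0 <= delta <= 1.0):
        raise ValidationError(f"delta must be in [0, 1], got {delta}")
    if neighbors.n_cells != probs.shape[1]:
        raise ValidationError("neighbor map does not match the number of cells")
    neighbor_mean = probs[:, neighbors.indices, :].mean(axis=2)
    return (1.0 - delta) * probs + delta * neighbor_mean


def smooth_genotypes(
    counts: SiteCellCounts,
    model: GenotypeModelParams | None = None,
    params: SmoothingParams | None = None,
) -> tuple[np.ndarray, np.ndarray, NeighborMap]:
    """Full smoothing stage: probabilities -> similarity -> kNN -> smoothing -> calls.

    Returns (smoothed probabilities, calls, neighbor map).  The calls contain
    no MISSING state: every element has a defined smoothed distribution.
    """
    params = params or SmoothingParams()
    if counts.n_cells < 2:
        raise ValidationError("smoothing requires at least two cells")
    probs = genotype_probabilities(counts, model)
    sim = pairwise_similarity(probs, params)
    K = min(params.K, counts.n_cells - 1)
    neighbors = build_knn(sim, K)
    delta = K / (K + 1.0) if params.delta is None else params.delta
    smoothed = smooth_probabilities(probs, neighbors, delta)
    calls = call_genotypes(smoothed)
    return smoothed, calls, neighbors
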