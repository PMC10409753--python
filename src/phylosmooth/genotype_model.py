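"""Beta-binomial genotype probabilities and discrete genotype calls.

For a site x cell element with ``r`` reference and ``a`` alternate reads, the
variant allele frequency p is modelled as Beta(a + 1, r + 1) — the posterior
under a uniform prior with the alternate reads as Bernoulli successes.  The
three genotype probabilities are masses of this density over three intervals
set by a noise threshold theta (default 0.3):

    P(Reference)    = I_theta(a + 1, r + 1)
    P(Alternate)    = 1 - I_{1 - theta}(a + 1, r + 1)
    P(Heterozygous) = 1 - P(Reference) - P(Alternate)

where I_x is the regularized incomplete beta function.  With zero reads the
density is uniform, so the masses are the interval lengths (theta, 1 - 2*theta,
theta).  The called genotype is the argmax; exact ties break with precedence
H > R > A (a tie means the reads cannot separate the homozygous states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc

from .io_formats import SiteCellCounts, ValidationError

# genotype codes used throughout the package
R, H, A = 0, 1, 2
MISSING = -1
GENOTYPE_NAMES = {R: "R", H: "H", A: "A", MISSING: "MISSING"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_NAMES.items()}


class ConfigurationError(ValueError):
    """A model parameter is outside its valid range."""


@dataclass(frozen=True)
class GenotypeModelParams:
    """Parameters of the beta-binomial genotype model.

    theta is the read-noise threshold: the alt-allele-frequency mass below
    theta is attributed to a homozygous-reference genotype, above 1 - theta
    to homozygous-alternate, and the remainder to heterozygous.  It must lie
    in (0, 0.5) so the three integration regions are non-degenerate.
    """

    theta: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 0.5):
            raise ConfigurationError(f"theta must be in (0, 0.5), got {self.theta}")


def genotype_probabilities(
    counts: SiteCellCounts, params: GenotypeModelParams | None = None
) -> np.ndarray:
    """Per-element genotype probabilities.

    Returns a (n_sites, n_cells, 3) array with slots ordered (R, H, A); each
    triple sums to 1.  Zero-read elements get the uniform-prior masses
    (theta, 1 - 2*theta, theta) so that downstream sampling and smoothing
    remain defined under dropout.
    """
    params = params or GenotypeModelParams()
    return probabilities_from_reads(counts.ref_counts, counts.alt_counts, params)


def probabilities_from_reads(
    ref: np.ndarray, alt: np.ndarray, params: GenotypeModelParams | None = None
) -> np.ndarray:
    """Vectorized core of :func:`genotype_probabilities` on raw count arrays."""
    params = params or GenotypeModelParams()
    ref = np.asarray(ref, dtype=np.float64)
    alt = np.asarray(alt, dtype=np.float64)
    if ref.shape != alt.shape:
        raise ValidationError("ref and alt count arrays differ in shape")
    alpha = alt + 1.0
    beta = ref + 1.0
    p_ref = betainc(alpha, beta, params.theta)
    p_alt = 1.0 - betainc(alpha, beta, 1.0 - params.theta)
    p_het = np.clip(1.0 - p_ref - p_alt, 0.0, 1.0)
    probs = np.stack([p_ref, p_het, p_alt], axis=-1)
    return probs / probs.sum(axis=-1, keepdims=True)


def call_genotypes(probs: np.ndarray) -> np.ndarray:
    """Argmax genotype call per element, ties broken H > R > A.

    ``probs`` has shape (..., 3) ordered (R, H, A); the result holds the
    genotype codes ``R``/``H``/``A``.
    """
    # argmax returns the first maximal slot, so ordering slots (H, R, A)
    # implements the tie precedence directly.
    reordered = probs[..., [H, R, A]]
    first = np.argmax(reordered, axis=-1)
    return np.array([H, R, A], dtype=np.int8)[first]


def call_unsmoothed(
    counts: SiteCellCounts, params: GenotypeModelParams | None = None
) -> np.ndarray:
    """Baseline calls without smoothing: zero-read elements are MISSING."""
    probs = genotype_probabilities(counts, params)
    calls = call_genotypes(probs)
    calls[counts.total_counts() == 0] = MISSING
    return calls


DEFAULT_COVERAGE_BINS = ((0, 0, "dropout"), (1, 1, "low"), (2, 4, "medium"), (5, None, "high"))


def coverage_bin_labels(
    total_reads: np.ndarray, bins=DEFAULT_COVERAGE_BINS
) -> np.ndarray:
    """Assign each element a coverage-bin label (object array of strings)."""
    labels = np.empty(total_reads.shape, dtype=object)
    for lo, hi, name in bins:
        mask = total_reads >= lo if hi is None else (total_reads >= lo) & (total_reads <= hi)
        labels[mask] = name
    return labels


def tabulate_genotype_changes(
    before: np.ndarray,
    after: np.ndarray,
    counts: SiteCellCounts,
    bins=DEFAULT_COVERAGE_BINS,
) -> dict[str, pd.DataFrame]:
    """Coverage-stratified before/after genotype transition tables.

    For each coverage bin, returns a percentage table whose columns are the
    genotype before smoothing and rows the genotype after; each before-column
    sums to 100%.  Bins with no elements of a given before-genotype hold NaN
    in that column (e.g. Heterozygous cannot be called from a single read, so
    the low-coverage H column is undefined without smoothing).
    """
    before = np.asarray(before)
    after = np.asarray(after)
    if before.shape != after.shape or before.shape != (counts.n_sites, counts.n_cells):
        raise ValidationError("before/after call matrices do not match the counts shape")
    bin_labels = coverage_bin_labels(counts.total_counts(), bins)
    states = [R, H, A, MISSING]
    names = [GENOTYPE_NAMES[s] for s in states]
    tables: dict[str, pd.DataFrame] = {}
    for _, _, bin_name in bins:
        mask = bin_labels == bin_name
        table = pd.DataFrame(0.0, index=names, columns=names)
        for bi, b in enumerate(states):
            col_mask = mask & (before == b)
            n = int(col_mask.sum())
            if n == 0:
                table.iloc[:, bi] = np.nan
                continue
            for ai, a in enumerate(states):
                table.iloc[ai, bi] = 100.0 * np.sum(col_mask & (after == a)) / n
        tables[bin_name] = table
    return tables


def change_rate_by_bin(
    before: np.ndarray,
    after: np.ndarray,
    counts: SiteCellCounts,
    bins=DEFAULT_COVERAGE_BINS,
) -> pd.Series:
    """Fraction of elements whose call changed, per coverage bin."""
    bin_labels = coverage_bin_labels(counts.total_counts(), bins)
    out = {}
    for _, _, bin_name in bins:
        mask = bin_labels == bin_name
        out[bin_name] = float(np.mean(before[mask] != after[mask])) if mask.any() else np.nan
    return pd.Series(out)


def calls_to_strings(calls: np.ndarray) -> np.ndarray:
    """Map integer genotype codes to 'R'/'H'/'A'/'MISSING' strings."""
    return np.vectorize(GENOTYPE_NAMES.get)(calls)


def write_calls_tsv(calls: np.ndarray, counts: SiteCellCounts, path: str) -> None:
    """Export calls as a long TSV (chrom, pos, cell, call)."""
    names = calls_to_strings(calls)
    rows = []
    for i, site in enumerate(counts.sites):
        for j, cell in enumerate(counts.cells):
            rows.append((site.chrom, site.pos, cell, names[i, j]))
    pd.DataFrame(rows, columns=["chrom", "pos", "cell", "call"]).to_csv(
        path, sep="\t", index=False
    )
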