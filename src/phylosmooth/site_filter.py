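"""Cell- and site-quality filters and final site selection.

The filters run in a fixed order: pseudobulk candidate-variant support, the
per-cell read-depth filter, the coarse per-site filters (coverage,
monomorphic fraction, chromosome, proximity), then — after smoothing, which
is a separate stage — the top-N selection by total reads.

Presets:

* ``default``  — min_site_reads 10, monomorphic_frac 0.90
* ``lenient``  — min_site_reads 5, monomorphic_frac 0.80 (for sparse data)
* ``subclone`` — monomorphic_frac 0.95 (retains sites private to small clades)

The per-site low-coverage clause is interpreted as total reads across cells
per site below ``min_site_reads``; the monomorphic fraction is computed on
unsmoothed argmax calls among covered cells only (dropout excluded from both
numerator and denominator).  A site is removed by the proximity filter when
any other site on the same chromosome lies within ``min_spacing_nt`` bases
(|delta pos| <= min_spacing_nt), which removes every member of a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_model import MISSING
from .io_formats import SiteCellCounts, ValidationError


@dataclass(frozen=True)
class FilterParams:
    min_cell_reads: int = 10_000
    min_pseudobulk_reads: int = 20
    min_alt_reads: int = 5
    min_vaf: float = 0.05
    min_site_reads: int = 10
    monomorphic_frac: float = 0.90
    allowed_chroms: frozenset[str] = frozenset(str(i) for i in range(1, 23))
    min_spacing_nt: int = 5
    max_sites: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.monomorphic_frac < 1.0):
            raise ValidationError(
                f"monomorphic_frac must be in (0, 1), got {self.monomorphic_frac}"
            )
        if self.max_sites < 1:
            raise ValidationError("max_sites must be >= 1")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "FilterParams":
        presets = {
            "default": {},
            "lenient": {"min_site_reads": 5, "monomorphic_frac": 0.80},
            "subclone": {"monomorphic_frac": 0.95},
        }
        if name not in presets:
            raise ValidationError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        return cls(**{**presets[name], **overrides})


def normalize_chrom(chrom: str) -> str:
    """Map 'chr1'/'1' dialects onto a bare name ('1', 'X', ...)."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def filter_cells(counts: SiteCellCounts, min_cell_reads: int = 10_000) -> SiteCellCounts:
    """Drop cells whose total reads across all sites are below the threshold."""
    totals = counts.total_counts().sum(axis=0)
    keep = np.flatnonzero(totals >= min_cell_reads)
    if keep.size == 0:
        raise ValidationError(
            f"all {counts.n_cells} cells fall below min_cell_reads={min_cell_reads}; "
            "review the threshold for this dataset"
        )
    return counts.subset_cells(keep)


def filter_candidate_variants(
    counts: SiteCellCounts, params: FilterParams | None = None
) -> SiteCellCounts:
    """Keep sites whose pseudobulk totals support a credible variant.

    A site passes when, summing reads over all cells: total >= 20, alternate
    reads >= 5, and the alternate fraction >= 5% (defaults).
    """
    params = params or FilterParams()
    ref_tot = counts.ref_counts.sum(axis=1)
    alt_tot = counts.alt_counts.sum(axis=1)
    total = ref_tot + alt_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(total > 0, alt_tot / np.maximum(total, 1), 0.0)
    keep = np.flatnonzero(
        (total >= params.min_pseudobulk_reads)
        & (alt_tot >= params.min_alt_reads)
        & (vaf >= params.min_vaf)
    )
    return counts.subset_sites(keep)


def coarse_filter_sites(
    counts: SiteCellCounts,
    unsmoothed_calls: np.ndarray,
    params: FilterParams | None = None,
    report: list | None = None,
) -> SiteCellCounts:
    """Per-site coarse filters, applied in order.

    Removes sites that (1) have total reads across cells below
    ``min_site_reads``; (2) have the same called base in more than
    ``monomorphic_frac`` of covered cells; (3) lie outside the allowed
    chromosomes; (4) lie within ``min_spacing_nt`` of another remaining site.
    ``report`` (if given) collects (site_key, filter_name) tuples.
    """
    params = params or FilterParams()
    calls = np.asarray(unsmoothed_calls)
    if calls.shape != (counts.n_sites, counts.n_cells):
        raise ValidationError("calls matrix does not match the counts shape")

    removed = np.zeros(counts.n_sites, dtype=bool)
    reason = np.empty(counts.n_sites, dtype=object)

    site_totals = counts.total_counts().sum(axis=1)
    low = site_totals < params.min_site_reads
    removed |= low
    reason[low] = "low_coverage"

    covered = calls != MISSING
    for i in np.flatnonzero(~removed):
        row = calls[i][covered[i]]
        if row.size == 0:
            removed[i] = True
            reason[i] = "monomorphic"
            continue
        _, freq = np.unique(row, return_counts=True)
        if freq.max() / row.size > params.monomorphic_frac:
            removed[i] = True
            reason[i] = "monomorphic"

    for i in np.flatnonzero(~removed):
        if normalize_chrom(counts.sites[i].chrom) not in params.allowed_chroms:
            removed[i] = True
            reason[i] = "chromosome"

    surviving = np.flatnonzero(~removed)
    by_chrom: dict[str, list[int]] = {}
    for i in surviving:
        by_chrom.setdefault(counts.sites[i].chrom, []).append(i)
    for chrom_sites in by_chrom.values():
        pos = np.array([counts.sites[i].pos for i in chrom_sites])
        order = np.argsort(pos)
        sorted_pos = pos[order]
        close = np.zeros(len(chrom_sites), dtype=bool)
        gaps = np.diff(sorted_pos)
        close[:-1] |= gaps <= params.min_spacing_nt
        close[1:] |= gaps <= params.min_spacing_nt
        for k in np.flatnonzero(close):
            i = chrom_sites[order[k]]
            removed[i] = True
            reason[i] = "proximity"

    if report is not None:
        for i in np.flatnonzero(removed):
            report.append((counts.sites[i].key, reason[i]))
    keep = np.flatnonzero(~removed)
    if keep.size == 0:
        raise ValidationError("all sites removed by coarse filters")
    return counts.subset_sites(keep)


def select_top_sites(counts: SiteCellCounts, max_sites: int = 1000) -> SiteCellCounts:
    """Keep the ``max_sites`` sites with the highest total reads.

    Ties at the cap boundary break by ascending (chrom, pos); if fewer sites
    exist, all are kept.  Site order in the result follows the input order.
    """
    if counts.n_sites <= max_sites:
        return counts
    totals = counts.total_counts().sum(axis=1)
    ranked = sorted(
        range(counts.n_sites),
        key=lambda i: (-totals[i], counts.sites[i].chrom, counts.sites[i].pos),
    )
    keep = np.array(sorted(ranked[:max_sites]))
    return counts.subset_sites(keep)


def filter_report_frame(report: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(chrom, pos, why) for (chrom, pos), why in report],
        columns=["chrom", "pos", "filter"],
    )
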