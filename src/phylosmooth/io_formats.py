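"""Readers and writers for the external representations the pipeline touches.

Variant sites come in as VCF 4.x (the output format of an upstream pseudobulk
variant caller), allele counts as long-format TSV or Matrix-Market sparse
triplets, trees as Newick, and per-cell traits/labels as TSV.  All readers
validate their inputs and raise :class:`ValidationError` with a
location-bearing message on bad data.

Positions are 1-based inclusive, as in VCF.  Counts are stored with sites as
rows and cells as columns.  Only biallelic SNVs are supported: indel and
multi-allelic records are skipped and counted, since the pipeline analyzes
base substitutions only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """An input violated a type invariant."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV site: chromosome, 1-based position, ref/alt alleles."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: alleles must be single bases in ACGT, "
                f"got ref={self.ref_allele!r} alt={self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.chrom}:{self.pos}: ref and alt alleles are identical "
                f"({self.ref_allele})"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class SiteCellCounts:
    """Paired sites x cells matrices of reference and alternate read counts."""

    sites: list[VariantSite]
    cells: list[str]
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts)
        self.alt_counts = np.asarray(self.alt_counts)
        shape = (len(self.sites), len(self.cells))
        for name, mat in (("ref_counts", self.ref_counts), ("alt_counts", self.alt_counts)):
            if mat.shape != shape:
                raise ValidationError(
                    f"{name} has shape {mat.shape}, expected {shape} "
                    f"(|sites| x |cells|)"
                )
            if np.any(mat < 0):
                raise ValidationError(f"{name} contains negative entries")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("cell barcodes are not unique")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValidationError("sites are not unique by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total_counts(self) -> np.ndarray:
        """Per-element total read depth (ref + alt)."""
        return self.ref_counts + self.alt_counts

    def sparsity(self) -> float:
        """Fraction of site x cell elements with zero reads (dropout)."""
        return float(np.mean(self.total_counts() == 0))

    def subset_sites(self, index: np.ndarray) -> "SiteCellCounts":
        index = np.asarray(index)
        return SiteCellCounts(
            sites=[self.sites[i] for i in index],
            cells=list(self.cells),
            ref_counts=self.ref_counts[index, :],
            alt_counts=self.alt_counts[index, :],
        )

    def subset_cells(self, index: np.ndarray) -> "SiteCellCounts":
        index = np.asarray(index)
        return SiteCellCounts(
            sites=list(self.sites),
            cells=[self.cells[i] for i in index],
            ref_counts=self.ref_counts[:, index],
            alt_counts=self.alt_counts[:, index],
        )

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format table of the nonzero elements."""
        rows, cols = np.nonzero(self.total_counts())
        return pd.DataFrame(
            {
                "chrom": [self.sites[i].chrom for i in rows],
                "pos": [self.sites[i].pos for i in rows],
                "cell": [self.cells[j] for j in cols],
                "ref_count": self.ref_counts[rows, cols],
                "alt_count": self.alt_counts[rows, cols],
            }
        )


@dataclass
class TraitVector:
    """Per-cell trait values: numeric for continuous traits, strings for labels."""

    labels: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for barcode, value in self.labels.items():
            if isinstance(value, (int, float, np.floating, np.integer)) and not np.isfinite(
                value
            ):
                raise ValidationError(f"trait for cell {barcode!r} is not finite: {value}")

    def values_for(self, cells: list[str]) -> list[float | str]:
        missing = [c for c in cells if c not in self.labels]
        if missing:
            raise ValidationError(f"trait missing for cells: {missing[:5]}")
        return [self.labels[c] for c in cells]


# ---------------------------------------------------------------------------
# Variant sites (VCF)
# ---------------------------------------------------------------------------

def read_variant_sites(path: str) -> list[VariantSite]:
    """Read biallelic SNVs from a VCF 4.x file, preserving record order.

    Indels and multi-allelic records are skipped; the number skipped is
    logged.  Returns one :class:`VariantSite` per accepted record.
    """
    import pysam

    sites: list[VariantSite] = []
    n_skipped = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref.upper() not in _BASES
                or alts[0].upper() not in _BASES
            ):
                n_skipped += 1
                continue
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_allele=alts[0].upper(),
                )
            )
    if n_skipped:
        logger.info("read_variant_sites: skipped %d non-SNV/multi-allelic records", n_skipped)
    return sites


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["chrom", "pos", "cell", "ref_count", "alt_count"]


def read_counts_long(path: str) -> SiteCellCounts:
    """Read allele counts from a long-format TSV.

    Columns: chrom, pos, cell, ref_count, alt_count.  (site, cell) pairs not
    mentioned are zero/zero (dropout).  Sites are ordered by first appearance,
    cells by first appearance.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell": str})
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        bad = df[(df["ref_count"] < 0) | (df["alt_count"] < 0)].iloc[0]
        raise ValidationError(
            f"{path}: negative count at {bad['chrom']}:{bad['pos']} cell {bad['cell']}"
        )
    dup = df.duplicated(subset=["chrom", "pos", "cell"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate row for ({bad['chrom']}:{bad['pos']}, {bad['cell']})"
        )

    ref_col = "ref_allele" if "ref_allele" in df.columns else None
    alt_col = "alt_allele" if "alt_allele" in df.columns else None
    site_keys: list[tuple[str, int]] = []
    site_index: dict[tuple[str, int], int] = {}
    sites: list[VariantSite] = []
    for _, row in df.drop_duplicates(subset=["chrom", "pos"]).iterrows():
        key = (row["chrom"], int(row["pos"]))
        site_index[key] = len(site_keys)
        site_keys.append(key)
        sites.append(
            VariantSite(
                chrom=key[0],
                pos=key[1],
                ref_allele=row[ref_col] if ref_col else "A",
                alt_allele=row[alt_col] if alt_col else "G",
            )
        )
    cells = list(dict.fromkeys(df["cell"]))
    cell_index = {c: j for j, c in enumerate(cells)}

    ref = np.zeros((len(sites), len(cells)), dtype=np.int64)
    alt = np.zeros_like(ref)
    i = df.apply(lambda r: site_index[(r["chrom"], int(r["pos"]))], axis=1).to_numpy()
    j = df["cell"].map(cell_index).to_numpy()
    ref[i, j] = df["ref_count"].to_numpy()
    alt[i, j] = df["alt_count"].to_numpy()
    return SiteCellCounts(sites=sites, cells=cells, ref_counts=ref, alt_counts=alt)


def write_counts_long(counts: SiteCellCounts, path: str) -> None:
    df = counts.to_long_dataframe()
    rows, _ = np.nonzero(counts.total_counts())
    df["ref_allele"] = [counts.sites[i].ref_allele for i in rows]
    df["alt_allele"] = [counts.sites[i].alt_allele for i in rows]
    df.to_csv(path, sep="\t", index=False)


def read_counts_triplet(
    sites_path: str, barcodes_path: str, ref_mtx_path: str, alt_mtx_path: str
) -> SiteCellCounts:
    """Read allele counts from sparse-triplet files.

    ``sites_path`` is a TSV with columns chrom, pos, ref_allele, alt_allele;
    ``barcodes_path`` one barcode per line; the two Matrix-Market files hold
    the ref and alt count matrices (sites x cells).
    """
    site_df = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
    sites = [
        VariantSite(
            chrom=r["chrom"],
            pos=int(r["pos"]),
            ref_allele=r["ref_allele"],
            alt_allele=r["alt_allele"],
        )
        for _, r in site_df.iterrows()
    ]
    with open(barcodes_path) as fh:
        cells = [line.strip() for line in fh if line.strip()]
    ref = np.asarray(mmread(ref_mtx_path).todense()).astype(np.int64)
    alt = np.asarray(mmread(alt_mtx_path).todense()).astype(np.int64)
    return SiteCellCounts(sites=sites, cells=cells, ref_counts=ref, alt_counts=alt)


def write_counts_triplet(
    counts: SiteCellCounts,
    sites_path: str,
    barcodes_path: str,
    ref_mtx_path: str,
    alt_mtx_path: str,
) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in counts.sites],
            "pos": [s.pos for s in counts.sites],
            "ref_allele": [s.ref_allele for s in counts.sites],
            "alt_allele": [s.alt_allele for s in counts.sites],
        }
    ).to_csv(sites_path, sep="\t", index=False)
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(counts.cells) + "\n")
    mmwrite(ref_mtx_path, coo_matrix(counts.ref_counts))
    mmwrite(alt_mtx_path, coo_matrix(counts.alt_counts))


# ---------------------------------------------------------------------------
# Trees (Newick)
# ---------------------------------------------------------------------------

def read_tree(path: str) -> dendropy.Tree:
    """Read a single rooted tree with branch lengths from a Newick file."""
    tree = dendropy.Tree.get(
        path=path, schema="newick", rooting="default-rooted", preserve_underscores=True
    )
    _validate_tree(tree)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", rooting="default-rooted", preserve_underscores=True
    )
    _validate_tree(tree)
    return tree


def _validate_tree(tree: dendropy.Tree) -> None:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValidationError("tree has an unlabeled tip")
        if leaf.edge.length is not None and leaf.edge.length < 0:
            raise ValidationError(
                f"negative branch length at tip {leaf.taxon.label!r}"
            )
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise ValidationError("tree has a negative branch length")


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(
        path=path, schema="newick", suppress_rooting=False, unquoted_underscores=True
    )


# ---------------------------------------------------------------------------
# Traits (TSV)
# ---------------------------------------------------------------------------

def read_traits(path: str, column: str | None = None) -> TraitVector:
    """Read a trait table: first column = cell barcode, one column of values.

    If ``column`` is None and the table has exactly two columns, the second
    is used.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cell_col = df.columns[0]
    if column is None:
        if df.shape[1] != 2:
            raise ValidationError(
                f"{path}: has {df.shape[1]} columns; specify which trait column to read"
            )
        column = df.columns[1]
    if df[cell_col].duplicated().any():
        dup = df[cell_col][df[cell_col].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate barcode {dup!r}")
    values = df[column]
    labels: dict[str, float | str] = {}
    for barcode, value in zip(df[cell_col], values):
        if isinstance(value, str):
            labels[barcode] = value
        else:
            labels[barcode] = float(value)
    return TraitVector(labels=labels)


def write_traits(traits: TraitVector, path: str, name: str = "trait") -> None:
    pd.DataFrame(
        {"cell": list(traits.labels), name: list(traits.labels.values())}
    ).to_csv(path, sep="\t", index=False)
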