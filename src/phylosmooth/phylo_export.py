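"""Sequence encoding of genotype calls and a deterministic fallback tree.

Each cell becomes one sequence over the selected sites: Reference maps to the
site's reference base, Alternate to the alternate base, and Heterozygous to a
deterministic surrogate — the first base in A < C < G < T order that is
neither the reference nor the alternate — so the three genotype states map to
three distinct bases at every site and re-runs produce byte-identical files.
MISSING (unsmoothed dropout) encodes as N.

The FASTA/NEXUS output feeds an external Bayesian tree-inference engine
(BEAST2 with an RLN clock, GTR site model and Yule prior is the intended
downstream; a JSON sidecar records those settings).  The neighbor-joining
builder here is a desk-scale fallback so the pipeline and downstream tree
statistics can run end-to-end without MCMC; it is not a substitute for
Bayesian inference on real data.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotype_model import A, H, MISSING, R
from .io_formats import SiteCellCounts, ValidationError, VariantSite

_BASE_ORDER = "ACGT"


@dataclass
class EncodedAlignment:
    """Per-cell sequences over the selected sites (equal length, {A,C,G,T,N})."""

    cells: list[str]
    sequences: list[str]
    sites: list[VariantSite] | None = None

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.sequences):
            raise ValidationError("one sequence per cell required")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("duplicate cell barcodes in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError(f"sequences have unequal lengths: {sorted(lengths)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def heterozygous_surrogate(ref: str, alt: str) -> str:
    """First base in A<C<G<T order that is neither ref nor alt."""
    for base in _BASE_ORDER:
        if base not in (ref, alt):
            return base
    raise ValidationError(f"no surrogate base for ref={ref} alt={alt}")


def encode_alignment(calls: np.ndarray, sites: list[VariantSite], cells: list[str]) -> EncodedAlignment:
    """Encode a calls matrix (sites x cells) as per-cell sequences."""
    calls = np.asarray(calls)
    if calls.shape != (len(sites), len(cells)):
        raise ValidationError("calls shape does not match sites x cells")
    lookup = np.empty((len(sites), 4), dtype="U1")
    for i, site in enumerate(sites):
        lookup[i, R] = site.ref_allele
        lookup[i, A] = site.alt_allele
        lookup[i, H] = heterozygous_surrogate(site.ref_allele, site.alt_allele)
        lookup[i, 3] = "N"
    codes = np.where(calls == MISSING, 3, calls)
    chars = lookup[np.arange(len(sites))[:, None], codes]
    sequences = ["".join(chars[:, j]) for j in range(len(cells))]
    return EncodedAlignment(cells=list(cells), sequences=sequences, sites=list(sites))


def write_fasta(alignment: EncodedAlignment, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=cell, description="")
        for cell, seq in zip(alignment.cells, alignment.sequences)
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> EncodedAlignment:
    records = list(SeqIO.parse(path, "fasta"))
    return EncodedAlignment(
        cells=[r.id for r in records], sequences=[str(r.seq) for r in records]
    )


def write_nexus(alignment: EncodedAlignment, path: str) -> None:
    """NEXUS DATA block with ntax/nchar consistent with the body."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={alignment.n_cells} NCHAR={alignment.n_columns};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=N GAP=-;\n")
        fh.write("    MATRIX\n")
        for cell, seq in zip(alignment.cells, alignment.sequences):
            fh.write(f"    {cell}  {seq}\n")
        fh.write("    ;\nEND;\n")


BEAST_MODEL_DEFAULTS = {
    "clock_model": "relaxed-log-normal",
    "site_model": "GTR",
    "tree_prior": "Yule",
    "chain_length": 100_000_000,
}


def write_beast_sidecar(path: str, **overrides) -> None:
    """Record the intended downstream Bayesian model settings next to the alignment."""
    with open(path, "w") as fh:
        json.dump({**BEAST_MODEL_DEFAULTS, **overrides}, fh, indent=2)
        fh.write("\n")


def hamming_distance_matrix(alignment: EncodedAlignment) -> np.ndarray:
    """Pairwise mismatch fraction over columns where neither sequence is N.

    Pairs with zero comparable columns get NaN (undefined distance).
    """
    base_to_code = {b: k for k, b in enumerate(_BASE_ORDER)}
    n, L = alignment.n_cells, alignment.n_columns
    codes = np.full((n, L), -1, dtype=np.int8)
    for i, seq in enumerate(alignment.sequences):
        for j, ch in enumerate(seq):
            codes[i, j] = base_to_code.get(ch, -1)
    valid = (codes >= 0).astype(np.float32)
    comparable = valid @ valid.T
    matches = np.zeros((n, n), dtype=np.float32)
    for g in range(4):
        onehot = (codes == g).astype(np.float32)
        matches += onehot @ onehot.T
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = 1.0 - matches / comparable
    dist[comparable == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return dist.astype(np.float64)


def nj_tree(distances: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix, midpoint-rooted.

    Negative branch lengths produced by NJ are clamped to zero.  Fallback
    builder for desk-scale runs only.
    """
    distances = np.asarray(distances, dtype=np.float64)
    n = distances.shape[0]
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    if distances.shape != (n, n) or len(labels) != n:
        raise ValidationError("distance matrix and labels are inconsistent")
    if np.isnan(distances).any():
        raise ValidationError("distance matrix contains undefined (NaN) entries")
    if not np.allclose(distances, distances.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, label in enumerate(labels):
        buf.write(label + "," + ",".join(f"{x:.17g}" for x in distances[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    return tree


def root_bipartition_labels(tree: dendropy.Tree) -> dict[str, int]:
    """Assign each tip the index of the root-child subtree containing it."""
    labels: dict[str, int] = {}
    for k, child in enumerate(tree.seed_node.child_nodes()):
        for leaf in child.leaf_iter():
            labels[leaf.taxon.label] = k
    return labels
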