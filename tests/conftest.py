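import random

import dendropy
import numpy as np
import pytest

from phylosmooth import SiteCellCounts, VariantSite


def make_counts(ref, alt, chroms=None, positions=None, cells=None):
    """Build a SiteCellCounts from dense arrays with generated metadata."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    n_sites, n_cells = ref.shape
    sites = [
        VariantSite(
            chrom=chroms[i] if chroms else "1",
            pos=positions[i] if positions else 100 + 10 * i,
            ref_allele="A",
            alt_allele="G",
        )
        for i in range(n_sites)
    ]
    return SiteCellCounts(
        sites=sites,
        cells=cells or [f"c{j}" for j in range(n_cells)],
        ref_counts=ref,
        alt_counts=alt,
    )


def random_yule_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Random birth-only tree with unique tip labels, rooted."""
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    tree.is_rooted = True
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{k}"
    return tree


@pytest.fixture
def counts_2x3():
    return make_counts(ref=[[3, 0, 1], [0, 2, 0]], alt=[[0, 1, 1], [4, 0, 0]])


@pytest.fixture
def tree_3tip():
    import phylosmooth

    return phylosmooth.tree_from_string("((a:1,b:1):1,c:2);")
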