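import itertools
import subprocess

import numpy as np
import pytest

import phylosmooth as ps
from phylosmooth.phylo_stats import (
    blomberg_k,
    cophenetic_distance_matrix,
    lambda_loglik,
    pagels_lambda,
    phylo_vcv,
    ses_mpd,
    simulate_brownian_trait,
)

from conftest import random_yule_tree


def brute_force_vcv(tree):
    """Independent oracle: shared path length from explicit root paths."""
    leaves = list(tree.leaf_node_iter())
    paths = []
    for leaf in leaves:
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append((id(node), node.edge.length or 0.0))
            node = node.parent_node
        paths.append(dict(path))
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                C[i, j] = sum(paths[i].values())
            else:
                shared = set(paths[i]) & set(paths[j])
                C[i, j] = sum(paths[i][k] for k in shared)
    return [l.taxon.label for l in leaves], C


class TestPhyloVcv:
    def test_three_tip_path_arithmetic(self, tree_3tip):
        labels, C = phylo_vcv(tree_3tip)
        idx = {l: i for i, l in enumerate(labels)}
        a, b, c = idx["a"], idx["b"], idx["c"]
        assert C[a, a] == C[b, b] == C[c, c] == 2.0
        assert C[a, b] == 1.0
        assert C[a, c] == 0.0 and C[b, c] == 0.0

    def test_star_tree_covariance_is_diagonal(self):
        tree = ps.tree_from_string("(a:1,b:1,c:1,d:1);")
        _, C = phylo_vcv(tree)
        np.testing.assert_allclose(C, np.eye(4), atol=1e-12)

    def test_matches_brute_force_path_walk_oracle(self):
        tree = random_yule_tree(30, seed=21)
        labels, C = phylo_vcv(tree)
        blabels, bC = brute_force_vcv(tree)
        order = [blabels.index(l) for l in labels]
        np.testing.assert_allclose(C, bC[np.ix_(order, order)], atol=1e-9)


class TestPagelsLambda:
    def test_brownian_trait_recovers_lambda_near_one(self):
        tree = random_yule_tree(80, seed=2)
        estimates = [
            pagels_lambda(tree, simulate_brownian_trait(tree, seed=s)).lambda_hat
            for s in range(15)
        ]
        assert 0.75 <= np.median(estimates) <= 1.15

    def test_permuted_trait_has_no_signal(self):
        tree = random_yule_tree(80, seed=2)
        rng = np.random.default_rng(3)
        trait = simulate_brownian_trait(tree, seed=0)
        labels = list(trait)
        estimates = []
        for _ in range(10):
            values = rng.permutation(list(trait.values()))
            estimates.append(
                pagels_lambda(tree, dict(zip(labels, values))).lambda_hat
            )
        assert np.median(estimates) < 0.1

    def test_optimum_matches_grid_search_oracle(self):
        tree = random_yule_tree(40, seed=7)
        trait = simulate_brownian_trait(tree, seed=5, lam=0.6)
        result = pagels_lambda(tree, trait)
        grid = np.arange(0.0, 1.2001, 0.001)
        lls = [lambda_loglik(tree, trait, lam) for lam in grid]
        assert abs(result.lambda_hat - grid[int(np.argmax(lls))]) < 0.01

    def test_likelihood_ordering_and_p_value_range(self):
        tree = random_yule_tree(50, seed=9)
        res = pagels_lambda(tree, simulate_brownian_trait(tree, seed=1))
        assert res.loglik_at_hat >= res.loglik_at_zero
        assert 0.0 <= res.p_value <= 1.0

    def test_constant_trait_rejected(self, tree_3tip):
        with pytest.raises(ps.ValidationError, match="constant"):
            pagels_lambda(tree_3tip, {"a": 1.0, "b": 1.0, "c": 1.0})

    def test_binary_labels_coded_and_clades_give_signal(self):
        tree = ps.tree_from_string(
            "(((a:0.1,b:0.1):1,(c:0.1,d:0.1):1):1,((e:0.1,f:0.1):1,(g:0.1,h:0.1):1):1);"
        )
        groups = {t: ("x" if t in "abcd" else "y") for t in "abcdefgh"}
        res = pagels_lambda(tree, groups)
        assert res.lambda_hat > 0.8

    def test_matches_phytools_phylosig_oracle(self, tmp_path):
        """Independent cross-check against the reference R implementation."""
        tree = random_yule_tree(40, seed=13)
        trait = simulate_brownian_trait(tree, seed=4, lam=0.7)
        ps.write_tree(tree, str(tmp_path / "tree.nwk"))
        labels = list(trait)
        with open(tmp_path / "trait.tsv", "w") as fh:
            for l in labels:
                fh.write(f"{l}\t{trait[l]}\n")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(phytools))\n'
            f'tree <- read.tree("{tmp_path}/tree.nwk")\n'
            f'tab <- read.table("{tmp_path}/trait.tsv", row.names=1)\n'
            "x <- setNames(tab[[1]], rownames(tab))\n"
            'res <- phylosig(tree, x, method="lambda")\n'
            'cat(res$lambda, "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        r_lambda = float(out.stdout.strip().split()[-1])
        mine = pagels_lambda(tree, trait).lambda_hat
        assert mine == pytest.approx(r_lambda, abs=0.02)


class TestBlombergK:
    def test_brownian_traits_give_k_near_one(self):
        tree = random_yule_tree(80, seed=4)
        ks = [blomberg_k(tree, simulate_brownian_trait(tree, seed=s)) for s in range(30)]
        assert np.mean(ks) == pytest.approx(1.0, abs=0.15)

    def test_permuted_traits_give_k_below_one(self):
        tree = random_yule_tree(80, seed=4)
        trait = simulate_brownian_trait(tree, seed=0)
        rng = np.random.default_rng(8)
        labels = list(trait)
        ks = [
            blomberg_k(tree, dict(zip(labels, rng.permutation(list(trait.values())))))
            for _ in range(10)
        ]
        assert np.mean(ks) < 0.5

    def test_star_tree_iid_traits_give_k_near_one(self):
        n = 60
        newick = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        tree = ps.tree_from_string(newick)
        rng = np.random.default_rng(11)
        ks = [
            blomberg_k(tree, {f"t{i}": x for i, x in enumerate(rng.standard_normal(n))})
            for _ in range(30)
        ]
        assert np.mean(ks) == pytest.approx(1.0, abs=0.1)


class TestSesMpd:
    def test_whole_tree_group_is_null_invariant(self):
        tree = random_yule_tree(20, seed=6)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        res = ses_mpd(tree, {l: "all" for l in labels}, n_perm=99, seed=0)[0]
        assert res.z == 0.0
        assert res.mpd_obs == pytest.approx(res.null_mean, abs=1e-12)

    def test_single_clade_group_is_clustered(self):
        tree = ps.tree_from_string(
            "(((a:0.1,b:0.1):1,(c:0.1,d:0.1):1):1,((e:0.1,f:0.1):1,(g:0.1,h:0.1):1):1);"
        )
        groups = {t: ("in" if t in "abcd" else "out") for t in "abcdefgh"}
        res = {r.group: r for r in ses_mpd(tree, groups, n_perm=499, seed=1)}
        assert res["in"].z < 0

    def test_matches_picante_mpd_oracle(self, tmp_path):
        """Observed MPD cross-checked against the reference R implementation."""
        tree = random_yule_tree(20, seed=15)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        group = {l: ("g1" if i % 3 == 0 else "g2") for i, l in enumerate(labels)}
        ps.write_tree(tree, str(tmp_path / "tree.nwk"))
        g1 = [l for l in labels if group[l] == "g1"]
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(picante))\n"
            f'tree <- read.tree("{tmp_path}/tree.nwk")\n'
            "labs <- tree$tip.label\n"
            f'g1 <- c({", ".join(repr(x) for x in g1)})\n'
            "samp <- matrix(as.numeric(labs %in% g1), nrow=1)\n"
            "colnames(samp) <- labs\n"
            "cat(mpd(samp, cophenetic(tree)), '\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        r_mpd = float(out.stdout.strip().split()[-1])
        res = {r.group: r for r in ses_mpd(tree, group, n_perm=49, seed=0)}
        assert res["g1"].mpd_obs == pytest.approx(r_mpd, rel=1e-6)

    def test_deterministic_under_seed(self):
        tree = random_yule_tree(15, seed=8)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        groups = {l: ("a" if i < 7 else "b") for i, l in enumerate(labels)}
        r1 = ses_mpd(tree, groups, n_perm=199, seed=5)
        r2 = ses_mpd(tree, groups, n_perm=199, seed=5)
        assert [(r.z, r.p_value) for r in r1] == [(r.z, r.p_value) for r in r2]

    def test_singleton_group_rejected(self, tree_3tip):
        with pytest.raises(ps.ValidationError, match="fewer than 2"):
            ses_mpd(tree_3tip, {"a": "x", "b": "y", "c": "y"}, n_perm=99)


class TestAdjustedRandIndex:
    def test_identical_labelings_score_one(self):
        assert ps.adjusted_rand_index(["a", "a", "b"], ["x", "x", "y"]) == 1.0

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(12)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)

        def pair_ari(a, b):
            n = len(a)
            ss = sd = ds = dd = 0
            for i, j in itertools.combinations(range(n), 2):
                sa, sb = a[i] == a[j], b[i] == b[j]
                ss += sa and sb
                sd += sa and not sb
                ds += sb and not sa
                dd += not sa and not sb
            total = ss + sd + ds + dd
            expected = (ss + sd) * (ss + ds) / total
            maximum = ((ss + sd) + (ss + ds)) / 2
            return (ss - expected) / (maximum - expected)

        assert ps.adjusted_rand_index(a, b) == pytest.approx(pair_ari(a, b), abs=1e-12)

    def test_symmetry_and_label_renaming_invariance(self):
        a = ["x", "x", "y", "z", "z"]
        b = ["1", "2", "2", "1", "1"]
        assert ps.adjusted_rand_index(a, b) == ps.adjusted_rand_index(b, a)
        renamed = ["q" + v for v in a]
        assert ps.adjusted_rand_index(a, b) == ps.adjusted_rand_index(renamed, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.adjusted_rand_index(["a"], ["a", "b"])
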