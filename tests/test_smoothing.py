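import numpy as np
import pytest

from phylosmooth import (
    ValidationError,
    build_knn,
    pairwise_similarity,
    sample_profiles,
    smooth_genotypes,
    smooth_probabilities,
)
from phylosmooth.genotype_model import A, H, R
from phylosmooth.smoothing import NeighborMap, SmoothingParams

from conftest import make_counts


def degenerate_probs(calls):
    """(sites, cells, 3) tensor with all mass on the given genotype codes."""
    calls = np.asarray(calls)
    probs = np.zeros(calls.shape + (3,))
    for g in (R, H, A):
        probs[..., g] = calls == g
    return probs


class TestSampling:
    def test_degenerate_distribution_always_drawn(self):
        probs = degenerate_probs([[R, A], [H, R]])
        draws = sample_profiles(probs, 50, seed=1)
        assert np.all(draws == np.array([[R, A], [H, R]]))

    def test_empirical_frequencies_match_probabilities(self):
        probs = np.array([[[0.3, 0.4, 0.3]]])
        draws = sample_profiles(probs, 10_000, seed=2)
        freqs = [np.mean(draws == g) for g in (R, H, A)]
        np.testing.assert_allclose(freqs, [0.3, 0.4, 0.3], atol=0.02)

    def test_same_seed_reproduces_tensor(self):
        probs = np.random.default_rng(3).dirichlet([1, 1, 1], size=(5, 4))
        np.testing.assert_array_equal(
            sample_profiles(probs, 10, seed=42), sample_profiles(probs, 10, seed=42)
        )


class TestSimilarity:
    def test_identical_degenerate_profiles_score_one(self):
        probs = degenerate_probs([[R, R], [A, A], [H, H]])
        sim = pairwise_similarity(probs, SmoothingParams(n_samplings=5, seed=0))
        assert sim[0, 1] == 1.0

    def test_fully_discordant_profiles_score_zero(self):
        probs = degenerate_probs([[R, A], [A, R], [H, R]])
        sim = pairwise_similarity(probs, SmoothingParams(n_samplings=5, seed=0))
        assert sim[0, 1] == 0.0

    def test_uniform_profiles_score_one_third(self):
        probs = np.full((300, 2, 3), 1 / 3)
        sim = pairwise_similarity(probs, SmoothingParams(n_samplings=200, seed=1))
        assert sim[0, 1] == pytest.approx(1 / 3, abs=0.02)

    def test_matrix_properties(self):
        rng = np.random.default_rng(9)
        probs = rng.dirichlet([1, 1, 1], size=(30, 6))
        sim = pairwise_similarity(probs, SmoothingParams(n_samplings=20, seed=9))
        np.testing.assert_array_equal(sim, sim.T)
        np.testing.assert_array_equal(np.diag(sim), np.ones(6))
        assert np.all((sim >= 0) & (sim <= 1))

    def test_zero_sites_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_similarity(np.empty((0, 3, 3)), SmoothingParams(n_samplings=2))


class TestKnn:
    def test_highest_scoring_neighbor_selected(self):
        sim = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.4], [0.2, 0.4, 1.0]])
        nm = build_knn(sim, K=1)
        assert nm.indices[0, 0] == 1
        assert nm.indices[2, 0] == 1

    def test_equal_scores_tie_break_by_ascending_index(self):
        sim = np.full((4, 4), 0.5)
        np.fill_diagonal(sim, 1.0)
        nm = build_knn(sim, K=2)
        np.testing.assert_array_equal(nm.indices[0], [1, 2])
        np.testing.assert_array_equal(nm.indices[3], [0, 1])

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(4)
        sim = rng.random((12, 12))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        nm = build_knn(sim, K=5)
        for i in range(12):
            others = [j for j in range(12) if j != i]
            expected = sorted(others, key=lambda j: (-sim[i, j], j))[:5]
            assert list(nm.indices[i]) == expected
            assert i not in nm.indices[i]
            assert np.all(np.diff(nm.scores[i]) <= 0)

    def test_k_at_least_n_cells_rejected(self):
        with pytest.raises(ValidationError):
            build_knn(np.eye(3), K=3)


class TestSmoothing:
    def test_delta_zero_is_identity(self):
        rng = np.random.default_rng(5)
        probs = rng.dirichlet([1, 1, 1], size=(8, 4))
        nm = build_knn(np.eye(4) + 0.5, K=2)
        np.testing.assert_array_equal(smooth_probabilities(probs, nm, 0.0), probs)

    def test_printed_equation_example(self):
        # cell 0 = (0.6, 0.3, 0.1); its one neighbor holds (0.2, 0.5, 0.3)
        probs = np.array([[[0.6, 0.3, 0.1], [0.2, 0.5, 0.3]]])
        nm = NeighborMap(indices=np.array([[1], [0]]), scores=np.ones((2, 1)))
        out = smooth_probabilities(probs, nm, 0.5)
        np.testing.assert_allclose(out[0, 0], [0.4, 0.4, 0.2], atol=1e-12)

    def test_shared_distribution_is_fixed_point(self):
        probs = np.tile(np.array([0.2, 0.5, 0.3]), (6, 5, 1))
        nm = build_knn(np.full((5, 5), 0.5) + np.eye(5) * 0.5, K=3)
        for delta in (0.0, 0.4, 1.0):
            np.testing.assert_allclose(
                smooth_probabilities(probs, nm, delta), probs, atol=1e-12
            )

    def test_default_delta_equals_plain_average_of_cell_and_neighbors(self):
        rng = np.random.default_rng(6)
        probs = rng.dirichlet([1, 1, 1], size=(10, 7))
        K = 3
        sim = rng.random((7, 7))
        sim = (sim + sim.T) / 2
        nm = build_knn(sim, K=K)
        delta = K / (K + 1)
        out = smooth_probabilities(probs, nm, delta)
        for j in range(7):
            group = np.concatenate([[j], nm.indices[j]])
            np.testing.assert_allclose(
                out[:, j, :], probs[:, group, :].mean(axis=1), atol=1e-12
            )

    def test_smoothing_is_convex_combination_on_simplex(self):
        rng = np.random.default_rng(7)
        probs = rng.dirichlet([1, 1, 1], size=(10, 7))
        sim = rng.random((7, 7))
        nm = build_knn((sim + sim.T) / 2, K=3)
        out = smooth_probabilities(probs, nm, 0.7)
        np.testing.assert_allclose(out.sum(axis=-1), 1.0, atol=1e-9)
        nbr_mean = probs[:, nm.indices, :].mean(axis=2)
        lo = np.minimum(probs, nbr_mean)
        hi = np.maximum(probs, nbr_mean)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_invalid_delta_rejected(self):
        probs = np.full((2, 3, 3), 1 / 3)
        nm = build_knn(np.eye(3), K=1)
        with pytest.raises(ValidationError):
            smooth_probabilities(probs, nm, 1.5)


class TestEndToEnd:
    def test_single_cell_input_rejected(self):
        counts = make_counts(ref=[[3], [1]], alt=[[0], [2]])
        with pytest.raises(ValidationError):
            smooth_genotypes(counts)

    def test_fixed_seed_is_bit_identical(self):
        counts = make_counts(
            ref=np.random.default_rng(0).integers(0, 4, (20, 8)),
            alt=np.random.default_rng(1).integers(0, 4, (20, 8)),
        )
        p1, c1, n1 = smooth_genotypes(counts, params=SmoothingParams(K=3, n_samplings=20, seed=13))
        p2, c2, n2 = smooth_genotypes(counts, params=SmoothingParams(K=3, n_samplings=20, seed=13))
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(n1.indices, n2.indices)

    def test_no_missing_calls_after_smoothing(self):
        counts = make_counts(ref=[[0, 2], [1, 0]], alt=[[0, 0], [0, 3]])
        _, calls, _ = smooth_genotypes(counts, params=SmoothingParams(K=1, n_samplings=5, seed=0))
        assert np.all(np.isin(calls, [R, H, A]))

    def test_smoothing_improves_clade_recovery_on_synthetic_data(self):
        from phylosmooth import SimConfig, call_unsmoothed, simulate_dataset
        from phylosmooth.synthetic_sim import genotype_clustering_ari

        counts, truth = simulate_dataset(SimConfig(seed=5))
        before = call_unsmoothed(counts)
        _, after, _ = smooth_genotypes(counts, params=SmoothingParams(seed=5))
        ari_before = genotype_clustering_ari(before, truth.clade_labels, seed=5)
        ari_after = genotype_clustering_ari(after, truth.clade_labels, seed=5)
        assert ari_after > ari_before
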