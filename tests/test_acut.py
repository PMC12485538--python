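import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from gule.acut import acut_objective, rescale_graph, spectral_project
from gule.cpf import epm_solve
from gule.evaluation import clustering_accuracy
from gule.exceptions import DataError
from gule.graph import CredibilityGraph

from conftest import block_graph


def _graph_from_dense(A, beta=0.5):
    G = CredibilityGraph(A=sp.csr_matrix(np.asarray(A, float)), alpha=np.nan,
                         layer=1)
    G.s, G.beta = 1.0 - beta, beta
    return G


def brute_force_acut(G, K, beta):
    """Exhaustive maximizer of the discrete objective (oracle)."""
    best, bestlab = -np.inf, None
    for lab in itertools.product(range(1, K + 1), repeat=G.n):
        if len(set(lab)) < K:
            continue
        sc = acut_objective(G, np.array(lab), beta)
        if sc > best:
            best, bestlab = sc, np.array(lab)
    return best, bestlab


class TestRescaleGraph:
    def test_beta_zero_is_identity_on_A(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0, 1, (5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        G = _graph_from_dense(A, beta=0.0)
        assert np.allclose(rescale_graph(G).toarray(), A)

    def test_beta_one_is_ncut_normalization(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, (6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        G = _graph_from_dense(A, beta=1.0)
        d = A.sum(axis=1)
        expected = A / np.sqrt(np.outer(d, d))
        assert np.allclose(rescale_graph(G).toarray(), expected)

    def test_two_by_two_arithmetic(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        G = _graph_from_dense(A, beta=1.0)
        assert np.allclose(rescale_graph(G).toarray(), A / 1.5)


class TestSpectralProject:
    def test_two_clique_block_indicators(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        G = _graph_from_dense(A, beta=0.5)
        proj = spectral_project(G, 2)
        # each column is supported on exactly one clique
        for k in range(2):
            support = np.abs(proj.U[:, k]) > 1e-8
            assert support[:3].all() ^ support[3:].all()
        assert proj.gap > 0

    def test_matches_full_dense_eigendecomposition(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0.1, 1, (7, 7))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        G = _graph_from_dense(A, beta=0.7)
        proj = spectral_project(G, 6)  # K = n - 1
        M = rescale_graph(G).toarray()
        w = np.sort(np.linalg.eigvalsh(M))[::-1]
        assert np.allclose(proj.eigvals, w[:7], atol=1e-10)
        # orthonormality
        assert np.allclose(proj.U.T @ proj.U, np.eye(6), atol=1e-8)

    def test_disconnected_components_give_perron_eigenvalues(self):
        rng = np.random.default_rng(3)
        G, labels = block_graph([3, 4, 3], rng)  # zero off-block mass
        proj = spectral_project(G, 3)
        M = rescale_graph(G).toarray()
        per_comp = []
        for k in (1, 2, 3):
            idx = np.where(labels == k)[0]
            per_comp.append(np.linalg.eigvalsh(M[np.ix_(idx, idx)])[-1])
        assert np.allclose(np.sort(proj.eigvals[:3]), np.sort(per_comp),
                           atol=1e-10)
        # one nonnegative Perron vector per component
        for k in range(3):
            col = proj.U[:, k]
            assert np.all(col >= 0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        G, _ = block_graph([4, 4], rng, off_scale=0.01)
        U1 = spectral_project(G, 2).U
        U2 = spectral_project(G, 2).U
        assert np.array_equal(U1, U2)  # bitwise identical

    def test_K_bounds_checked(self):
        G = _graph_from_dense(np.eye(3) + 0.1, beta=0.5)
        with pytest.raises(DataError):
            spectral_project(G, 3)


class TestAcutObjective:
    def test_single_class_beta_zero(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, (5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        G = _graph_from_dense(A)
        assert acut_objective(G, np.ones(5, int), 0.0) == pytest.approx(
            A.sum() / 5)

    def test_correct_split_beats_merged_labeling(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1.0
        A[3:, 3:] = 1.0
        G = _graph_from_dense(A)
        right = np.array([1, 1, 1, 2, 2, 2])
        wrong = np.array([1, 1, 2, 2, 2, 1])
        assert acut_objective(G, right, 0.5) > acut_objective(G, wrong, 0.5)

    def test_ideal_block_graph_scores_K_at_beta_one(self):
        A = np.zeros((7, 7))
        A[:3, :3] = 0.8
        A[3:, 3:] = 0.3
        np.fill_diagonal(A, 1.0)
        G = _graph_from_dense(A)
        labels = np.array([1] * 3 + [2] * 4)
        assert acut_objective(G, labels, 1.0) == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        G = _graph_from_dense(np.eye(4) + 0.1)
        with pytest.raises(DataError):
            acut_objective(G, np.array([1, 1]), 0.5)


class TestRelaxationAndOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_continuous_optimum_dominates_discrete(self, seed):
        rng = np.random.default_rng(seed)
        G, labels = block_graph([3, 3, 3], rng, off_scale=0.03)
        K = 3
        M = rescale_graph(G).toarray()
        proj = spectral_project(G, K)
        cont = np.trace(proj.U.T @ M @ proj.U)
        for _ in range(20):
            lab = rng.integers(1, K + 1, size=G.n)
            if len(np.unique(lab)) < 1:
                continue
            assert cont >= acut_objective(G, lab, G.beta) - 1e-9

    @pytest.mark.parametrize("K,seed", [(2, 0), (2, 1), (3, 2), (3, 3)])
    def test_matches_brute_force_on_separated_blocks(self, K, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 4, size=K)
        G, truth = block_graph(sizes, rng, off_scale=0.02)
        proj = spectral_project(G, K)
        lab = epm_solve(proj.U, K, seed=0).labels
        best, bestlab = brute_force_acut(G, K, G.beta)
        ours = acut_objective(G, lab, G.beta)
        assert (clustering_accuracy(lab, bestlab) == 1.0
                or ours == pytest.approx(best, abs=1e-9))
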