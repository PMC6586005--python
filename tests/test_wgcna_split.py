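"""Biweight midcorrelation, sigmoid adjacency, TOM, and the network split."""

import numpy as np
import pytest

from clintpipe.wgcna_split import (
    NetworkConfig,
    bicor_matrix,
    cluster_and_cut,
    sigmoid_adjacency,
    split_compounds,
    tom_similarity,
)


def bicor_reference(x: np.ndarray, y: np.ndarray) -> float:
    """Direct per-pair evaluation of the biweight midcorrelation formula."""

    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w

    xt, yt = weighted(x), weighted(y)
    if xt is None or yt is None:
        xc, yc = x - x.mean(), y - y.mean()
        return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(xt @ yt / np.sqrt((xt @ xt) * (yt @ yt)))


def tom_reference(A: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological overlap formula."""
    n = A.shape[0]
    T = np.eye(n)
    k = np.array([sum(A[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestBicor:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        S = bicor_matrix(np.vstack([x, x, rng.normal(size=12)]))
        assert S[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        S = bicor_matrix(np.vstack([x, -x, rng.normal(size=12)]))
        assert S[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula_with_outlier(self):
        """Fixed 10-vectors, one containing a gross outlier."""
        x = np.array([0.1, 0.4, -0.3, 0.8, -0.2, 0.05, 0.6, -0.7, 0.3, 25.0])
        y = np.array([0.2, 0.5, -0.1, 0.9, -0.4, 0.1, 0.55, -0.6, 0.2, 0.3])
        z = np.arange(10.0)
        S = bicor_matrix(np.vstack([x, y, z]))
        assert S[0, 1] == pytest.approx(bicor_reference(x, y), abs=1e-12)
        assert S[0, 2] == pytest.approx(bicor_reference(x, z), abs=1e-12)

    def test_zero_mad_row_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 5.0])  # MAD 0
        y = np.arange(10.0)
        S = bicor_matrix(np.vstack([x, y, y[::-1]]))
        assert S[0, 1] == pytest.approx(bicor_reference(x, y), abs=1e-12)

    def test_requires_three_rows(self):
        with pytest.raises(ValueError, match="at least 3"):
            bicor_matrix(np.ones((2, 5)))


class TestSigmoidAdjacency:
    def test_midpoint_maps_to_half(self):
        S = np.full((3, 3), 0.9)
        A = sigmoid_adjacency(S, NetworkConfig(alpha=25, tau=0.9))
        assert A[0, 1] == pytest.approx(0.5)

    def test_perfect_similarity_value(self):
        S = np.ones((3, 3))
        A = sigmoid_adjacency(S, NetworkConfig(alpha=25, tau=0.9))
        assert A[0, 1] == pytest.approx(1.0 / (1.0 + np.exp(-2.5)), rel=1e-12)

    def test_strong_negative_similarity_vanishes(self):
        S = np.full((3, 3), -1.0)
        A = sigmoid_adjacency(S, NetworkConfig(alpha=25, tau=0.9))
        assert A[0, 1] < 1e-20


class TestTOM:
    def test_hand_computed_three_node_example(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(A)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert T[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_no_edges_gives_zero_overlap(self):
        T = tom_similarity(np.eye(4))
        assert np.allclose(T - np.eye(4), 0.0)

    def test_complete_graph_full_overlap(self):
        T = tom_similarity(np.ones((5, 5)))
        assert np.allclose(T, 1.0)

    def test_matches_triple_loop_on_random_matrices(self):
        """Vectorized TOM equals brute force on random 8-node adjacencies."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = rng.uniform(0, 1, size=(8, 8))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom_similarity(A)
            assert np.allclose(T, tom_reference(A), atol=1e-12)
            assert np.all((0 <= T) & (T <= 1)) and np.allclose(T, T.T)
            assert np.allclose(np.diag(T), 1.0)

    def test_rejects_asymmetric_input(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(A)


def planted_blobs(n1: int, n2: int, seed: int = 0, sep: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    b1, b2 = rng.normal(size=30), rng.normal(size=30)
    X = np.vstack(
        [b1 + sep * rng.normal(size=30) for _ in range(n1)]
        + [b2 + sep * rng.normal(size=30) for _ in range(n2)]
    )
    labels = np.array([0] * n1 + [1] * n2)
    return X, labels


class TestClusterAndCut:
    def test_planted_partition_recovered_exactly(self):
        """ARI = 1 on two well-separated blobs (between-blob bicor ~ 0)."""
        from sklearn.metrics import adjusted_rand_score

        X, truth = planted_blobs(40, 10)
        res = split_compounds(X, [f"c{i}" for i in range(50)])
        assert adjusted_rand_score(truth, res.cluster_labels) == 1.0

    def test_train_fraction_matches_planted_majority(self):
        X, _ = planted_blobs(40, 10)
        res = split_compounds(X, [f"c{i}" for i in range(50)])
        assert len(res.train_ids) == 40 and len(res.test_ids) == 10

    def test_identical_compounds_single_cluster_empty_test(self):
        X = np.tile(np.arange(8.0), (3, 1))
        with pytest.warns(UserWarning, match="test set is empty"):
            res = split_compounds(X, ["a", "b", "c"])
        assert res.test_ids == [] and set(res.train_ids) == {"a", "b", "c"}

    def test_partition_is_disjoint_and_exhaustive(self):
        X, _ = planted_blobs(25, 12, seed=3)
        ids = [f"c{i}" for i in range(37)]
        res = split_compounds(X, ids)
        assert sorted(res.train_ids + res.test_ids) == sorted(ids)
        assert not (set(res.train_ids) & set(res.test_ids))
        sizes = res.cluster_sizes
        proper = {k: v for k, v in sizes.items() if k != 0}
        assert len(res.train_ids) == max(proper.values())

    def test_deterministic_without_rng(self):
        X, _ = planted_blobs(20, 10, seed=5)
        ids = [f"c{i}" for i in range(30)]
        r1 = split_compounds(X, ids)
        r2 = split_compounds(X, ids)
        assert np.array_equal(r1.cluster_labels, r2.cluster_labels)
        assert r1.train_ids == r2.train_ids

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(tau=1.5)
        with pytest.raises(ValueError):
            NetworkConfig(min_cluster_size=1)
        with pytest.raises(ValueError):
            NetworkConfig(deep_split=5)
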