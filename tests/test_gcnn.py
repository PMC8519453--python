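"""Graph operator, Chebyshev filtering, training and metrics."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from embed2net import (GCNNArchitecture, TrainConfig, build_graph_operator,
                       chebyshev_conv, compute_metrics, train_gcnn,
                       watts_strogatz_prior)
from embed2net.coarsening import rescaled_laplacian
from embed2net.errors import ParameterError, StructureError, TrainingError
from embed2net.expression import GraphAlignedDataset
from embed2net.gcnn import GraphConvNet, prepare_features
from embed2net.networks import SimilarityNetwork


def line_network(n):
    g = nx.Graph()
    names = [f"v{i:02d}" for i in range(n)]
    for a, b in zip(names, names[1:]):
        g.add_edge(a, b, weight=1.0)
    return SimilarityNetwork(g)


class TestGraphOperator:
    def test_two_vertex_laplacian_eigenvalues(self):
        net = line_network(2)
        A = sp.csr_matrix(net.adjacency())
        n = A.shape[0]
        d = np.asarray(A.sum(axis=1)).ravel()
        L = np.eye(n) - A.toarray() / np.sqrt(np.outer(d, d))
        assert sorted(np.round(np.linalg.eigvalsh(L), 9)) == [0.0, 2.0]

    def test_each_level_halves(self):
        op = build_graph_operator(watts_strogatz_prior(30, k=4, seed=1))
        sizes = [len(p) for p in op.perms]
        assert sizes[0] == 2 * sizes[1] == 4 * sizes[2]

    def test_normalized_laplacian_spectrum_in_range(self):
        net = watts_strogatz_prior(30, k=4, seed=2)
        A = sp.csr_matrix(net.adjacency())
        d = np.asarray(A.sum(axis=1)).ravel()
        L = np.eye(30) - A.toarray() / np.sqrt(np.outer(d, d))
        eig = np.linalg.eigvalsh(L)
        assert eig.min() >= -1e-9 and eig.max() <= 2 + 1e-9
        # and the rescaled operator has spectrum within [-1, 1]
        Lr = rescaled_laplacian(A).toarray()
        eig_r = np.linalg.eigvalsh(Lr)
        assert eig_r.min() >= -1 - 1e-6 and eig_r.max() <= 1 + 1e-6

    def test_disconnected_graph_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("c", "d", weight=1.0)
        with pytest.raises(StructureError, match="main"):
            build_graph_operator(SimilarityNetwork(g))


class TestChebyshevConv:
    def test_order_one_is_pointwise_scaling(self):
        net = line_network(5)
        op = build_graph_operator(net)
        x = np.arange(len(op.perms[0]), dtype=float)
        out = chebyshev_conv(x, op, K=1, weights=np.array([2.5]))
        assert np.allclose(out, 2.5 * x)

    def test_order_two_matches_dense(self):
        net = line_network(5)
        L = rescaled_laplacian(sp.csr_matrix(net.adjacency()))
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        theta = np.array([0.3, -1.2])
        out = chebyshev_conv(x, L, K=2, weights=theta)
        dense = theta[0] * x + theta[1] * (L.toarray() @ x)
        assert np.allclose(out, dense, atol=1e-12)

    @pytest.mark.parametrize("n,K", [(5, 3), (12, 5), (30, 7)])
    def test_matches_dense_polynomial_evaluation(self, n, K):
        rng = np.random.default_rng(n * K)
        g = nx.connected_watts_strogatz_graph(n, min(4, n - 1), 0.3,
                                              seed=int(n + K))
        A = nx.to_numpy_array(g)
        L = rescaled_laplacian(sp.csr_matrix(A))
        Ld = L.toarray()
        x = rng.normal(size=n)
        theta = rng.normal(size=K)
        # dense oracle: explicit Chebyshev polynomial matrices
        T = [np.eye(n), Ld]
        for _ in range(2, K):
            T.append(2 * Ld @ T[-1] - T[-2])
        expected = sum(theta[k] * (T[k] @ x) for k in range(K))
        out = chebyshev_conv(x, L, K=K, weights=theta)
        assert np.allclose(out, expected, atol=1e-9)

    def test_locality_k_minus_one_hops(self):
        # on a path graph, perturbing one vertex moves outputs only within
        # K-1 hops
        n, K = 15, 4
        net = line_network(n)
        L = rescaled_laplacian(sp.csr_matrix(net.adjacency()))
        theta = np.ones(K)
        x = np.zeros(n)
        base = chebyshev_conv(x, L, K=K, weights=theta)
        x2 = x.copy()
        src = 7
        x2[src] = 1.0
        moved = np.nonzero(
            np.abs(chebyshev_conv(x2, L, K=K, weights=theta) - base)
            > 1e-12)[0]
        assert np.all(np.abs(moved - src) <= K - 1)

    def test_weight_order_mismatch(self):
        net = line_network(4)
        op = build_graph_operator(net)
        with pytest.raises(ParameterError):
            chebyshev_conv(np.zeros(len(op.perms[0])), op, K=3,
                           weights=np.ones(2))


def small_dataset(n_samples=40, n_vertices=24, separable=True, seed=0):
    rng = np.random.default_rng(seed)
    net = watts_strogatz_prior(n_vertices, k=4, seed=seed)
    y = np.array([0, 1] * (n_samples // 2))
    X = rng.normal(size=(n_samples, n_vertices))
    if separable:
        X[y == 1, :6] += 3.0
    return GraphAlignedDataset(X, y, net.vertices,
                               [f"s{i}" for i in range(n_samples)], net)


class TestTraining:
    def test_overfits_separable_data(self):
        ds = small_dataset()
        from embed2net import build_graph_operator
        op = build_graph_operator(ds.graph)
        arch = GCNNArchitecture(filters=(8, 8), cheb_order=3, fc=(32, 16))
        model = train_gcnn(ds, op, arch,
                           TrainConfig(epochs=60, seed=0, dropout=0.0,
                                       batch_size=8))
        X = prepare_features(ds, op)
        pred = model.predict_proba(X)[:, 1] >= 0.5
        assert (pred == ds.y).mean() == 1.0

    def test_deterministic_given_seed(self):
        ds = small_dataset()
        from embed2net import build_graph_operator
        op = build_graph_operator(ds.graph)
        arch = GCNNArchitecture(filters=(4, 4), cheb_order=3, fc=(16, 8))
        cfg = TrainConfig(epochs=5, seed=7, batch_size=8)
        a = train_gcnn(ds, op, arch, cfg)
        b = train_gcnn(ds, op, arch, cfg)
        assert a.loss_history[-1] == pytest.approx(b.loss_history[-1],
                                                   abs=1e-6)

    def test_single_class_rejected(self):
        ds = small_dataset()
        ds.y[:] = 1
        from embed2net import build_graph_operator
        op = build_graph_operator(ds.graph)
        with pytest.raises(TrainingError):
            train_gcnn(ds, op, GCNNArchitecture(filters=(4, 4),
                                                cheb_order=2, fc=(8, 4)),
                       TrainConfig(epochs=1, seed=0))

    def test_divergent_training_reported_not_hidden(self):
        # an absurd learning rate must be reported as non-convergence,
        # not silently averaged into results
        ds = small_dataset()
        from embed2net import build_graph_operator
        op = build_graph_operator(ds.graph)
        arch = GCNNArchitecture(filters=(4, 4), cheb_order=2, fc=(8, 4))
        model = train_gcnn(ds, op, arch,
                           TrainConfig(epochs=3, seed=0, batch_size=8,
                                       learning_rate=1e5))
        assert model.converged is False

    def test_architecture_echo(self):
        arch = GCNNArchitecture()
        assert arch.filters == (32, 32)
        assert arch.pool == (2, 2)
        assert arch.fc == (512, 128)
        assert arch.n_classes == 2

    def test_padding_vertices_never_influence_real_outputs(self):
        ds = small_dataset(n_samples=10)
        from embed2net import build_graph_operator
        op = build_graph_operator(ds.graph)
        n_fake0 = int((~op.masks[0]).sum())
        assert n_fake0 > 0  # the hierarchy does pad this graph
        model = GraphConvNet(op, GCNNArchitecture(filters=(4, 4),
                                                  cheb_order=3, fc=(8, 4)),
                             seed=1)
        X = prepare_features(ds, op)
        base = model.predict_proba(X)
        X_perturbed = X.copy()
        X_perturbed[:, ~op.masks[0]] = 99.0
        assert np.allclose(model.predict_proba(X_perturbed), base,
                           atol=1e-6)


class TestMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m == {"auc": 100.0, "accuracy": 100.0, "f1_weighted": 100.0}

    def test_hand_computed_case(self):
        # brute force over positive-negative pairs: 3 of 4 ordered right
        m = compute_metrics([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert m["auc"] == pytest.approx(75.0)
        assert m["accuracy"] == pytest.approx(75.0)
        assert m["f1_weighted"] == pytest.approx(73.33, abs=0.01)

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 2)  # ties likely
            wins = halves = total = 0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    total += 1
                    if s[i] > s[j]:
                        wins += 1
                    elif s[i] == s[j]:
                        halves += 1
            expected = 100.0 * (wins + 0.5 * halves) / total
            assert compute_metrics(y, s)["auc"] == pytest.approx(expected)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, size=10_000)
        s = rng.random(10_000)
        assert compute_metrics(y, s)["auc"] == pytest.approx(50.0, abs=2.0)

    def test_single_class_auc_undefined(self):
        with pytest.raises(ParameterError):
            compute_metrics([1, 1, 1], [0.1, 0.2, 0.3])

    def test_sem_matches_direct_recomputation(self):
        import pandas as pd
        from embed2net.gcnn import EvaluationResult
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({"auc": rng.uniform(60, 90, 10),
                              "accuracy": rng.uniform(60, 90, 10),
                              "f1_weighted": rng.uniform(60, 90, 10)})
        result = EvaluationResult(frame)
        for col in frame:
            manual = frame[col].std(ddof=1) / np.sqrt(len(frame))
            assert result.sem[col] == pytest.approx(manual, abs=1e-12)
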