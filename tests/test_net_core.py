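"""Network container, validation, I/O round trips and the synthetic
generator."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from strengthnulls import (
    WeightedNetwork,
    degrees,
    generate_synthetic,
    load_ensemble,
    load_network,
    save_ensemble,
    save_network,
    strengths,
)
from strengthnulls.net_core import lognormal_mean

from conftest import make_random_net, sorted_weights


class TestValidation:
    def test_identity_roundtrip_matrix(self):
        A = np.array([[0, 2, 3], [2, 0, 0], [3, 0, 0]], dtype=float)
        net = WeightedNetwork(A)
        assert net.n_nodes == 3
        assert net.n_edges == 2

    @pytest.mark.parametrize(
        "bad, kwargs, msg",
        [
            (np.array([[0.0, 1], [1, 0], [0, 0]]), {}, "square"),
            (np.array([[1.0, 1], [1, 0]]), {}, "diagonal"),
            (np.array([[0.0, 1], [2, 0]]), {}, "symmetric"),
            (np.array([[0.0, -1], [-1, 0]]), {}, "negative"),
            (np.array([[0.0, np.nan], [np.nan, 0]]), {}, "NaN"),
            (np.zeros((3, 3)), {}, "no edges"),
        ],
    )
    def test_invalid_matrices_rejected(self, bad, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            WeightedNetwork(bad, **kwargs)

    def test_directed_asymmetry_allowed(self):
        A = np.array([[0.0, 5], [0, 0]])
        net = WeightedNetwork(A, directed=True)
        assert net.n_edges == 1


class TestIO:
    @pytest.mark.parametrize("fmt", ["dense", "edgelist"])
    @pytest.mark.parametrize(
        "directed, signed", [(False, False), (True, False), (False, True)]
    )
    def test_roundtrip_lossless(self, tmp_path, fmt, directed, signed):
        net = make_random_net(3, n=10, directed=directed, signed=signed,
                              connected=not signed)
        p = tmp_path / "net.txt"
        save_network(net, p, format=fmt)
        back = load_network(p, format=fmt, directed=directed, signed=signed)
        assert np.array_equal(back.weights, net.weights)

    def test_edgelist_symmetrized(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("0\t1\t2.0\n1\t2\t3.0\n")
        net = load_network(p, format="edgelist")
        assert net.weights[0, 1] == net.weights[1, 0] == 2.0
        assert net.weights[1, 2] == net.weights[2, 1] == 3.0

    def test_duplicate_edge_error(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("0\t1\t2.0\n1\t0\t3.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_network(p, format="edgelist")

    def test_dense_nan_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("0,nan\nnan,0\n")
        with pytest.raises(ValueError, match="NaN"):
            load_network(p, format="dense")

    def test_labels_roundtrip(self, tmp_path):
        A = np.array([[0.0, 1.5], [1.5, 0]])
        net = WeightedNetwork(A, labels=["hippocampus", "thalamus"])
        p = tmp_path / "lab.csv"
        save_network(net, p)
        back = load_network(p)
        assert back.labels == ["hippocampus", "thalamus"]
        assert np.array_equal(back.weights, net.weights)

    def test_ensemble_manifest(self, tmp_path):
        nets = [make_random_net(s, n=8) for s in range(5)]
        save_ensemble(nets, tmp_path / "ens", "ms", {"spe": 10}, seeds=range(5))
        back, manifest = load_ensemble(tmp_path / "ens")
        assert len(back) == 5
        assert len(manifest["files"]) == 5
        assert manifest["algorithm"] == "ms"
        for a, b in zip(nets, back):
            assert np.array_equal(a.weights, b.weights)


class TestStrengthsDegrees:
    def test_triangle_strengths(self, triangle):
        assert np.array_equal(strengths(triangle).s, [2, 2, 2])
        assert np.array_equal(degrees(triangle).k, [2, 2, 2])

    def test_directed_two_node(self):
        A = np.array([[0.0, 5], [0, 0]])
        s = strengths(WeightedNetwork(A, directed=True))
        assert np.array_equal(s.s_out, [5, 0])
        assert np.array_equal(s.s_in, [0, 5])

    def test_signed_edge(self):
        A = np.array([[0.0, -2], [-2, 0]])
        s = strengths(WeightedNetwork(A, signed=True))
        assert np.array_equal(s.s_pos, [0, 0])
        assert np.array_equal(s.s_neg, [2, 2])

    def test_star_degrees(self, star4):
        assert np.array_equal(degrees(star4).k, [3, 1, 1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_agreement(self, seed):
        """strengths/degrees match an explicit double loop on random nets."""
        net = make_random_net(seed, n=8)
        A = net.weights
        s = strengths(net).s
        k = degrees(net).k
        for i in range(8):
            assert s[i] == pytest.approx(sum(A[i, j] for j in range(8)), abs=1e-12)
            assert k[i] == sum(1 for j in range(8) if A[i, j] != 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_signed_degree_partition(self, seed):
        net = make_random_net(seed, n=10, signed=True, connected=False)
        d = degrees(net)
        binary = (net.weights != 0).sum(axis=1)
        assert np.array_equal(d.k_pos + d.k_neg, binary)

    def test_undirected_strength_sum_identity(self, und_fixture):
        s = strengths(und_fixture).s
        total = sorted_weights(und_fixture).sum()
        assert s.sum() == pytest.approx(2 * total)

    def test_directed_inout_sum_identity(self, dir_fixture):
        s = strengths(dir_fixture)
        assert s.s_in.sum() == pytest.approx(s.s_out.sum())


class TestGenerator:
    def test_determinism(self):
        a = generate_synthetic(n=50, density=0.2, seed=7)
        b = generate_synthetic(n=50, density=0.2, seed=7)
        assert np.array_equal(a.weights, b.weights)

    def test_complete_graph(self):
        net = generate_synthetic(n=10, density=1.0, seed=0)
        assert np.array_equal(degrees(net).k, np.full(10, 9))

    def test_density_within_one_edge(self):
        for d in (0.05, 0.2, 0.5):
            net = generate_synthetic(n=60, density=d, seed=1)
            target = round(d * 60 * 59 / 2)
            assert abs(net.n_edges - target) <= 1

    @pytest.mark.parametrize("directed", [False, True])
    def test_connected(self, directed):
        net = generate_synthetic(n=200, density=0.05, seed=3,
                                 directed=directed, connected=True)
        ncomp, _ = connected_components(
            csr_matrix(net.weights != 0), directed=directed,
            connection="strong" if directed else "weak")
        assert ncomp == 1

    def test_lognormal_mean_converges(self):
        """Empirical log-normal weight mean within 3 SE of the analytic mean
        at ~10^4 edges."""
        net = generate_synthetic(n=150, density=0.9, seed=9,
                                 weight_dist="lognormal")
        w = sorted_weights(net)
        assert w.size > 9000
        mu = lognormal_mean(0.0, 1.0)
        se = w.std(ddof=1) / np.sqrt(w.size)
        assert abs(w.mean() - mu) < 3 * se

    def test_infeasible_density_error(self):
        with pytest.raises(ValueError):
            generate_synthetic(n=50, density=0.01, seed=0, connected=True)
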