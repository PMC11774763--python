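"""Shared fixtures and brute-force oracles."""

import numpy as np
import pytest

from strengthnulls import WeightedNetwork, generate_synthetic


# ---------------------------------------------------------------------------
# Small hand-built networks
# ---------------------------------------------------------------------------


@pytest.fixture
def triangle():
    A = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return WeightedNetwork(A)


@pytest.fixture
def path3():
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return WeightedNetwork(A)


@pytest.fixture
def star4():
    """Center node 0 with 3 unit-weight leaves."""
    A = np.zeros((4, 4))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    return WeightedNetwork(A)


def make_random_net(seed, n=8, density=0.5, directed=False, signed=False,
                    connected=True):
    return generate_synthetic(
        n=n, density=density, weight_dist="lognormal", directed=directed,
        signed=signed, connected=connected, seed=seed,
    )


@pytest.fixture
def und_fixture():
    return generate_synthetic(n=50, density=0.2, seed=7, connected=True)


@pytest.fixture
def dir_fixture():
    return generate_synthetic(n=40, density=0.15, seed=11, directed=True,
                              connected=True)


@pytest.fixture
def signed_fixture():
    return generate_synthetic(n=40, density=0.2, seed=5, signed=True)


# ---------------------------------------------------------------------------
# Conservation helpers
# ---------------------------------------------------------------------------


def sorted_weights(net: WeightedNetwork) -> np.ndarray:
    """Sorted multiset of logical edge weights (bit-exact comparison)."""
    if net.directed:
        w = net.weights[net.weights != 0]
    else:
        up = net.weights[np.triu_indices(net.n_nodes, 1)]
        w = up[up != 0]
    return np.sort(w)


def row_multisets_equal(a: WeightedNetwork, b: WeightedNetwork) -> bool:
    """Per-row weight multisets bit-equal (out-strength conservation at the
    multiset level, immune to float summation order)."""
    A, B = a.weights, b.weights
    return all(
        np.array_equal(np.sort(A[i][A[i] != 0]), np.sort(B[i][B[i] != 0]))
        for i in range(A.shape[0])
    )


# ---------------------------------------------------------------------------
# Brute-force metric oracles (explicit loops, independent of the library)
# ---------------------------------------------------------------------------


def brute_strengths_und(A):
    n = A.shape[0]
    s = np.zeros(n)
    for i in range(n):
        for j in range(n):
            s[i] += A[i, j]
    return s


def brute_clustering(A):
    """Triangle-intensity clustering by exhaustive triple enumeration."""
    n = A.shape[0]
    W = A / A.max()
    C = np.zeros(n)
    for u in range(n):
        k = int(np.sum(A[u] != 0))
        if k < 2:
            continue
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j or i == u or j == u:
                    continue
                if W[u, i] and W[i, j] and W[j, u]:
                    total += (W[u, i] * W[i, j] * W[j, u]) ** (1 / 3)
        C[u] = total / (k * (k - 1))
    return C


def brute_cpl(A, mapping="inverse"):
    """Floyd–Warshall characteristic path length."""
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if A[i, j] != 0:
                D[i, j] = -np.log(A[i, j]) if mapping == "neg_log" else 1.0 / A[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    vals = [D[i, j] for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(vals))


def brute_assortativity(A):
    """Pearson correlation over edge-endpoint strength pairs, duplicating
    each undirected edge in both orientations (symmetric estimator)."""
    s = A.sum(axis=1)
    pairs = []
    n = A.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] != 0:
                pairs.append((s[i], s[j]))
                pairs.append((s[j], s[i]))
    x, y = np.array(pairs).T
    return float(np.corrcoef(x, y)[0, 1])


def brute_modularity_quality(A, labels):
    """Direct double-loop evaluation of the modularity quality function."""
    n = A.shape[0]
    s = A.sum(axis=1)
    two_m = s.sum()
    Q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                Q += A[i, j] - s[i] * s[j] / two_m
    return Q / two_m


def set_partitions(items):
    """All partitions of a list (for exhaustive modularity search)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part
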