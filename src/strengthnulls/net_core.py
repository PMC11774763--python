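"""Weighted-network data model, validation, file I/O and synthetic fixtures.

The central object is :class:`WeightedNetwork`: a dense square weight matrix
``A`` with directedness/signedness flags.  Exact zero means "no edge"; the
diagonal is always zero (no self-loops).  Undirected networks are stored as
full symmetric matrices, but every operation that iterates over edges treats
the upper triangle as the set of logical edges, so each undirected edge is a
single object.

Node indexing is 0-based everywhere.  File formats that carry string labels
map labels to indices in first-appearance order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "WeightedNetwork",
    "StrengthSequence",
    "DegreeSequence",
    "load_network",
    "save_network",
    "save_ensemble",
    "load_ensemble",
    "strengths",
    "degrees",
    "generate_synthetic",
]


@dataclass
class WeightedNetwork:
    """A weighted graph as a dense adjacency matrix.

    Parameters
    ----------
    weights : (n, n) ndarray
        Edge weights ``A_ij``; exact zero encodes an absent edge.
    directed : bool
        If False the matrix must be symmetric and each undirected edge is
        represented once (upper triangle) in edge iterations.
    signed : bool
        If False all entries must be non-negative.  Signed networks cannot
        carry zero-weight edges (zero means absent by convention).
    labels : list of str, optional
        Node names, length n.
    """

    weights: np.ndarray
    directed: bool = False
    signed: bool = False
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        A = self.weights
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("weight matrix contains NaN or infinite entries")
        if np.any(np.diagonal(A) != 0):
            raise ValueError("nonzero diagonal: self-loops are not allowed")
        if not self.directed and not np.array_equal(A, A.T):
            raise ValueError("undirected network requires a symmetric matrix")
        if not self.signed and np.any(A < 0):
            raise ValueError("negative weight in a network flagged as unsigned")
        if not np.any(A):
            raise ValueError("network has no edges")
        if self.labels is not None and len(self.labels) != A.shape[0]:
            raise ValueError("labels length does not match matrix size")

    # -- basic descriptors --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of logical edges (upper triangle only when undirected)."""
        nz = np.count_nonzero(self.weights)
        return nz if self.directed else nz // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        possible = n * (n - 1) if self.directed else n * (n - 1) // 2
        return self.n_edges / possible

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (u, v, w) arrays of logical edges."""
        if self.directed:
            u, v = np.nonzero(self.weights)
        else:
            u, v = np.nonzero(np.triu(self.weights))
        return u, v, self.weights[u, v]

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        """A new network with the same flags/labels and a different matrix."""
        return WeightedNetwork(
            weights=np.asarray(weights, dtype=float),
            directed=self.directed,
            signed=self.signed,
            labels=None if self.labels is None else list(self.labels),
        )

    def copy(self) -> "WeightedNetwork":
        return self.with_weights(self.weights.copy())


@dataclass
class StrengthSequence:
    """Node strengths; only the fields matching the network kind are set.

    ``s`` for undirected, (``s_in``, ``s_out``) for directed, and
    (``s_pos``, ``s_neg``) for signed networks.  ``s_neg`` stores the sum of
    absolute negative weights (a non-negative magnitude).
    """

    s: np.ndarray | None = None
    s_in: np.ndarray | None = None
    s_out: np.ndarray | None = None
    s_pos: np.ndarray | None = None
    s_neg: np.ndarray | None = None


@dataclass
class DegreeSequence:
    """Binary degrees; fields populated per network kind, like strengths."""

    k: np.ndarray | None = None
    k_in: np.ndarray | None = None
    k_out: np.ndarray | None = None
    k_pos: np.ndarray | None = None
    k_neg: np.ndarray | None = None


def strengths(network: WeightedNetwork) -> StrengthSequence:
    """Strength = sum of edge weights incident on each node."""
    A = network.weights
    if network.signed:
        pos = np.where(A > 0, A, 0.0)
        neg = np.where(A < 0, -A, 0.0)
        return StrengthSequence(s_pos=pos.sum(axis=1), s_neg=neg.sum(axis=1))
    if network.directed:
        return StrengthSequence(s_out=A.sum(axis=1), s_in=A.sum(axis=0))
    return StrengthSequence(s=A.sum(axis=1))


def degrees(network: WeightedNetwork) -> DegreeSequence:
    """Degree = number of edges incident on each node."""
    A = network.weights
    if network.signed:
        return DegreeSequence(
            k_pos=(A > 0).sum(axis=1).astype(np.int64),
            k_neg=(A < 0).sum(axis=1).astype(np.int64),
        )
    if network.directed:
        return DegreeSequence(
            k_out=(A != 0).sum(axis=1).astype(np.int64),
            k_in=(A != 0).sum(axis=0).astype(np.int64),
        )
    return DegreeSequence(k=(A != 0).sum(axis=1).astype(np.int64))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _parse_dense(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Read a dense square table; comma or whitespace delimited, optional
    header row of labels."""
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty file: {path}")
    delim = "," if "," in lines[0] else None
    first = lines[0].split(delim)
    labels: list[str] | None = None
    try:
        [float(tok) for tok in first]
    except ValueError:
        labels = [tok.strip() for tok in first]
        lines = lines[1:]
    rows = []
    for ln in lines:
        toks = ln.split(delim)
        rows.append([float(t) for t in toks])
    A = np.array(rows, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"dense matrix in {path} is not square: {A.shape}")
    return A, labels


def _parse_edgelist(
    path: Path, directed: bool
) -> tuple[np.ndarray, list[str] | None]:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    recs = []
    for i, ln in enumerate(lines):
        toks = ln.split("\t") if "\t" in ln else ln.split()
        if len(toks) != 3:
            raise ValueError(f"edge list line {i + 1} does not have 3 columns")
        if i == 0:
            try:
                float(toks[2])
            except ValueError:
                continue  # header row
        recs.append((toks[0], toks[1], float(toks[2])))
    if not recs:
        raise ValueError(f"no edges in {path}")

    # map labels to indices in first-appearance order; pure-integer files
    # keep their integer indexing
    all_int = all(s.lstrip("-").isdigit() for r in recs for s in r[:2])
    if all_int:
        idx = {s: int(s) for r in recs for s in r[:2]}
        n = max(idx.values()) + 1
        labels = None
    else:
        order: dict[str, int] = {}
        for r in recs:
            for s in r[:2]:
                if s not in order:
                    order[s] = len(order)
        idx = order
        n = len(order)
        labels = list(order)
    A = np.zeros((n, n))
    for src, dst, w in recs:
        i, j = idx[src], idx[dst]
        if A[i, j] != 0 or (not directed and A[j, i] != 0):
            raise ValueError(f"duplicate edge ({src}, {dst})")
        A[i, j] = w
        if not directed:
            A[j, i] = w
    return A, labels


def load_network(
    path: str | Path,
    format: str = "dense",
    directed: bool = False,
    signed: bool = False,
) -> WeightedNetwork:
    """Read a network from a dense matrix or a (source, target, weight) edge
    list; undirected edge lists are symmetrized by mirroring each entry."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense":
        A, labels = _parse_dense(path)
    elif format == "edgelist":
        A, labels = _parse_edgelist(path, directed)
    else:
        raise ValueError(f"unknown format {format!r}")
    return WeightedNetwork(A, directed=directed, signed=signed, labels=labels)


def save_network(
    network: WeightedNetwork, path: str | Path, format: str = "dense"
) -> None:
    """Write a network losslessly (full repr-precision floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "dense":
        lines = []
        if network.labels is not None:
            lines.append(",".join(network.labels))
        for row in network.weights:
            lines.append(",".join(repr(float(x)) for x in row))
        path.write_text("\n".join(lines) + "\n")
    elif format == "edgelist":
        u, v, w = network.edge_list()
        lines = ["source\ttarget\tweight"]
        for i, j, x in zip(u, v, w):
            a = network.labels[i] if network.labels else str(i)
            b = network.labels[j] if network.labels else str(j)
            lines.append(f"{a}\t{b}\t{float(x)!r}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def save_ensemble(
    networks: Sequence[WeightedNetwork],
    directory: str | Path,
    algorithm: str,
    config: dict,
    seeds: Sequence[int],
    final_energies: Sequence[float] | None = None,
) -> Path:
    """Write an ensemble as dense files plus a JSON manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, net in enumerate(networks):
        fname = f"null_{i:05d}.csv"
        save_network(net, directory / fname, format="dense")
        files.append(fname)
    manifest = {
        "algorithm": algorithm,
        "config": config,
        "seeds": [int(s) for s in seeds],
        "final_energies": None
        if final_energies is None
        else [float(e) for e in final_energies],
        "files": files,
        "directed": networks[0].directed,
        "signed": networks[0].signed,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_ensemble(directory: str | Path) -> tuple[list[WeightedNetwork], dict]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    nets = [
        load_network(
            directory / f,
            format="dense",
            directed=manifest.get("directed", False),
            signed=manifest.get("signed", False),
        )
        for f in manifest["files"]
    ]
    return nets, manifest


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

_DIST_DEFAULTS = {
    "uniform": {"low": 0.01, "high": 1.0},
    "lognormal": {"mean": 0.0, "sigma": 1.0},
    "pareto": {"alpha": 1.5},
}


def _draw_weights(rng: np.random.Generator, dist: str, params: dict, size: int):
    if dist == "uniform":
        return rng.uniform(params["low"], params["high"], size)
    if dist == "lognormal":
        return rng.lognormal(params["mean"], params["sigma"], size)
    if dist == "pareto":
        # unit-scale Pareto: X = (1 - U)^(-1/alpha), support [1, inf)
        return (1.0 - rng.random(size)) ** (-1.0 / params["alpha"])
    raise ValueError(f"unknown weight distribution {dist!r}")


def lognormal_mean(mean: float = 0.0, sigma: float = 1.0) -> float:
    """Analytic mean of the log-normal weight distribution."""
    return float(np.exp(mean + sigma**2 / 2.0))


def _prufer_tree(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labeled spanning tree via Prüfer-sequence decoding."""
    if n == 1:
        return []
    if n == 2:
        return [(0, 1)]
    seq = rng.integers(0, n, size=n - 2)
    deg = np.ones(n, dtype=np.int64)
    for x in seq:
        deg[x] += 1
    edges = []
    import heapq

    leaves = [i for i in range(n) if deg[i] == 1]
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(x)))
        deg[x] -= 1
        if deg[x] == 1:
            heapq.heappush(leaves, int(x))
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def generate_synthetic(
    n: int,
    density: float,
    weight_dist: str = "lognormal",
    dist_params: dict | None = None,
    directed: bool = False,
    signed: bool = False,
    neg_fraction: float = 0.3,
    connected: bool = False,
    seed: int = 0,
) -> WeightedNetwork:
    """Generate a random weighted network with connectome-like heterogeneity.

    Binary topology is drawn by uniform sampling of node pairs without
    replacement; when ``connected`` is requested, a uniform random spanning
    tree (undirected) or a random Hamiltonian cycle (directed, giving strong
    connectivity) is seeded first and the remaining edges fill in around it.
    Weights are i.i.d. from the named distribution; for signed networks a
    ``neg_fraction`` of edges is negated.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    params = dict(_DIST_DEFAULTS[weight_dist])
    if dist_params:
        params.update(dist_params)

    possible = n * (n - 1) if directed else n * (n - 1) // 2
    m = int(round(density * possible))
    m = max(m, 1)

    seed_edges: list[tuple[int, int]] = []
    if connected:
        if directed:
            if m < n:
                raise ValueError(
                    "density too low for a strongly connected directed graph"
                )
            perm = rng.permutation(n)
            seed_edges = [
                (int(perm[i]), int(perm[(i + 1) % n])) for i in range(n)
            ]
        else:
            if m < n - 1:
                raise ValueError("density too low for a connected graph")
            seed_edges = _prufer_tree(n, rng)

    chosen = {e for e in seed_edges}
    # sample remaining pairs without replacement from the complement
    remaining = m - len(chosen)
    if remaining < 0:
        raise ValueError("density too low to hold the connectivity seed")
    iu, ju = (np.nonzero(np.ones((n, n)) - np.eye(n)) if directed
              else np.triu_indices(n, k=1))
    all_pairs = list(zip(iu.tolist(), ju.tolist()))
    if not directed:
        taken = {tuple(sorted(e)) for e in chosen}
        pool = [p for p in all_pairs if p not in taken]
    else:
        pool = [p for p in all_pairs if p not in chosen]
    if remaining > len(pool):
        raise ValueError("infeasible density")
    extra_idx = rng.choice(len(pool), size=remaining, replace=False)
    edges = list(chosen) + [pool[i] for i in sorted(extra_idx.tolist())]

    w = _draw_weights(rng, weight_dist, params, len(edges))
    w = np.where(w == 0, np.finfo(float).tiny, w)  # zero means "no edge"
    if signed:
        flip = rng.random(len(edges)) < neg_fraction
        w = np.where(flip, -w, w)

    A = np.zeros((n, n))
    for (i, j), x in zip(edges, w):
        A[i, j] = x
        if not directed:
            A[j, i] = x
    return WeightedNetwork(A, directed=directed, signed=signed)
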