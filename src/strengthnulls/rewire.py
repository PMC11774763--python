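"""Degree-preserving topology randomization (Maslov–Sneppen family).

These rewirers disrupt the binary topology by repeated double-edge swaps
while conserving size, density and the degree sequence(s); weights are
carried with their edges, so the weight multiset is conserved exactly.  The
directed variant additionally preserves the out-strength sequence (weights
travel with their source row).  The connectedness-preserving variants never
emit a network with a disconnected node.

Swap proposals are drawn uniformly from the current edge list; a proposal is
rejected if it would create a self-loop, a multi-edge, or (guarded variants)
disconnect the graph.  Rejected proposals count toward ``swaps_attempted``
but not ``swaps_effected``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import _kernels
from .net_core import WeightedNetwork

__all__ = [
    "RewireResult",
    "maslov_sneppen_und",
    "maslov_sneppen_dir",
    "switch_signed",
    "is_connected",
]

#: default number of swaps per edge ("approximately ten swaps per edge")
DEFAULT_SWAPS_PER_EDGE = 10.0

#: proposals allowed per target swap before moving on
MAX_ATTEMPTS_PER_SWAP = 50


@dataclass
class RewireResult:
    network: WeightedNetwork
    swaps_attempted: int
    swaps_effected: int


def is_connected(network: WeightedNetwork) -> bool:
    """Single component (undirected) / strong connectivity (directed) of the
    binary graph."""
    A = csr_matrix(network.weights != 0)
    n_comp, _ = connected_components(
        A,
        directed=network.directed,
        connection="strong" if network.directed else "weak",
    )
    return n_comp == 1


def _check_small(network: WeightedNetwork, name: str) -> RewireResult | None:
    if network.n_edges < 4:
        warnings.warn(
            f"{name}: fewer than 4 edges, no rewiring performed", stacklevel=3
        )
        return RewireResult(network.copy(), 0, 0)
    return None


def _seed_int(seed) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))


def maslov_sneppen_und(
    network: WeightedNetwork,
    swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    preserve_connectedness: bool = True,
    seed: int = 0,
) -> RewireResult:
    """Undirected degree-preserving rewiring with optional connectedness
    guard."""
    if network.directed or network.signed:
        raise ValueError("maslov_sneppen_und requires an undirected, unsigned network")
    if preserve_connectedness and not is_connected(network):
        raise ValueError("input network is disconnected; cannot preserve connectedness")
    small = _check_small(network, "maslov_sneppen_und")
    if small is not None:
        return small
    W = network.weights.copy()
    target = int(round(swaps_per_edge * network.n_edges))
    att, eff = _kernels.rewire_und(
        W, target, MAX_ATTEMPTS_PER_SWAP, preserve_connectedness, _seed_int(seed)
    )
    return RewireResult(network.with_weights(W), int(att), int(eff))


def maslov_sneppen_dir(
    network: WeightedNetwork,
    swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    preserve_connectedness: bool = True,
    seed: int = 0,
) -> RewireResult:
    """Directed rewiring: preserves in/out-degree sequences and the
    out-strength sequence; guard enforces strong connectivity."""
    if not network.directed or network.signed:
        raise ValueError("maslov_sneppen_dir requires a directed, unsigned network")
    if preserve_connectedness and not is_connected(network):
        raise ValueError(
            "input network is not strongly connected; cannot preserve connectedness"
        )
    small = _check_small(network, "maslov_sneppen_dir")
    if small is not None:
        return small
    W = network.weights.copy()
    target = int(round(swaps_per_edge * network.n_edges))
    att, eff = _kernels.rewire_dir(
        W, target, MAX_ATTEMPTS_PER_SWAP, preserve_connectedness, _seed_int(seed)
    )
    return RewireResult(network.with_weights(W), int(att), int(eff))


def switch_signed(
    network: WeightedNetwork,
    swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    seed: int = 0,
) -> RewireResult:
    """Signed connection switching: swaps within sign classes, preserving
    positive and negative degree sequences.  Connectedness is not
    guaranteed."""
    if network.directed or not network.signed:
        raise ValueError("switch_signed requires an undirected, signed network")
    small = _check_small(network, "switch_signed")
    if small is not None:
        return small
    W = network.weights.copy()
    target = int(round(swaps_per_edge * network.n_edges))
    att, eff = _kernels.rewire_signed(
        W, target, MAX_ATTEMPTS_PER_SWAP, _seed_int(seed)
    )
    return RewireResult(network.with_weights(W), int(att), int(eff))
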