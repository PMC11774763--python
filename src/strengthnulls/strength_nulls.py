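"""Strength-sequence-preserving randomization of weighted networks.

Both algorithms operate on a degree-preserving rewired *scaffold* of the
reference network and only rearrange the original weights on top of it, so
size, density, degree sequence(s) and the exact weight multiset are always
conserved; what varies is how faithfully each null reproduces the reference
strength sequence.

* :func:`rubinov_sporns` — deterministic-greedy rank matching: edges expected
  to carry large weights (product of residual strengths of their endpoints)
  receive the largest remaining original weights, one random edge at a time.
* :func:`simulated_annealing` — stochastic minimization of the mean squared
  error between reference and null strength sequences by Metropolis-accepted
  weight-pair swaps under a geometric cooling schedule.  Objective variants
  cover undirected (strengths), directed (in + out), directed-alternative
  (in only, with out-strengths exact by construction) and signed
  (positive + negative) networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from joblib import Parallel, delayed

from . import _kernels
from .net_core import (
    DegreeSequence,
    StrengthSequence,
    WeightedNetwork,
    degrees,
    strengths,
)
from .rewire import (
    DEFAULT_SWAPS_PER_EDGE,
    maslov_sneppen_dir,
    maslov_sneppen_und,
    switch_signed,
)

__all__ = [
    "AnnealingConfig",
    "EnergyTrace",
    "NullEnsemble",
    "mse_energy",
    "metropolis_accept",
    "rubinov_sporns",
    "simulated_annealing",
    "simulated_annealing_dir_alt",
    "generate_ensemble",
]

Objective = Literal["und", "dir", "dir_alt", "signed"]


@dataclass
class AnnealingConfig:
    """Annealing schedule and objective.

    Defaults follow the canonical schedule: 100 stages of 10,000 permutations,
    initial temperature 1,000 halved at each stage.  When ``energy_threshold``
    is set the run stops at the first stage end with E <= threshold, up to
    ``max_stages`` stages (threshold mode; 1e-4 with a 1,000-stage cap is the
    participant-level setting).
    """

    n_stages: int = 100
    iters_per_stage: int = 10_000
    T0: float = 1000.0
    cooling_factor: float = 0.5
    energy_threshold: float | None = None
    max_stages: int = 1000
    objective: Objective | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.energy_threshold is not None and self.energy_threshold <= 0:
            raise ValueError("energy_threshold must be positive when set")


@dataclass
class EnergyTrace:
    """Per-stage energies of one annealing run."""

    stage_energies: np.ndarray
    accepted_per_stage: np.ndarray
    initial_energy: float
    final_energy: float
    stages_run: int
    best_energy: float

    def to_dict(self) -> dict:
        return {
            "stage_energies": [float(x) for x in self.stage_energies],
            "accepted_per_stage": [int(x) for x in self.accepted_per_stage],
            "initial_energy": float(self.initial_energy),
            "final_energy": float(self.final_energy),
            "stages_run": int(self.stages_run),
            "best_energy": float(self.best_energy),
        }


@dataclass
class NullEnsemble:
    """A population of randomized networks with per-null provenance."""

    networks: list[WeightedNetwork]
    algorithm: str
    master_seed: int
    seeds: list[int]
    traces: list[EnergyTrace] | None = None

    def __len__(self) -> int:
        return len(self.networks)

    def validate_against(self, reference: WeightedNetwork) -> None:
        ref_w = np.sort(np.abs(reference.weights[reference.weights != 0]))
        for net in self.networks:
            if net.n_nodes != reference.n_nodes:
                raise ValueError("null/reference size mismatch")
            if net.directed != reference.directed or net.signed != reference.signed:
                raise ValueError("null/reference kind mismatch")
            null_w = np.sort(np.abs(net.weights[net.weights != 0]))
            if null_w.shape != ref_w.shape or not np.array_equal(null_w, ref_w):
                raise ValueError("weight multiset not conserved in ensemble")


# ---------------------------------------------------------------------------
# Objective / acceptance primitives
# ---------------------------------------------------------------------------


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("strength vectors have mismatched lengths")
    return float(np.mean((a - b) ** 2))


def mse_energy(
    s_target: StrengthSequence,
    s_current: StrengthSequence,
    objective: Objective | None = None,
) -> float:
    """Mean squared error between strength sequences (the annealing energy).

    Undirected: (1/n) sum_i (s_i - s_hat_i)^2.  Directed: mse(in) + mse(out).
    Signed: mse(positive) + mse(negative magnitudes).  ``dir_alt``: mse(in)
    only.  The objective is inferred from the populated fields unless given.
    """
    if objective is None:
        if s_target.s is not None:
            objective = "und"
        elif s_target.s_pos is not None:
            objective = "signed"
        elif s_target.s_in is not None:
            objective = "dir"
        else:
            raise ValueError("empty strength sequence")
    if objective == "und":
        if s_target.s is None or s_current.s is None:
            raise ValueError("objective 'und' requires the undirected field s")
        return _mse(s_target.s, s_current.s)
    if objective == "dir":
        if s_target.s_in is None or s_current.s_in is None:
            raise ValueError("objective 'dir' requires directed fields")
        return _mse(s_target.s_in, s_current.s_in) + _mse(
            s_target.s_out, s_current.s_out
        )
    if objective == "dir_alt":
        if s_target.s_in is None or s_current.s_in is None:
            raise ValueError("objective 'dir_alt' requires directed fields")
        return _mse(s_target.s_in, s_current.s_in)
    if objective == "signed":
        if s_target.s_pos is None or s_current.s_pos is None:
            raise ValueError("objective 'signed' requires signed fields")
        return _mse(s_target.s_pos, s_current.s_pos) + _mse(
            s_target.s_neg, s_current.s_neg
        )
    raise ValueError(f"unknown objective {objective!r}")


def metropolis_accept(E: float, E_prime: float, T: float, u: float) -> bool:
    """Metropolis criterion: downhill always, uphill iff u < exp(-(E'-E)/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if E_prime < E:
        return True
    return u < np.exp(-(E_prime - E) / T)


# ---------------------------------------------------------------------------
# Shared validation
# ---------------------------------------------------------------------------


def _check_pair(reference: WeightedNetwork, scaffold: WeightedNetwork) -> None:
    if reference.n_nodes != scaffold.n_nodes:
        raise ValueError("reference/scaffold size mismatch")
    if (
        reference.directed != scaffold.directed
        or reference.signed != scaffold.signed
    ):
        raise ValueError("reference/scaffold kind mismatch")
    dr, ds = degrees(reference), degrees(scaffold)
    for name in ("k", "k_in", "k_out", "k_pos", "k_neg"):
        a, b = getattr(dr, name), getattr(ds, name)
        if (a is None) != (b is None):
            raise ValueError("reference/scaffold degree-field mismatch")
        if a is not None and not np.array_equal(a, b):
            raise ValueError(f"degree sequence mismatch in field {name}")
    wr = np.sort(reference.weights[reference.weights != 0])
    ws = np.sort(scaffold.weights[scaffold.weights != 0])
    if wr.shape != ws.shape or not np.array_equal(wr, ws):
        raise ValueError("reference/scaffold weight multiset mismatch")


def _seed_int(seed_seq_or_int) -> int:
    ss = (
        seed_seq_or_int
        if isinstance(seed_seq_or_int, np.random.SeedSequence)
        else np.random.SeedSequence(seed_seq_or_int)
    )
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Rubinov–Sporns rank matching
# ---------------------------------------------------------------------------


def rubinov_sporns(
    reference: WeightedNetwork,
    scaffold: WeightedNetwork,
    seed: int = 0,
) -> WeightedNetwork:
    """Rank-matched weight reassignment on the scaffold topology.

    Unsigned networks: the procedure is applied to all edges at once against
    the reference strength sequence.  Signed networks: applied separately to
    positive and negative edges against the positive/negative strength
    sequences.
    """
    _check_pair(reference, scaffold)
    if reference.directed:
        raise ValueError("rubinov_sporns supports undirected networks only")
    n = reference.n_nodes
    s_ref = strengths(reference)
    out = np.zeros((n, n))
    rng_seed = _seed_int(seed)
    if not reference.signed:
        u, v, _ = scaffold.edge_list()
        w_desc = np.sort(reference.weights[np.triu_indices(n, 1)][
            reference.weights[np.triu_indices(n, 1)] != 0
        ])[::-1].copy()
        assigned = _kernels.rubinov_sporns_core(
            u.astype(np.int64), v.astype(np.int64), s_ref.s, w_desc, rng_seed
        )
        out[u, v] = assigned
        out[v, u] = assigned
    else:
        iu, ju = np.triu_indices(n, 1)
        ref_up = reference.weights[iu, ju]
        sc_up = scaffold.weights[iu, ju]
        for sign, s_tgt, sub_seed in (
            (1.0, s_ref.s_pos, rng_seed),
            (-1.0, s_ref.s_neg, rng_seed + 1),
        ):
            mask = sc_up * sign > 0
            u, v = iu[mask], ju[mask]
            w_desc = np.sort(np.abs(ref_up[ref_up * sign > 0]))[::-1].copy()
            if w_desc.size != u.size:
                raise ValueError("sign-class edge counts differ between "
                                 "reference and scaffold")
            if u.size == 0:
                continue
            assigned = _kernels.rubinov_sporns_core(
                u.astype(np.int64), v.astype(np.int64), s_tgt, w_desc, sub_seed
            )
            out[u, v] = sign * assigned
            out[v, u] = sign * assigned
    return reference.with_weights(out)


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


def _trace_from_kernel(res) -> EnergyTrace:
    stage_E, stage_acc, stages_run, E0, best_E, max_drift = res
    return EnergyTrace(
        stage_energies=np.asarray(stage_E),
        accepted_per_stage=np.asarray(stage_acc),
        initial_energy=float(E0),
        final_energy=float(stage_E[-1]),
        stages_run=int(stages_run),
        best_energy=float(best_E),
    ), float(max_drift)


def _check_drift(max_drift: float, n: int, E0: float) -> None:
    tol = 1e-9 * n * max(1.0, abs(E0))
    if max_drift > tol:
        raise RuntimeError(
            f"incremental energy drifted from full recomputation by "
            f"{max_drift:.3e} (tolerance {tol:.3e})"
        )


def _resolve_objective(net: WeightedNetwork, config: AnnealingConfig) -> str:
    if config.objective is not None:
        obj = config.objective
    elif net.signed:
        obj = "signed"
    elif net.directed:
        obj = "dir"
    else:
        obj = "und"
    if obj == "und" and (net.directed or net.signed):
        raise ValueError("objective 'und' requires an undirected unsigned network")
    if obj in ("dir", "dir_alt") and not net.directed:
        raise ValueError(f"objective {obj!r} requires a directed network")
    if obj == "signed" and not net.signed:
        raise ValueError("objective 'signed' requires a signed network")
    return obj


def simulated_annealing(
    reference: WeightedNetwork,
    scaffold: WeightedNetwork,
    config: AnnealingConfig | None = None,
) -> tuple[WeightedNetwork, EnergyTrace]:
    """Anneal the scaffold's weight placement toward the reference strength
    sequence.

    At each iteration two edges are chosen uniformly at random (within sign
    class for the signed objective) and their weights are swapped if the move
    lowers the energy or passes the Metropolis criterion; the temperature is
    multiplied by ``cooling_factor`` at each stage end.  Returns the final
    configuration and its energy trace.
    """
    config = config or AnnealingConfig()
    _check_pair(reference, scaffold)
    obj = _resolve_objective(reference, config)
    if obj == "dir_alt":
        return simulated_annealing_dir_alt(reference, scaffold, config)
    n = reference.n_nodes
    s_ref = strengths(reference)
    use_thr = config.energy_threshold is not None
    cap = config.max_stages if use_thr else config.n_stages
    thr = config.energy_threshold if use_thr else 0.0
    seed = _seed_int(config.seed)
    u, v, w = scaffold.edge_list()
    u = u.astype(np.int64)
    v = v.astype(np.int64)
    w = w.astype(np.float64).copy()

    if obj == "und":
        res = _kernels.sa_und(
            u, v, w, s_ref.s, n, cap, config.iters_per_stage, config.T0,
            config.cooling_factor, use_thr, thr, seed,
        )
    elif obj == "dir":
        res = _kernels.sa_dir(
            u, v, w, s_ref.s_in, s_ref.s_out, n, cap, config.iters_per_stage,
            config.T0, config.cooling_factor, use_thr, thr, seed,
        )
    else:  # signed
        res = _kernels.sa_signed(
            u, v, w, s_ref.s_pos, s_ref.s_neg, n, cap, config.iters_per_stage,
            config.T0, config.cooling_factor, use_thr, thr, seed,
        )
    trace, max_drift = _trace_from_kernel(res)
    _check_drift(max_drift, n, trace.initial_energy)
    out = np.zeros((n, n))
    out[u, v] = w
    if not reference.directed:
        out[v, u] = w
    return reference.with_weights(out), trace


def simulated_annealing_dir_alt(
    reference: WeightedNetwork,
    scaffold: WeightedNetwork,
    config: AnnealingConfig | None = None,
) -> tuple[WeightedNetwork, EnergyTrace]:
    """Out-strength-exact directed annealing.

    The basic iteration picks a node at random and swaps a pair of edge
    weights among its outgoing connections only, so row sums (out-strengths)
    are invariant; the energy is the in-strength mean squared error alone.
    """
    config = config or AnnealingConfig(objective="dir_alt")
    _check_pair(reference, scaffold)
    if not reference.directed or reference.signed:
        raise ValueError("dir_alt variant requires a directed, unsigned network")
    n = reference.n_nodes
    s_ref = strengths(reference)
    use_thr = config.energy_threshold is not None
    cap = config.max_stages if use_thr else config.n_stages
    thr = config.energy_threshold if use_thr else 0.0
    seed = _seed_int(config.seed)

    # CSR-by-source layout of the scaffold edges
    A = scaffold.weights
    rowptr = np.zeros(n + 1, dtype=np.int64)
    cols = []
    ws = []
    for i in range(n):
        nz = np.nonzero(A[i])[0]
        rowptr[i + 1] = rowptr[i] + nz.size
        cols.append(nz)
        ws.append(A[i, nz])
    colv = np.concatenate(cols).astype(np.int64)
    colw = np.concatenate(ws).astype(np.float64)

    res = _kernels.sa_dir_alt(
        rowptr, colw, colv, s_ref.s_in, n, cap, config.iters_per_stage,
        config.T0, config.cooling_factor, use_thr, thr, seed,
    )
    trace, max_drift = _trace_from_kernel(res)
    _check_drift(max_drift, n, trace.initial_energy)
    out = np.zeros((n, n))
    for i in range(n):
        out[i, colv[rowptr[i]:rowptr[i + 1]]] = colw[rowptr[i]:rowptr[i + 1]]
    return reference.with_weights(out), trace


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------


def _null_seed(master_seed: int, index: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(index, stream))


def _make_scaffold(
    reference: WeightedNetwork,
    swaps_per_edge: float,
    preserve_connectedness: bool,
    seed_seq: np.random.SeedSequence,
) -> WeightedNetwork:
    seed = _seed_int(seed_seq)
    if reference.signed:
        return switch_signed(reference, swaps_per_edge, seed=seed).network
    if reference.directed:
        return maslov_sneppen_dir(
            reference, swaps_per_edge, preserve_connectedness, seed=seed
        ).network
    return maslov_sneppen_und(
        reference, swaps_per_edge, preserve_connectedness, seed=seed
    ).network


def _make_null(
    reference: WeightedNetwork,
    algorithm: str,
    index: int,
    master_seed: int,
    swaps_per_edge: float,
    preserve_connectedness: bool,
    annealing_config: AnnealingConfig | None,
):
    scaffold = _make_scaffold(
        reference,
        swaps_per_edge,
        preserve_connectedness,
        _null_seed(master_seed, index, 0),
    )
    weight_seed = _seed_int(_null_seed(master_seed, index, 1))
    if algorithm == "ms":
        return scaffold, None, weight_seed
    if algorithm == "rs":
        return rubinov_sporns(reference, scaffold, seed=weight_seed), None, weight_seed
    if algorithm in ("sa", "sa_dir_alt"):
        cfg = annealing_config or AnnealingConfig()
        cfg = AnnealingConfig(
            n_stages=cfg.n_stages,
            iters_per_stage=cfg.iters_per_stage,
            T0=cfg.T0,
            cooling_factor=cfg.cooling_factor,
            energy_threshold=cfg.energy_threshold,
            max_stages=cfg.max_stages,
            objective="dir_alt" if algorithm == "sa_dir_alt" else cfg.objective,
            seed=weight_seed,
        )
        if algorithm == "sa_dir_alt":
            net, trace = simulated_annealing_dir_alt(reference, scaffold, cfg)
        else:
            net, trace = simulated_annealing(reference, scaffold, cfg)
        return net, trace, weight_seed
    raise ValueError(f"unknown algorithm {algorithm!r}")


def generate_ensemble(
    reference: WeightedNetwork,
    algorithm: str,
    n_nulls: int,
    rewire_config: dict | None = None,
    annealing_config: AnnealingConfig | None = None,
    seed: int = 0,
    n_jobs: int = 1,
) -> NullEnsemble:
    """Generate ``n_nulls`` independent nulls.

    The i-th null of every algorithm is built on the i-th rewired scaffold:
    with a shared master seed the ms/rs/sa ensembles share binary topologies
    null-by-null and differ only in their weight placement.  Per-null seeds
    are derived from (master seed, null index), so parallel generation
    (``n_jobs``) cannot change the result.
    """
    if algorithm not in ("ms", "rs", "sa", "sa_dir_alt"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if algorithm == "rs" and reference.directed:
        raise ValueError("rubinov_sporns does not support directed networks")
    if algorithm == "sa_dir_alt" and not reference.directed:
        raise ValueError("sa_dir_alt requires a directed network")
    rc = {"swaps_per_edge": DEFAULT_SWAPS_PER_EDGE, "preserve_connectedness": True}
    if rewire_config:
        rc.update(rewire_config)
    results = Parallel(n_jobs=n_jobs)(
        delayed(_make_null)(
            reference,
            algorithm,
            i,
            seed,
            rc["swaps_per_edge"],
            rc["preserve_connectedness"],
            annealing_config,
        )
        for i in range(n_nulls)
    )
    networks = [r[0] for r in results]
    traces = [r[1] for r in results]
    seeds = [r[2] for r in results]
    ensemble = NullEnsemble(
        networks=networks,
        algorithm=algorithm,
        master_seed=seed,
        seeds=seeds,
        traces=None if traces[0] is None else traces,
    )
    ensemble.validate_against(reference)
    return ensemble
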