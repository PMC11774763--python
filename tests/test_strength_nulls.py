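"""Strength-preserving randomizers: energy primitives, rank matching,
simulated annealing variants and ensemble generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from strengthnulls import (
    AnnealingConfig,
    StrengthSequence,
    WeightedNetwork,
    degrees,
    generate_ensemble,
    generate_synthetic,
    is_connected,
    maslov_sneppen_dir,
    maslov_sneppen_und,
    metropolis_accept,
    mse_energy,
    rubinov_sporns,
    simulated_annealing,
    simulated_annealing_dir_alt,
    strengths,
    switch_signed,
)

from conftest import make_random_net, row_multisets_equal, sorted_weights

QUICK = AnnealingConfig(n_stages=20, iters_per_stage=2000)


class TestMseEnergy:
    def test_identity_is_zero(self):
        s = StrengthSequence(s=np.array([1.0, 2, 3]))
        assert mse_energy(s, s) == 0.0

    def test_hand_computed_value(self):
        a = StrengthSequence(s=np.array([3.0, 1, 2]))
        b = StrengthSequence(s=np.array([1.0, 3, 2]))
        assert mse_energy(a, b) == pytest.approx(8 / 3)

    def test_directed_additivity(self):
        a = StrengthSequence(s_in=np.array([0.0, 0]), s_out=np.array([0.0, 0]))
        b = StrengthSequence(s_in=np.array([1.0, 1]), s_out=np.array([1.0, 0]))
        assert mse_energy(a, b) == pytest.approx(1.0 + 0.5)
        assert mse_energy(a, b, objective="dir_alt") == pytest.approx(1.0)

    def test_signed_additivity(self):
        a = StrengthSequence(s_pos=np.array([2.0, 0]), s_neg=np.array([0.0, 2]))
        b = StrengthSequence(s_pos=np.array([0.0, 0]), s_neg=np.array([0.0, 0]))
        assert mse_energy(a, b) == pytest.approx(2.0 + 2.0)

    def test_length_mismatch_error(self):
        a = StrengthSequence(s=np.array([1.0, 2]))
        b = StrengthSequence(s=np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            mse_energy(a, b)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=10))
    def test_nonnegative(self, vals):
        a = StrengthSequence(s=np.array(vals))
        b = StrengthSequence(s=np.array(vals[::-1]))
        assert mse_energy(a, b) >= 0.0


class TestMetropolis:
    def test_downhill_always_accepted(self):
        assert metropolis_accept(10.0, 5.0, 1e-12, u=0.999999)

    def test_ln2_closed_form(self):
        """E' - E = T ln 2 gives acceptance probability exactly 1/2."""
        T = 3.7
        assert metropolis_accept(1.0, 1.0 + T * np.log(2), T, u=0.4)
        assert not metropolis_accept(1.0, 1.0 + T * np.log(2), T, u=0.6)

    def test_cold_limit_rejects_uphill(self):
        assert not metropolis_accept(1.0, 2.0, 1e-300, u=1e-10)

    def test_nonpositive_temperature_error(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 2.0, 0.0, u=0.5)

    @settings(max_examples=100, derandomize=True)
    @given(
        dE=st.floats(0.001, 100),
        T=st.floats(0.01, 1e4),
        u1=st.floats(0, 0.999),
        u2=st.floats(0, 0.999),
    )
    def test_monotone_in_u(self, dE, T, u1, u2):
        """If an uphill move is accepted at u, it is accepted at any u' < u."""
        lo, hi = min(u1, u2), max(u1, u2)
        if metropolis_accept(0.0, dE, T, hi):
            assert metropolis_accept(0.0, dE, T, lo)


def _rubinov_sporns_reference(reference, scaffold, seed):
    """Full-recompute rank-matching oracle: residual strengths rebuilt from
    scratch at every step."""
    rng = np.random.default_rng(seed)
    u, v, _ = scaffold.edge_list()
    m = u.size
    s = strengths(reference).s
    w_remaining = sorted(sorted_weights(reference).tolist(), reverse=True)
    A = np.zeros_like(reference.weights)
    unassigned = list(range(m))
    while unassigned:
        resid = s - A.sum(axis=1)
        pos = rng.integers(len(unassigned))
        e = unassigned[pos]
        ehat_e = resid[u[e]] * resid[v[e]]
        greater = ties = 0
        for f in unassigned:
            if f == e:
                continue
            val = resid[u[f]] * resid[v[f]]
            if val > ehat_e:
                greater += 1
            elif val == ehat_e:
                ties += 1
        rank = greater + int(rng.integers(ties + 1))
        w = w_remaining.pop(rank)
        A[u[e], v[e]] = A[v[e], u[e]] = w
        unassigned.remove(e)
    return reference.with_weights(A)


class TestRubinovSporns:
    def test_single_edge_forced(self):
        A = np.array([[0.0, 4.2], [4.2, 0]])
        net = WeightedNetwork(A)
        out = rubinov_sporns(net, net, seed=0)
        assert np.array_equal(out.weights, A)

    @pytest.mark.parametrize("seed", range(4))
    def test_two_edge_path_hand_trace(self, seed):
        """Path 0-1 (w=10), 1-2 (w=1): the edge whose endpoints have the
        larger residual-strength product must receive the weight 10,
        regardless of which edge is drawn first."""
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 10.0
        A[1, 2] = A[2, 1] = 1.0
        net = WeightedNetwork(A)
        out = rubinov_sporns(net, net, seed=seed)
        assert np.array_equal(out.weights, A)
        ref = _rubinov_sporns_reference(net, net, seed=seed)
        assert np.array_equal(ref.weights, A)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation(self, und_fixture, seed):
        scaffold = maslov_sneppen_und(und_fixture, seed=seed).network
        out = rubinov_sporns(und_fixture, scaffold, seed=seed)
        assert np.array_equal(sorted_weights(out), sorted_weights(und_fixture))
        assert np.array_equal(out.weights != 0, scaffold.weights != 0)

    def test_matches_full_recompute_reference_quality(self):
        """Incremental kernel and full-recompute oracle achieve the same
        strength fidelity (distribution over seeds)."""
        net = make_random_net(0, n=25, density=0.2)
        s_ref = strengths(net).s
        rho_kernel, rho_oracle = [], []
        for seed in range(10):
            scaffold = maslov_sneppen_und(net, seed=seed).network
            a = rubinov_sporns(net, scaffold, seed=seed)
            b = _rubinov_sporns_reference(net, scaffold, seed=seed)
            assert np.array_equal(sorted_weights(a), sorted_weights(b))
            rho_kernel.append(spearmanr(s_ref, strengths(a).s).statistic)
            rho_oracle.append(spearmanr(s_ref, strengths(b).s).statistic)
        assert abs(np.mean(rho_kernel) - np.mean(rho_oracle)) < 0.05

    def test_signed_variant_per_class(self, signed_fixture):
        scaffold = switch_signed(signed_fixture, seed=2).network
        out = rubinov_sporns(signed_fixture, scaffold, seed=2)
        assert np.array_equal(sorted_weights(out), sorted_weights(signed_fixture))
        # sign pattern follows the scaffold exactly
        assert np.array_equal(np.sign(out.weights), np.sign(scaffold.weights))

    def test_directed_unsupported(self, dir_fixture):
        with pytest.raises(ValueError):
            rubinov_sporns(dir_fixture, dir_fixture, seed=0)

    def test_degree_mismatch_error(self, und_fixture):
        other = generate_synthetic(n=50, density=0.3, seed=99, connected=True)
        with pytest.raises(ValueError):
            rubinov_sporns(und_fixture, other, seed=0)


class TestAnnealingConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_stages": 0},
            {"T0": 0.0},
            {"cooling_factor": 1.0},
            {"cooling_factor": 0.0},
            {"energy_threshold": -1.0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            AnnealingConfig(**kwargs)


class TestSimulatedAnnealing:
    def test_uniform_weights_zero_energy(self):
        """Equal weights make strength a pure function of the (preserved)
        degrees: the initial energy is 0 and strengths match exactly."""
        net = generate_synthetic(n=20, density=0.3, seed=1,
                                 weight_dist="uniform",
                                 dist_params={"low": 1.0, "high": 1.0},
                                 connected=True)
        scaffold = maslov_sneppen_und(net, seed=0).network
        out, trace = simulated_annealing(net, scaffold, QUICK)
        assert trace.initial_energy == 0.0
        assert np.array_equal(strengths(out).s, strengths(net).s)

    def test_near_perfect_strength_recovery(self, und_fixture):
        scaffold = maslov_sneppen_und(und_fixture, seed=3).network
        out, trace = simulated_annealing(und_fixture, scaffold,
                                         AnnealingConfig(seed=3))
        rho = spearmanr(strengths(und_fixture).s, strengths(out).s).statistic
        assert rho >= 0.99
        assert trace.final_energy <= trace.initial_energy
        assert trace.final_energy < 0.01 * trace.initial_energy

    def test_trace_invariants(self, und_fixture):
        scaffold = maslov_sneppen_und(und_fixture, seed=5).network
        out, trace = simulated_annealing(und_fixture, scaffold, QUICK)
        assert trace.final_energy == trace.stage_energies[-1]
        assert trace.stages_run == QUICK.n_stages
        assert trace.best_energy <= trace.initial_energy
        assert np.array_equal(sorted_weights(out), sorted_weights(und_fixture))
        assert is_connected(out)

    def test_energy_threshold_stops_early(self, und_fixture):
        scaffold = maslov_sneppen_und(und_fixture, seed=4).network
        cfg = AnnealingConfig(energy_threshold=1e-4, max_stages=1000, seed=4)
        _, trace = simulated_annealing(und_fixture, scaffold, cfg)
        assert trace.stages_run < 1000
        assert trace.final_energy <= 1e-4

    def test_perfect_matching_degenerate(self):
        """Disjoint-edge networks still anneal (the only swap toggles two
        configurations) and conserve everything."""
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 2.0
        A[2, 3] = A[3, 2] = 5.0
        net = WeightedNetwork(A)
        out, trace = simulated_annealing(net, net, QUICK)
        assert np.array_equal(sorted_weights(out), sorted_weights(net))
        assert trace.final_energy <= trace.initial_energy

    def test_directed_energy_reduction(self, dir_fixture):
        scaffold = maslov_sneppen_dir(dir_fixture, seed=2).network
        out, trace = simulated_annealing(dir_fixture, scaffold,
                                         AnnealingConfig(seed=2))
        # the 40-node fixture has few edges per node; the acceptance-scale
        # directed fixture reaches < 1% of the initial energy
        assert trace.final_energy < 0.05 * trace.initial_energy
        assert np.array_equal(sorted_weights(out), sorted_weights(dir_fixture))

    def test_signed_within_class_swaps(self, signed_fixture):
        scaffold = switch_signed(signed_fixture, seed=6).network
        out, trace = simulated_annealing(signed_fixture, scaffold,
                                         AnnealingConfig(seed=6))
        assert np.array_equal(np.sign(out.weights), np.sign(scaffold.weights))
        d0, d1 = degrees(signed_fixture), degrees(out)
        assert np.array_equal(d0.k_pos, d1.k_pos)
        assert np.array_equal(d0.k_neg, d1.k_neg)
        s0, s1 = strengths(signed_fixture), strengths(out)
        assert spearmanr(s0.s_pos, s1.s_pos).statistic > 0.95
        # the negative class is sparse (~30% of edges), so its rank
        # correlation carries more tie noise
        assert spearmanr(s0.s_neg, s1.s_neg).statistic > 0.8
        assert trace.final_energy <= trace.initial_energy


class TestDirAlt:
    def test_out_strengths_exact(self, dir_fixture):
        scaffold = maslov_sneppen_dir(dir_fixture, seed=7).network
        out, trace = simulated_annealing_dir_alt(dir_fixture, scaffold,
                                                 AnnealingConfig(seed=7))
        assert row_multisets_equal(dir_fixture, out)
        assert np.allclose(strengths(dir_fixture).s_out,
                           strengths(out).s_out, rtol=1e-12)
        assert np.array_equal(sorted_weights(out), sorted_weights(dir_fixture))
        assert trace.final_energy <= trace.initial_energy

    def test_improves_in_strength_mse(self, dir_fixture):
        scaffold = maslov_sneppen_dir(dir_fixture, seed=8).network
        out, trace = simulated_annealing_dir_alt(dir_fixture, scaffold,
                                                 AnnealingConfig(seed=8))
        s_ref = strengths(dir_fixture)
        e_scaffold = mse_energy(s_ref, strengths(scaffold), objective="dir_alt")
        e_out = mse_energy(s_ref, strengths(out), objective="dir_alt")
        assert e_out < e_scaffold
        rho = spearmanr(s_ref.s_in, strengths(out).s_in).statistic
        assert rho >= 0.95

    def test_requires_directed(self, und_fixture):
        with pytest.raises(ValueError):
            simulated_annealing_dir_alt(und_fixture, und_fixture)


class TestEnsembles:
    def test_basic_invariants(self, und_fixture):
        ens = generate_ensemble(und_fixture, "sa", 5, annealing_config=QUICK,
                                seed=1)
        assert len(ens) == 5
        ens.validate_against(und_fixture)
        assert len(ens.traces) == 5
        for net in ens.networks:
            assert np.array_equal(sorted_weights(net), sorted_weights(und_fixture))

    def test_shared_topologies_across_algorithms(self, und_fixture):
        e_ms = generate_ensemble(und_fixture, "ms", 3, seed=42)
        e_rs = generate_ensemble(und_fixture, "rs", 3, seed=42)
        e_sa = generate_ensemble(und_fixture, "sa", 3, annealing_config=QUICK,
                                 seed=42)
        for a, b, c in zip(e_ms.networks, e_rs.networks, e_sa.networks):
            assert np.array_equal(a.weights != 0, b.weights != 0)
            assert np.array_equal(a.weights != 0, c.weights != 0)

    def test_parallel_matches_serial(self, und_fixture):
        serial = generate_ensemble(und_fixture, "sa", 4, annealing_config=QUICK,
                                   seed=9, n_jobs=1)
        parallel = generate_ensemble(und_fixture, "sa", 4, annealing_config=QUICK,
                                     seed=9, n_jobs=2)
        for a, b in zip(serial.networks, parallel.networks):
            assert np.array_equal(a.weights, b.weights)

    def test_incompatible_combinations(self, dir_fixture, und_fixture):
        with pytest.raises(ValueError):
            generate_ensemble(dir_fixture, "rs", 2, seed=0)
        with pytest.raises(ValueError):
            generate_ensemble(und_fixture, "sa_dir_alt", 2, seed=0)
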