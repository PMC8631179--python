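"""Solver correctness: linking fractions, equilibrium, rates, evolution.

Oracles are independent re-implementations: brute-force term-by-term sums
for the rate formulas, direct Boltzmann arithmetic for equilibria, and a
tight-tolerance stiff ODE integration for the time evolution.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from gitr.engine import (
    dominant_path,
    equilibrium_distribution,
    equilibrium_flux,
    evolve,
    kinetic_matrix,
    linking_fractions,
    path_rates,
    state_rates,
)
from gitr.network import (
    ConcentrationState,
    SelfAssemblyNetwork,
    StableState,
    TransitionState,
)
from gitr.pdl1 import random_network

RT310 = 1.9872e-3 * 310.0


def brute_force_path_rate(net, conc, s, t, k_scale=1.0):
    """Direct term-by-term evaluation of the path-rate formula."""
    a = net.frequency_factors()
    if a[s, t] == 0:
        return 0.0
    g_s, g_t = net.g_state, net.g_transition
    nu, cs, rt = net.nu, conc.cs, net.rt
    k = k_scale * a
    lf_st = k[s, t] / k[:, t].sum()
    out = -k[s, t] * np.exp(-(g_t[t] - g_s[s]) / rt) * cs[s]
    inn = sum(
        lf_st * k[sp, t] * np.exp(-(g_t[t] - g_s[sp]) / rt) * nu[sp] / nu[s] * cs[sp]
        for sp in range(net.n_states)
    )
    return out + inn


class TestLinkingFractions:
    def test_uniform_when_factors_equal(self):
        net = random_network(3, 1, seed=0)
        # rebuild with all A = 1 so the single column is uniform over links
        transitions = tuple(
            TransitionState(t.id, t.g_monomer, tuple((s, 1.0) for s, _ in t.links))
            for t in net.transitions
        )
        net = SelfAssemblyNetwork(net.states, transitions)
        lf = linking_fractions(net)
        col = lf.matrix[:, 0]
        n_linked = (col > 0).sum()
        assert np.allclose(col[col > 0], 1.0 / n_linked)

    def test_single_link_column_is_one(self):
        net = SelfAssemblyNetwork(
            states=(StableState("S1", 1, 0.0),),
            transitions=(TransitionState("T1", 1.0, (("S1", 1.0),)),),
        )
        assert linking_fractions(net).matrix[0, 0] == 1.0

    def test_weighted_factors_give_direct_ratios(self):
        net = SelfAssemblyNetwork(
            states=(
                StableState("S1", 1, 0.0),
                StableState("S2", 1, -1.0),
                StableState("S3", 1, -2.0),
            ),
            transitions=(
                TransitionState("T1", 1.0, (("S1", 2.0), ("S2", 1.0), ("S3", 1.0))),
            ),
        )
        assert np.allclose(linking_fractions(net).matrix[:, 0], [0.5, 0.25, 0.25])

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_columns_sum_to_one_on_random_networks(self, seed):
        net = random_network(
            1 + seed % 6, 1 + (seed // 7) % 4, seed=seed
        )
        sums = linking_fractions(net).matrix.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestEquilibriumDistribution:
    def test_equal_energies_split_evenly(self):
        net = SelfAssemblyNetwork(
            states=(StableState("S1", 2, -4.0), StableState("S2", 2, -4.0)),
            transitions=(TransitionState("T1", 1.0, (("S1", 1.0), ("S2", 1.0))),),
        )
        conc = equilibrium_distribution(net)
        p = conc.ms / conc.ms.sum()
        assert np.allclose(p, 0.5)

    def test_pdl1_predrug_populations(self, pdl1):
        """Boltzmann ratio of the two apo dimers at 310 K."""
        conc = equilibrium_distribution(pdl1, accessible=("S1", "S2"))
        p = conc.ms / conc.ms.sum()
        g1, g2 = -23.63 / 2, -31.15 / 2
        expected_p2 = 1.0 / (1.0 + np.exp((g2 - g1) / RT310))
        assert p[1] == pytest.approx(expected_p2, rel=1e-12)
        assert p[1] == pytest.approx(0.9978, abs=5e-4)
        assert conc.cs[2] == 0.0  # S3 inaccessible pre-drug

    def test_single_accessible_state(self, pdl1):
        conc = equilibrium_distribution(pdl1, accessible=("S2",))
        assert conc.cs[1] == pytest.approx(pdl1.c0_monomer / 2)
        assert conc.cs[0] == conc.cs[2] == 0.0

    def test_empty_accessible_set_rejected(self, pdl1):
        with pytest.raises(ValueError):
            equilibrium_distribution(pdl1, accessible=())


class TestPathRates:
    def test_zero_concentrations_give_zero_rates(self, two_state_net):
        conc = ConcentrationState.for_network(two_state_net, [0.0, 0.0])
        assert np.all(path_rates(two_state_net, conc).path_rates == 0.0)

    def test_negative_concentration_rejected(self, two_state_net):
        conc = ConcentrationState.for_network(two_state_net, [1.0, -0.1])
        with pytest.raises(ValueError):
            path_rates(two_state_net, conc)

    @pytest.mark.parametrize("seed", range(10))
    def test_rates_vanish_at_equilibrium(self, random_net_factory, seed):
        """Stationarity: the analytic Lf normalisation makes the net flow
        through every path cancel exactly at the Boltzmann distribution."""
        net = random_net_factory(seed)
        conc = equilibrium_distribution(net)
        r = path_rates(net, conc).path_rates
        scale = equilibrium_flux(net).path_rates.max()
        assert np.abs(r).max() <= 1e-10 * scale

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, random_net_factory, seed):
        net = random_net_factory(seed, n_states=4)
        rng = np.random.default_rng(seed + 99)
        conc = ConcentrationState.for_network(net, rng.uniform(0, 1, net.n_states))
        table = path_rates(net, conc)
        for s in range(net.n_states):
            for t in range(net.n_transitions):
                assert table.path_rates[s, t] == pytest.approx(
                    brute_force_path_rate(net, conc, s, t), rel=1e-10, abs=1e-300
                )

    def test_unlinked_pairs_are_exactly_zero(self, pdl1):
        conc = equilibrium_distribution(pdl1, accessible=("S1", "S2"))
        table = path_rates(pdl1, conc)
        assert table.path(state_id="S1", transition_id="T2") == 0.0


class TestStateRates:
    def test_exact_row_sum(self, random_net_factory):
        net = random_net_factory(3, n_states=4)
        rng = np.random.default_rng(5)
        conc = ConcentrationState.for_network(net, rng.uniform(0, 1, net.n_states))
        table = path_rates(net, conc)
        # independent summation oracle over the path-rate formula
        expected = [
            sum(brute_force_path_rate(net, conc, s, t) for t in range(net.n_transitions))
            for s in range(net.n_states)
        ]
        assert np.allclose(state_rates(table), expected, rtol=1e-10)
        assert np.array_equal(state_rates(table), table.path_rates.sum(axis=1))

    def test_single_path_network(self):
        net = SelfAssemblyNetwork(
            states=(StableState("S1", 1, -1.0),),
            transitions=(TransitionState("T1", 1.0, (("S1", 1.0),)),),
        )
        conc = ConcentrationState.for_network(net, [0.7])
        table = path_rates(net, conc)
        assert state_rates(table)[0] == table.path_rates[0, 0]


class TestEquilibriumFlux:
    def test_monomer_form_independent_of_state_energy(self):
        """Two states of different depth feeding one barrier: the one-way
        monomer flux depends only on the barrier energy and A."""
        net = SelfAssemblyNetwork(
            states=(StableState("S1", 2, -8.0), StableState("S2", 3, -3.0)),
            transitions=(TransitionState("T1", 1.5, (("S1", 1.0), ("S2", 1.0))),),
        )
        flux = equilibrium_flux(net, monomer_form=True).path_rates
        assert flux[0, 0] == pytest.approx(flux[1, 0], rel=1e-12)

    def test_flux_ratio_between_barriers_is_boltzmann(self, pdl1):
        flux = equilibrium_flux(pdl1, accessible=("S1", "S2"), monomer_form=True)
        g = dict(zip(pdl1.transition_ids, pdl1.g_transition))
        ratio = flux.path("S2", "T2") / flux.path("S2", "T1")
        assert ratio == pytest.approx(np.exp(-(g["T2"] - g["T1"]) / RT310), rel=1e-10)

    def test_high_barrier_limit_vanishes(self):
        net = SelfAssemblyNetwork(
            states=(StableState("S1", 1, 0.0),),
            transitions=(TransitionState("T1", 500.0, (("S1", 1.0),)),),
        )
        assert equilibrium_flux(net).path_rates[0, 0] == pytest.approx(0.0, abs=1e-200)


class TestKineticMatrix:
    @pytest.mark.parametrize("seed", range(8))
    def test_monomer_count_is_left_null_vector(self, random_net_factory, seed):
        net = random_net_factory(seed)
        system = kinetic_matrix(net)
        residual = net.nu @ system.matrix
        scale = max(np.abs(system.matrix).max(), 1e-300)
        assert np.abs(residual).max() <= 1e-12 * scale * net.n_states

    @pytest.mark.parametrize("seed", range(8))
    def test_matrix_times_c_equals_state_rates(self, random_net_factory, seed):
        net = random_net_factory(seed)
        system = kinetic_matrix(net)
        rng = np.random.default_rng(seed)
        cs = rng.uniform(0, 2, net.n_states)
        conc = ConcentrationState.for_network(net, cs)
        direct = state_rates(path_rates(net, conc))
        assert np.allclose(system.matrix @ cs, direct, rtol=1e-9, atol=1e-300)

    def test_equilibrium_is_null_vector(self, random_net_factory):
        net = random_net_factory(11)
        system = kinetic_matrix(net)
        c_eq = equilibrium_distribution(net).cs
        scale = np.abs(system.matrix).max() * c_eq.max()
        assert np.abs(system.matrix @ c_eq).max() <= 1e-10 * scale

    def test_self_loop_single_state_is_zero_matrix(self):
        net = SelfAssemblyNetwork(
            states=(StableState("S1", 1, -1.0),),
            transitions=(TransitionState("T1", 2.0, (("S1", 1.0),)),),
        )
        assert np.allclose(kinetic_matrix(net).matrix, 0.0, atol=1e-300)


class TestEvolve:
    def test_equilibrium_start_stays_constant(self, random_net_factory):
        net = random_net_factory(2)
        system = kinetic_matrix(net)
        c_eq = equilibrium_distribution(net).cs
        course = evolve(system, c_eq, np.linspace(0, 50, 7))
        for snap in course:
            assert np.allclose(snap.cs, c_eq, rtol=1e-8, atol=1e-14)

    def test_initial_condition_reproduced(self, random_net_factory):
        net = random_net_factory(4)
        system = kinetic_matrix(net)
        rng = np.random.default_rng(4)
        c0 = rng.uniform(0, 1, net.n_states)
        course = evolve(system, c0, [0.0, 1.0])
        assert np.allclose(course[0].cs, c0, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_stiff_ode_oracle(self, random_net_factory, seed):
        net = random_net_factory(seed, n_states=min(6, 3 + seed % 4))
        system = kinetic_matrix(net)
        rng = np.random.default_rng(seed + 7)
        c0 = rng.uniform(0.1, 1, net.n_states)
        times = np.linspace(0.0, 10.0, 6)
        course = evolve(system, c0, times)
        sol = solve_ivp(
            lambda _, c: system.matrix @ c,
            (0, times[-1]),
            c0,
            method="LSODA",
            t_eval=times,
            rtol=1e-12,
            atol=1e-14,
        )
        ours = np.array([s.cs for s in course])
        scale = np.abs(sol.y.T).max()
        assert np.abs(ours - sol.y.T).max() <= 1e-6 * scale

    @pytest.mark.parametrize("seed", range(6))
    def test_monomer_total_conserved(self, random_net_factory, seed):
        net = random_net_factory(seed)
        system = kinetic_matrix(net)
        rng = np.random.default_rng(seed)
        c0 = rng.uniform(0, 1, net.n_states)
        total0 = float(net.nu @ c0)
        for snap in evolve(system, c0, np.linspace(0, 20, 9)):
            assert snap.total_monomer == pytest.approx(total0, rel=1e-8)

    def test_long_time_limit_reaches_equilibrium(self, pdl1):
        """From the pre-drug distribution with S3 opened up, the trajectory
        relaxes to the full-network Boltzmann distribution."""
        system = kinetic_matrix(pdl1)
        c0 = equilibrium_distribution(pdl1, accessible=("S1", "S2")).cs
        c_eq = equilibrium_distribution(pdl1).cs
        # eigenvalues: one zero (conservation), the rest strictly negative
        lams = np.sort(system.eigenvalues.real)
        assert lams[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(lams[:-1] < 0)
        t_long = 60.0 / np.abs(lams[lams < -1e-15]).min()
        final = evolve(system, c0, [t_long])[0]
        assert np.allclose(final.cs, c_eq, rtol=1e-6, atol=1e-12)

    def test_bad_inputs_rejected(self, two_state_net):
        system = kinetic_matrix(two_state_net)
        with pytest.raises(ValueError):
            evolve(system, [1.0], [0.0])
        with pytest.raises(ValueError):
            evolve(system, [1.0, 1.0], [-1.0, 0.0])


class TestDominantPath:
    def test_symmetric_two_path_network_ties(self):
        net = SelfAssemblyNetwork(
            states=(StableState("S1", 1, -2.0), StableState("S2", 1, -2.0)),
            transitions=(
                TransitionState("T1", 1.0, (("S1", 1.0), ("S2", 1.0))),
            ),
        )
        conc = ConcentrationState.for_network(net, [1.0, 0.0])
        ranking = dominant_path(net, conc)
        assert ranking[0].rank == ranking[1].rank == 1

    def test_all_zero_rates_yield_empty_ranking(self, two_state_net):
        conc = ConcentrationState.for_network(two_state_net, [0.0, 0.0])
        assert dominant_path(two_state_net, conc) == []

    def test_raising_a_barrier_flips_the_ranking(self, pdl1):
        """Monotonicity: pushing the insertion barrier far above the
        separation barrier makes the separation paths dominate."""
        conc = equilibrium_distribution(pdl1, accessible=("S1", "S2"))
        first = dominant_path(pdl1, conc)[0]
        assert (first.state_id, first.transition_id) == ("S2", "T2")

        lifted = SelfAssemblyNetwork(
            states=pdl1.states,
            transitions=tuple(
                TransitionState(t.id, 8.0, t.links) if t.id == "T2" else t
                for t in pdl1.transitions
            ),
            temperature=pdl1.temperature,
            c0_monomer=pdl1.c0_monomer,
        )
        flipped = dominant_path(lifted, equilibrium_distribution(lifted, ("S1", "S2")))
        assert flipped[0].transition_id == "T1"
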