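import numpy as np
import pytest

from phic31rec import (HOUR, Variant, algebraic_equilibrium, build_network,
                       concentration_scan, equilibrium_composition,
                       fraction_recombinant, initial_state, simulate,
                       state_fraction_recombinant)


def test_no_integrase_means_no_recombination(ref_network):
    c0 = initial_state(ref_network, "pPB", 10.0, 0.0, 0.0)
    sim = simulate(ref_network, c0, [60.0, HOUR, 3 * HOUR])
    assert np.all(fraction_recombinant(sim, "pPB") == 0.0)


def test_fraction_zero_at_time_zero(ref_network):
    c0 = initial_state(ref_network, "pLR", 10.0, 400.0, 800.0)
    sim = simulate(ref_network, c0, [0.0, 60.0])
    frac = fraction_recombinant(sim, "pLR")
    assert frac[0] == 0.0
    assert frac[1] > 0.0


def test_zero_dna_fraction_flagged(ref_network):
    c0 = initial_state(ref_network, "pPB", 0.0, 400.0, 0.0)
    sim = simulate(ref_network, c0, [60.0])
    with pytest.raises(ValueError, match="zero total DNA"):
        fraction_recombinant(sim, "pPB")


def test_times_validation(ref_network):
    c0 = initial_state(ref_network, "pPB", 10.0, 400.0, 0.0)
    with pytest.raises(ValueError):
        simulate(ref_network, c0, [10.0, 5.0])
    with pytest.raises(ValueError):
        simulate(ref_network, c0, [-1.0, 5.0])


def test_conservation_along_trajectory(ref_network):
    c0 = initial_state(ref_network, "pLR", 10.0, 400.0, 800.0)
    sim = simulate(ref_network, c0, np.linspace(10.0, 3 * HOUR, 25))
    ref = ref_network.conservation @ c0
    got = sim.conc @ ref_network.conservation.T
    assert np.max(np.abs(got - ref) / ref) < 1e-6
    assert sim.conc.min() >= 0.0


def test_simulation_is_deterministic(ref_network):
    c0 = initial_state(ref_network, "pPB", 10.0, 400.0, 0.0)
    a = simulate(ref_network, c0, [HOUR, 2 * HOUR]).conc
    b = simulate(ref_network, c0, [HOUR, 2 * HOUR]).conc
    assert np.array_equal(a, b)


def test_long_time_ode_matches_algebraic_oracle(reduced_network):
    """Reduced -RDF network: integration endpoint vs formation-constant solve."""
    c0 = initial_state(reduced_network, "pPB", 10.0, 400.0, 0.0)
    sim = simulate(reduced_network, c0, [1e8], rtol=1e-10, atol=1e-14)
    oracle = algebraic_equilibrium(reduced_network, c0)
    live = oracle > 1e-9
    rel = np.abs(sim.conc[-1, live] - oracle[live]) / oracle[live]
    assert np.max(rel) < 1e-6


def test_equilibrium_polish_and_detailed_balance(ref_network):
    c0 = initial_state(ref_network, "pPB", 10.0, 400.0, 800.0)
    eq = equilibrium_composition(ref_network, c0, substrate="pPB")
    assert eq.max_rhs < 1e-10
    assert eq.max_step_flux < 1e-12   # detailed balance, reversible network
    assert 0.0 < eq.fraction_recombinant < 1.0


def test_equilibrium_is_path_independent(ref_network):
    """pPB-start and pLR-start with identical totals share one equilibrium."""
    a = equilibrium_composition(
        ref_network, initial_state(ref_network, "pPB", 10.0, 400.0, 0.0))
    b = equilibrium_composition(
        ref_network, initial_state(ref_network, "pLR", 10.0, 400.0, 0.0))
    live = a.conc > 1e-9
    rel = np.abs(a.conc[live] - b.conc[live]) / a.conc[live]
    assert np.max(rel) < 1e-6


def test_scan_zero_point_and_inhibition_decline(ref_params):
    df = concentration_scan(Variant.MODEL1_PLASMID, ref_params, "pPB",
                            [0.0, 400.0, 3200.0], [0.0])
    assert df[df.int_total_nM == 0.0].fraction_recombinant.iloc[0] == 0.0
    y400 = df[df.int_total_nM == 400.0].fraction_recombinant.iloc[0]
    y3200 = df[df.int_total_nM == 3200.0].fraction_recombinant.iloc[0]
    assert y3200 < y400  # tetramer inhibition at high integrase


def test_rdf_saturation_plateau(ref_params):
    """Yield at RDF:int = 2 within 2% of RDF:int = 4 (int2rdf2 saturated)."""
    df = concentration_scan(Variant.MODEL1_PLASMID, ref_params, "pLR",
                            [400.0], [800.0, 1600.0])
    y2, y4 = df.fraction_recombinant.to_numpy()
    assert abs(y4 - y2) / y2 < 0.02


def test_linear_substrate_simulation(linear_params):
    net = build_network(Variant.MODEL1_LINEAR, linear_params)
    c0 = initial_state(net, "linear_PB", 10.0, 400.0, 0.0)
    sim = simulate(net, c0, [HOUR, 3 * HOUR])
    frac = fraction_recombinant(sim, "linear_PB")
    assert 0.0 < frac[0] < frac[1] < 1.0
    # attL and attR products are created in lockstep
    attL = sum(sim.conc[-1, net.index[s]] for s in net.species
               if s.startswith("attL:"))
    attR = sum(sim.conc[-1, net.index[s]] for s in net.species
               if s.startswith("attR:"))
    assert attL == pytest.approx(attR, rel=1e-9)


def test_state_fraction_matches_trajectory_readout(ref_network):
    c0 = initial_state(ref_network, "pPB", 10.0, 400.0, 0.0)
    sim = simulate(ref_network, c0, [HOUR])
    a = fraction_recombinant(sim, "pPB")[-1]
    b = state_fraction_recombinant(ref_network, sim.conc[-1], "pPB")
    assert a == pytest.approx(b)
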