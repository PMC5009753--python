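import numpy as np
import pytest

from phic31rec import (Variant, algebraic_equilibrium, build_network,
                       initial_state)
from phic31rec.network import ReactionNetwork, Step

from conftest import toy_params

MAIN_KINDS = {"b1", "b2", "b3", "b4", "s1", "s2", "s3", "s4", "r1", "r2",
              "mod", "modr"}


def test_model1_step_kinds_match_scheme(ref_network):
    kinds = {st.kind for st in ref_network.steps}
    assert kinds & MAIN_KINDS == MAIN_KINDS
    assert kinds - MAIN_KINDS == {"ii", "ir", "inh"}


def test_model0_lacks_stable_synapse_species(model0_params, ref_network):
    net0 = build_network(Variant.MODEL0_PLASMID, model0_params)
    assert "LR-int_s2" not in net0.index
    assert "PB-int-rdf_s2" not in net0.index
    assert {st.kind for st in net0.steps} & {"mod", "modr"} == set()
    # otherwise the same species inventory as Model 1
    assert set(ref_network.species) - set(net0.species) == {
        "LR-int_s2", "PB-int-rdf_s2"}


@pytest.mark.parametrize("variant,n_laws,n_moieties", [
    (Variant.MODEL1_PLASMID, 3, 3),   # plasmid, integrase, RDF
    (Variant.MODEL0_PLASMID, 3, 3),
    # linear: P-fragment, B-fragment, integrase, RDF, plus the pairing
    # invariant (every synapse holds one P-type and one B-type fragment,
    # so the attP-minus-attB occupancy difference never changes)
    (Variant.MODEL1_LINEAR, 5, 4),
])
def test_stoichiometry_rank_equals_species_minus_conservation_laws(
        variant, n_laws, n_moieties, ref_params, model0_params, linear_params):
    params = {Variant.MODEL1_PLASMID: ref_params,
              Variant.MODEL0_PLASMID: model0_params,
              Variant.MODEL1_LINEAR: linear_params}[variant]
    net = build_network(variant, params)
    S = net.stoichiometry
    assert np.linalg.matrix_rank(S) == len(net.species) - n_laws
    assert net.conservation.shape[0] == n_moieties
    assert np.abs(net.conservation @ S).max() == 0.0


def test_every_step_is_reversible_and_at_most_second_order(ref_network):
    for st in ref_network.steps:
        assert st.kf > 0 and st.kr > 0
        assert sum(c for _, c in st.reactants) <= 2
        assert sum(c for _, c in st.products) <= 2


def test_statistical_binding_factors(ref_network):
    by_name = {st.name: st for st in ref_network.steps}
    first = by_name["b1[PB:ee+i]"]
    second = by_name["b1[PB:ei+i]"]
    # first dimer binds at 2kf / releases at kr; second at kf / 2kr
    assert first.kf == pytest.approx(2.0 * second.kf)
    assert second.kr == pytest.approx(2.0 * first.kr)
    # per-site equilibrium constant preserved across the pair
    K = ref_network.params.K["b1"]
    assert first.K_eff * second.K_eff == pytest.approx(K * K)


def test_build_rejects_variant_mismatch(ref_params):
    with pytest.raises(ValueError, match="parameter set is for"):
        build_network(Variant.MODEL0_PLASMID, ref_params)


def test_build_rejects_unclosed_without_flag(ref_params):
    broken = ref_params.with_updates(K={"r1": ref_params.K["r1"] * 2})
    with pytest.raises(ValueError, match="Wegscheider"):
        build_network(Variant.MODEL1_PLASMID, broken)
    net = build_network(Variant.MODEL1_PLASMID, broken, allow_unclosed=True)
    with pytest.raises(ValueError, match="not thermodynamically closed"):
        net.formation_log_constants()


def test_rhs_zero_state_is_fixed_point(ref_network):
    z = np.zeros(len(ref_network.species))
    assert np.all(ref_network.rhs(0.0, z) == 0.0)


def test_single_step_detailed_balance():
    """A+B <-> C with kf = kr = 1 and all concentrations 1 has zero flux."""
    p = toy_params()
    net = ReactionNetwork(
        Variant.MODEL1_PLASMID, p, ["A", "B", "C"],
        {"A": {"a": 1}, "B": {"b": 1}, "C": {"a": 1, "b": 1}},
        [Step("bind", "b1", (("A", 1), ("B", 1)), (("C", 1),), 1.0, 1.0)])
    c = np.ones(3)
    assert np.all(net.fluxes(c) == 0.0)
    assert np.all(net.rhs(0.0, c) == 0.0)


def test_rhs_vanishes_at_algebraic_equilibrium(ref_network):
    c0 = initial_state(ref_network, "pPB", 10.0, 400.0, 800.0)
    eq = algebraic_equilibrium(ref_network, c0)
    assert np.max(np.abs(ref_network.rhs(0.0, eq))) < 1e-10


def test_jacobian_matches_finite_differences(ref_network):
    rng = np.random.default_rng(0)
    c = rng.uniform(0.1, 5.0, size=len(ref_network.species))
    J = ref_network.jacobian(0.0, c)
    eps = 1e-6
    for k in rng.choice(len(c), size=6, replace=False):
        dc = np.zeros_like(c)
        dc[k] = eps
        fd = (ref_network.rhs(0.0, c + dc) - ref_network.rhs(0.0, c - dc)) / (2 * eps)
        assert np.allclose(J[:, k], fd, rtol=1e-5, atol=1e-7)


def test_initial_state_examples(ref_network):
    c = initial_state(ref_network, "pPB", 10.0, 400.0, 0.0)
    assert c[ref_network.index["PB:ee"]] == 10.0
    assert c[ref_network.index["int"]] == 400.0
    assert c.sum() == 410.0  # nothing else populated
    c2 = initial_state(ref_network, "pLR", 10.0, 400.0, 800.0)
    assert c2[ref_network.index["LR:ee"]] == 10.0
    assert c2[ref_network.index["rdf"]] == 800.0
    with pytest.raises(ValueError, match=">= 0"):
        initial_state(ref_network, "pPB", -1.0, 400.0, 0.0)
    with pytest.raises(ValueError, match="substrate"):
        initial_state(ref_network, "pXX", 10.0, 400.0, 0.0)


def test_conservation_counts_monomers(ref_network):
    # a synapse carries 4 integrase monomers, a tetramer-blocked site 4, etc.
    i = ref_network.moieties.index("int")
    A = ref_network.conservation
    assert A[i, ref_network.index["LR-int-rdf_s"]] == 4
    assert A[i, ref_network.index["PB:tt"]] == 8
    r = ref_network.moieties.index("rdf")
    assert A[r, ref_network.index["int2rdf1"]] == 1
    assert A[r, ref_network.index["PB-int-rdf_s2"]] == 4


def test_step_table_roundtrips_constants(ref_network):
    df = ref_network.step_table()
    assert set(df.columns) >= {"step", "kind", "reactants", "products",
                               "kf", "kr", "K_eff"}
    assert len(df) == len(ref_network.steps)
    row = df[df.step == "r1"].iloc[0]
    assert row.K_eff == pytest.approx(ref_network.params.K["r1"])
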