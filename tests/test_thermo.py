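import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phic31rec import (Variant, close_parameters, compensated_perturbation,
                       energy_landscape, wegscheider_residuals)
from phic31rec.params import ParameterSet, step_names
from phic31rec.thermo import DEFAULT_T, R_KJ, step_free_energy

from conftest import toy_params

log_const = st.floats(min_value=-3.0, max_value=3.0)


def random_params(draw_values):
    names = step_names(Variant.MODEL1_PLASMID)
    K = {s: 10.0 ** v for s, v in zip(names, draw_values)}
    kf = {s: 10.0 ** v for s, v in zip(names, draw_values[len(names):])}
    return ParameterSet(Variant.MODEL1_PLASMID, K, kf)


def test_close_parameters_zeroes_residuals_and_is_idempotent():
    p = toy_params(K_r1=0.7, K_mod=3.0)
    closed = close_parameters(p)
    assert max(wegscheider_residuals(closed)) < 1e-12
    again = close_parameters(closed)
    assert again.K == closed.K and again.kf == closed.kf


def test_closing_via_Ks2_compensates_Kr1_in_log_space():
    # desynapsis sign convention: K_s2 sits on the same side of the closure
    # product as K_r1, so doubling K_r1 halves the re-derived K_s2
    base = close_parameters(toy_params())
    doubled = close_parameters(
        base.with_updates(K={"r1": base.K["r1"] * 2.0}))
    assert doubled.K["s2"] == pytest.approx(base.K["s2"] / 2.0)
    # forward rates untouched, reverse rate of s2 rederived
    assert doubled.kf == base.kf
    assert doubled.kr("s2") == pytest.approx(2.0 * base.kr("s2"))


def test_residual_is_signed_log_sum():
    base = close_parameters(toy_params())
    broken = base.with_updates(K={"r1": base.K["r1"] * 2.0})
    res = wegscheider_residuals(broken)
    assert res[0] == pytest.approx(math.log(2.0))
    assert res[1] < 1e-12


def test_compensated_perturbation_contract():
    base = close_parameters(toy_params())
    pert = compensated_perturbation(base, "K_r1", 2.0, "K_s2")
    assert max(wegscheider_residuals(pert)) < 1e-12
    assert pert.K["r1"] == pytest.approx(2.0 * base.K["r1"])
    assert pert.kf == base.kf
    # invertible
    back = compensated_perturbation(pert, "K_r1", 0.5, "K_s2")
    for s in base.K:
        assert back.K[s] == pytest.approx(base.K[s])
    # identity fold
    same = compensated_perturbation(base, "K_modr", 1.0, "K_s4")
    assert same.K == pytest.approx(base.K)


@pytest.mark.parametrize("target,comp", [
    ("K_r1", "K_r1"),       # target == compensator
    ("K_ii", "K_s2"),       # target off both paths
    ("K_r1", "K_s4"),       # different paths
])
def test_compensated_perturbation_rejects_bad_pairs(target, comp):
    base = close_parameters(toy_params())
    with pytest.raises(ValueError):
        compensated_perturbation(base, target, 2.0, comp)


def test_unimolecular_step_free_energy_closed_form():
    # K_eq = 10, Gamma = 1, T = 303.15 K -> dG = -RT ln 10 = -5.80 kJ/mol
    assert step_free_energy(10.0, 1.0, 303.15) == pytest.approx(
        -R_KJ * 303.15 * math.log(10.0))
    assert step_free_energy(10.0, 1.0, 303.15) == pytest.approx(-5.80, abs=0.01)
    # Gamma = K_eq -> 0 by definition
    assert step_free_energy(3.7, 3.7) == 0.0


def test_landscape_cumulative_zero_and_sign_pattern(ref_params):
    el = energy_landscape(ref_params)
    assert abs(el.cumulative("noRDF")) < 1e-6
    assert abs(el.cumulative("RDF")) < 1e-6
    steps = el.steps("noRDF")
    assert steps["b1"] < 0 and steps["s1"] < 0   # favourable entry
    assert steps["s2"] > 0 and steps["b2"] > 0   # unfavourable product release


def test_landscape_temperature_linearity(ref_params):
    el1 = energy_landscape(ref_params, temperature_K=300.0)
    el2 = energy_landscape(ref_params, temperature_K=600.0)
    for (p1, k1, dg1), (p2, k2, dg2) in zip(el1.rows, el2.rows):
        assert (p1, k1) == (p2, k2)
        assert dg2 == pytest.approx(2.0 * dg1)


def test_landscape_rejects_nonpositive_references(ref_params):
    with pytest.raises(ValueError):
        energy_landscape(ref_params, ref_dna_nM=0.0)


@settings(max_examples=25, deadline=None)
@given(st.lists(log_const, min_size=30, max_size=30))
def test_closure_iff_zero_cumulative_landscape(values):
    """Residuals and pathway-cumulative dG vanish together (dG = -RT log)."""
    p = random_params(values)
    el = energy_landscape(p, temperature_K=DEFAULT_T)
    res = wegscheider_residuals(p)
    for path, r in zip(("noRDF", "RDF"), res):
        assert abs(el.cumulative(path)) == pytest.approx(
            R_KJ * DEFAULT_T * r, abs=1e-9)
    closed = close_parameters(p)
    el_c = energy_landscape(closed)
    assert max(wegscheider_residuals(closed)) < 1e-12
    assert abs(el_c.cumulative("noRDF")) < 1e-9
    assert abs(el_c.cumulative("RDF")) < 1e-9
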