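import numpy as np
import pytest

from phic31rec import (ParameterSet, Variant, build_network,
                       close_parameters, reference_parameters)


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters(Variant.MODEL1_PLASMID)


@pytest.fixture(scope="session")
def model0_params():
    return reference_parameters(Variant.MODEL0_PLASMID)


@pytest.fixture(scope="session")
def linear_params():
    return reference_parameters(Variant.MODEL1_LINEAR)


@pytest.fixture(scope="session")
def ref_network(ref_params):
    return build_network(Variant.MODEL1_PLASMID, ref_params)


@pytest.fixture(scope="session")
def reduced_network(ref_params):
    """-RDF-only, inhibition-free network for oracle cross-checks."""
    return build_network(Variant.MODEL1_PLASMID, ref_params,
                         include_rdf=False, include_inhibition=False)


def toy_params(variant=Variant.MODEL1_PLASMID, **overrides) -> ParameterSet:
    """Small hand-made closed parameter set for structural tests."""
    K = dict(ii=25.0, ir=5.0, b1=0.05, b2=0.1, b3=0.05, b4=0.05,
             s1=10.0, s2=1.0, s3=10.0, s4=1.0, r1=0.5, r2=0.5,
             mod=2.0, modr=2.0, inh=5e-4)
    kf = dict(ii=0.01, ir=0.01, b1=0.01, b2=0.01, b3=0.01, b4=0.01,
              s1=0.01, s2=1e-6, s3=0.01, s4=1e-6, r1=0.005, r2=0.005,
              mod=0.005, modr=0.005, inh=0.001)
    if not Variant(variant).is_model1:
        K.pop("mod"), K.pop("modr"), kf.pop("mod"), kf.pop("modr")
    for name, v in overrides.items():
        tab, step = name.split("_", 1)
        (K if tab == "K" else kf)[step] = v
    return close_parameters(ParameterSet(Variant(variant), K, kf))
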