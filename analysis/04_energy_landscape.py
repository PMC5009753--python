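"""Per-step free-energy landscapes of Model 0 and Model 1.

Finding: in Model 1 the favourable binding/synapsis entry steps (b1, s1 /
b3, s3) and the modification steps (mod, modr) are balanced by unfavourable
desynapsis (s2, s4) and protein release (b2, b4), so the cumulative change
along each full pathway is zero, as energy conservation between
isoenergetic substrate and product DNA requires.  Model 0 instead
concentrates the entire compensation in its single dissociation step,
which is why it needs an inflated attL/attR binding affinity.

Writes results/landscape_model{0,1}.csv and .json; reference state 10 nM
DNA species, 200 nM unbound protein complexes, 303.15 K.
"""

import pathlib

from phic31rec import (Variant, energy_landscape, reference_parameters,
                       wegscheider_residuals)
from phic31rec.io_utils import write_csv_with_meta

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    for variant, name in ((Variant.MODEL1_PLASMID, "model1"),
                          (Variant.MODEL0_PLASMID, "model0")):
        params = reference_parameters(variant)
        el = energy_landscape(params)
        res = wegscheider_residuals(params)
        write_csv_with_meta(el.to_dataframe(),
                            RESULTS / f"landscape_{name}.csv",
                            {"residual_noRDF": res[0], "residual_RDF": res[1],
                             "temperature_K": el.temperature_K}, force=True)
        (RESULTS / f"landscape_{name}.json").write_text(el.to_json())
        steps = el.steps("noRDF")
        print(f"{name}: cumulative noRDF={el.cumulative('noRDF'):+.2e} "
              f"RDF={el.cumulative('RDF'):+.2e} kJ/mol")
        print("  noRDF per-step dG (kJ/mol):",
              {k: round(v, 2) for k, v in steps.items()})


if __name__ == "__main__":
    main()
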