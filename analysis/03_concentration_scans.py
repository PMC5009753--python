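"""3-h endpoint yields over integrase and RDF concentration grids (Model 1).

Findings: the P x B (-RDF) yield rises with integrase, peaks around
200-400 nM and declines slightly at higher concentrations (tetramer
blocking of att sites); the L x R (+RDF) yield grows with the RDF:integrase
ratio and plateaus once RDF matches integrase (1:1 stoichiometry of the
productive int2rdf2 unit).

Writes results/scan_PxB_noRDF.csv and results/scan_LxR_RDF.csv.
"""

import pathlib

from phic31rec import Variant, concentration_scan, reference_parameters
from phic31rec.io_utils import write_csv_with_meta
from phic31rec.synth import INT_GRID, RDF_RATIOS

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    params = reference_parameters(Variant.MODEL1_PLASMID)
    ints = sorted(INT_GRID) + [1600.0]

    pxb = concentration_scan(Variant.MODEL1_PLASMID, params, "pPB",
                             ints, [0.0])
    write_csv_with_meta(pxb, RESULTS / "scan_PxB_noRDF.csv",
                        {"params_hash": params.content_hash()}, force=True)
    best = pxb.loc[pxb.fraction_recombinant.idxmax()]
    top = pxb.loc[pxb.int_total_nM.idxmax()]
    print(f"PxB(-RDF): optimum {best.fraction_recombinant:.3f} at "
          f"{best.int_total_nM:g} nM; {top.fraction_recombinant:.3f} at "
          f"{top.int_total_nM:g} nM (high-integrase inhibition)")

    # RDF grid is a ratio grid, so build it per integrase concentration
    import pandas as pd
    frames = []
    for int_t in sorted(INT_GRID):
        scan = concentration_scan(Variant.MODEL1_PLASMID, params, "pLR",
                                  [int_t], [int_t * r for r in RDF_RATIOS])
        frames.append(scan)
    lxr = pd.concat(frames, ignore_index=True)
    lxr["rdf_ratio"] = lxr.rdf_total_nM / lxr.int_total_nM
    write_csv_with_meta(lxr, RESULTS / "scan_LxR_RDF.csv",
                        {"params_hash": params.content_hash()}, force=True)
    at400 = lxr[lxr.int_total_nM == 400.0].set_index("rdf_ratio")
    print("LxR(+RDF) at 400 nM integrase, yield by RDF:int ratio:",
          {r: round(v, 3) for r, v in
           at400.fraction_recombinant.items()})


if __name__ == "__main__":
    main()
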