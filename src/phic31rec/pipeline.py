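"""One-shot reproducible pipeline: simulate, scan, landscape, equilibria.

`run_pipeline` ties the tested operations into a single deterministic
output bundle under one directory, with every file carrying a metadata
header (version, seed, tolerances, parameter hash).  Identical configs
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_utils import write_csv_with_meta
from .network import build_network, initial_state
from .params import Variant, load_parameters, reference_parameters
from .simulate import (HOUR, concentration_scan, equilibrium_composition,
                       fraction_recombinant, simulate)
from .thermo import energy_landscape, wegscheider_residuals

log = logging.getLogger("phic31rec")


@dataclass
class RunConfig:
    variant: Variant = Variant.MODEL1_PLASMID
    params_path: Optional[str] = None      # None -> shipped reference set
    out_dir: str = "phic31rec_run"
    seed: int = 1
    dna_conc: float = 10.0
    int_total: float = 400.0
    rdf_total: float = 800.0
    t_max_h: float = 3.0
    rtol: float = 1e-8
    atol: float = 1e-12
    force: bool = False
    log_level: str = "INFO"

    def validate(self):
        for name in ("dna_conc", "int_total", "rdf_total", "t_max_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"RunConfig.{name} must be >= 0, "
                                 f"got {getattr(self, name)}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("RunConfig.rtol/atol must be positive")


def run_pipeline(config: RunConfig) -> dict:
    """Run the standard bundle; returns {output name: file path}."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    variant = Variant(config.variant)
    params = (load_parameters(config.params_path) if config.params_path
              else reference_parameters(variant))
    if params.variant is not variant:
        raise ValueError(f"parameter file is for {params.variant.value}, "
                         f"config asks for {variant.value}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "variant": variant.value,
            "rtol": config.rtol, "atol": config.atol,
            "params_hash": params.content_hash()}
    paths = {}

    def save(df, name, extra=None):
        p = out / name
        write_csv_with_meta(df, p, {**meta, **(extra or {})},
                            force=config.force)
        paths[name] = str(p)

    # parameter echo
    p_echo = out / "parameters.yaml"
    if p_echo.exists() and not config.force:
        raise FileExistsError(f"{p_echo} exists; set force=True")
    from .params import save_parameters
    save_parameters(params, p_echo)
    paths["parameters.yaml"] = str(p_echo)

    net = build_network(variant, params)
    log.info("network: %d species, %d steps", len(net.species), len(net.steps))
    save(net.step_table(), "steps.csv")

    # time courses of the four reaction arms (or the linear P x B arm)
    times = np.linspace(0.0, config.t_max_h * HOUR, 181)
    times[0] = 1e-3
    rows = []
    arms = ([("linear_PB", config.int_total, 0.0)] if variant.is_linear else
            [("pPB", config.int_total, 0.0),
             ("pLR", config.int_total, 0.0),
             ("pLR", config.int_total, config.rdf_total),
             ("pPB", config.int_total, config.rdf_total)])
    import pandas as pd
    eq_report = {}
    for sub, int_t, rdf_t in arms:
        c0 = initial_state(net, sub, config.dna_conc, int_t, rdf_t)
        sim = simulate(net, c0, times, rtol=config.rtol, atol=config.atol)
        frac = fraction_recombinant(sim, sub)
        for t, f in zip(times, frac):
            rows.append({"substrate": sub, "int_total_nM": int_t,
                         "rdf_total_nM": rdf_t, "time_h": t / HOUR,
                         "fraction_recombinant": f})
        eq = equilibrium_composition(net, c0, substrate=sub)
        eq_report[f"{sub}_int{int_t:g}_rdf{rdf_t:g}"] = {
            "fraction_recombinant": eq.fraction_recombinant,
            "max_rhs_nM_per_s": eq.max_rhs,
            "max_step_flux_nM_per_s": eq.max_step_flux,
        }
    save(pd.DataFrame(rows), "timecourses.csv")

    eq_path = out / "equilibria.json"
    if eq_path.exists() and not config.force:
        raise FileExistsError(f"{eq_path} exists; set force=True")
    eq_path.write_text(json.dumps({"meta": meta, "equilibria": eq_report},
                                  indent=2, sort_keys=True))
    paths["equilibria.json"] = str(eq_path)

    # landscape + closure audit
    el = energy_landscape(params)
    save(el.to_dataframe(), "landscape.csv",
         {"residuals_log": wegscheider_residuals(params)})

    if not variant.is_linear:
        scan = concentration_scan(variant, params, "pPB",
                                  [25, 50, 100, 200, 400, 800], [0.0],
                                  t_hours=config.t_max_h,
                                  dna_conc=config.dna_conc)
        save(scan, "scan_pPB_noRDF.csv")
    return paths
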