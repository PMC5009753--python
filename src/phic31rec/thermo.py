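"""Energy conservation across the recombination pathways.

Because free substrate and free product DNA are isoenergetic (linear
substrates; topology effects deliberately out of scope), the product of the
equilibrium constants along each full pathway -- free pPB through to free
pLR with the same proteins released, and its +RDF mirror -- must equal one
(Wegscheider's condition), equivalently the per-step Gibbs free-energy
changes must sum to zero.

The closure products, with s2/s4 written as desynapsis constants::

    -RDF:  K_b1^2 * K_s1 * K_r1 * [K_mod] * K_s2 / K_b2^2  = 1
    +RDF:  K_b3^2 * K_s3 * K_r2 * [K_modr] * K_s4 / K_b4^2 = 1

(mod/modr only in Model 1).  The identical-sites statistical binding
factors (2:1) cancel around each path and are excluded from the
bookkeeping.  Free energies use dG = RT ln(Gamma/K_eq) with every
DNA-containing species at a reference 10 nM and every unbound protein
complex (int2 or int2rdf2) at 200 nM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .params import ParameterSet, Variant

#: gas constant, kJ/(mol*K)
R_KJ = 8.314e-3

#: default temperature: the reactions were incubated at 30 C
DEFAULT_T = 303.15

# signed exponent of each K around the two closure paths
_PATH_NO_RDF = {"b1": 2, "s1": 1, "r1": 1, "mod": 1, "s2": 1, "b2": -2}
_PATH_RDF = {"b3": 2, "s3": 1, "r2": 1, "modr": 1, "s4": 1, "b4": -2}


def _paths(variant: Variant) -> Tuple[Dict[str, int], Dict[str, int]]:
    if variant.is_model1:
        return dict(_PATH_NO_RDF), dict(_PATH_RDF)
    no = {k: v for k, v in _PATH_NO_RDF.items() if k != "mod"}
    yes = {k: v for k, v in _PATH_RDF.items() if k != "modr"}
    return no, yes


def wegscheider_residuals(params: ParameterSet) -> Tuple[float, float]:
    """Absolute log-space deviation from closure of the two pathways."""
    a, b = params.closure_log_products()
    return (abs(a), abs(b))


def close_parameters(params: ParameterSet,
                     derived_constant_names: Sequence[str] = ("K_s2", "K_s4"),
                     ) -> ParameterSet:
    """Recompute the named constants so both closure residuals vanish.

    Each derived constant must appear on exactly one closure path and at
    most one derived constant may sit on a path.  Forward rate constants
    are untouched; reverse rates follow from the new K automatically.
    Idempotent, and always solvable for positive inputs (log-linear).
    """
    path_no, path_rdf = _paths(params.variant)
    updates: Dict[str, float] = {}
    seen_paths = set()
    for name in derived_constant_names:
        if not name.startswith("K_"):
            raise ValueError(f"derived constant must be a K_*, got {name!r}")
        step = name[2:]
        on_no, on_rdf = step in path_no, step in path_rdf
        if not (on_no or on_rdf):
            raise ValueError(f"{name} is not on either closure path")
        path_id = "noRDF" if on_no else "RDF"
        if path_id in seen_paths:
            raise ValueError(f"two derived constants on the {path_id} path")
        seen_paths.add(path_id)
        coef = (path_no if on_no else path_rdf)[step]
        resid = params.closure_log_products()[0 if on_no else 1]
        if abs(resid) > 1e-14:   # already closed: keep bit-identical values
            updates[step] = params.K[step] * float(np.exp(-resid / coef))
    return params.with_updates(K=updates)


def compensated_perturbation(params: ParameterSet, target_K_name: str,
                             fold: float, compensating_K_name: str,
                             ) -> ParameterSet:
    """Multiply one equilibrium constant by *fold*, re-closing via another.

    Both constants must sit on the same closure path; all other constants
    and every forward rate stay fixed, so the perturbation is invertible
    (fold then 1/fold restores the original set).
    """
    if target_K_name == compensating_K_name:
        raise ValueError("target and compensating constant must differ")
    if fold <= 0:
        raise ValueError(f"fold must be positive, got {fold}")
    path_no, path_rdf = _paths(params.variant)
    t_step, c_step = target_K_name[2:], compensating_K_name[2:]
    for path in (path_no, path_rdf):
        if t_step in path:
            if c_step not in path:
                raise ValueError(
                    f"{compensating_K_name} is not on the closure path of "
                    f"{target_K_name}")
            break
    else:
        raise ValueError(f"{target_K_name} is not on either closure path")
    perturbed = params.with_updates(K={t_step: params.K[t_step] * fold})
    return close_parameters(perturbed, (compensating_K_name,))


# ======================================================================
# free-energy landscape
# ======================================================================

@dataclass
class EnergyLandscape:
    """Per-step Gibbs free-energy changes along the two reaction pathways."""

    variant: Variant
    ref_dna_nM: float
    ref_protein_nM: float
    temperature_K: float
    #: list of (pathway, step kind, dG kJ/mol) in path order
    rows: List[Tuple[str, str, float]]

    def cumulative(self, pathway: str) -> float:
        return float(sum(dg for p, _, dg in self.rows if p == pathway))

    def steps(self, pathway: str) -> Dict[str, float]:
        """step kind -> dG for one pathway (binding steps summed per event)."""
        out: Dict[str, float] = {}
        for p, kind, dg in self.rows:
            if p == pathway:
                out[kind] = out.get(kind, 0.0) + dg
        return out

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.rows, columns=["pathway", "step", "dG_kJ_per_mol"])
        df["sign"] = np.sign(df["dG_kJ_per_mol"]).astype(int)
        return df

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant.value,
            "ref_dna_nM": self.ref_dna_nM,
            "ref_protein_nM": self.ref_protein_nM,
            "temperature_K": self.temperature_K,
            "steps": [{"pathway": p, "step": k, "dG_kJ_per_mol": dg}
                      for p, k, dg in self.rows],
            "cumulative": {p: self.cumulative(p) for p in ("noRDF", "RDF")},
        }, indent=2)


def step_free_energy(K_eq: float, gamma: float = 1.0,
                     temperature_K: float = DEFAULT_T) -> float:
    """dG = RT ln(Gamma/K_eq) in kJ/mol."""
    if K_eq <= 0 or gamma <= 0:
        raise ValueError("K_eq and Gamma must be positive")
    return R_KJ * temperature_K * float(np.log(gamma / K_eq))


def energy_landscape(params: ParameterSet, ref_dna_nM: float = 10.0,
                     ref_protein_nM: float = 200.0,
                     temperature_K: float = DEFAULT_T) -> EnergyLandscape:
    """Free-energy landscape of both pathways at reference concentrations.

    Binding events appear once per protein unit bound (b1 and b2 etc. occur
    twice along a plasmid pathway); for a closed parameter set each
    pathway's cumulative dG is zero because free substrate and free product
    DNA are isoenergetic and the same proteins are released.
    """
    if ref_dna_nM <= 0 or ref_protein_nM <= 0:
        raise ValueError("reference concentrations must be positive")
    K = params.K
    linear = params.variant.is_linear
    model1 = params.variant.is_model1

    g_bind = 1.0 / ref_protein_nM      # DNA + prot -> DNA'   (conc ratio)
    g_diss = ref_protein_nM            # DNA' -> DNA + prot
    g_syn_bi = 1.0 / ref_dna_nM        # two fragments -> one synapse
    g_desyn_bi = ref_dna_nM

    def row(pathway, kind, K_eq, gamma):
        return (pathway, kind,
                step_free_energy(K_eq, gamma, temperature_K))

    rows: List[Tuple[str, str, float]] = []
    # -RDF pathway: pPB -> ... -> pLR (two binding events either way:
    # both plasmid sites, or the attP and attB fragments)
    for _ in range(2):
        rows.append(row("noRDF", "b1", K["b1"], g_bind))
    rows.append(row("noRDF", "s1", K["s1"], g_syn_bi if linear else 1.0))
    rows.append(row("noRDF", "r1", K["r1"], 1.0))
    if model1:
        rows.append(row("noRDF", "mod", K["mod"], 1.0))
    rows.append(row("noRDF", "s2", K["s2"], g_desyn_bi if linear else 1.0))
    for _ in range(2):
        rows.append(row("noRDF", "b2", 1.0 / K["b2"], g_diss))

    # +RDF pathway: pLR -> ... -> pPB
    for _ in range(2):
        rows.append(row("RDF", "b3", K["b3"], g_bind))
    rows.append(row("RDF", "s3", K["s3"], g_syn_bi if linear else 1.0))
    rows.append(row("RDF", "r2", K["r2"], 1.0))
    if model1:
        rows.append(row("RDF", "modr", K["modr"], 1.0))
    rows.append(row("RDF", "s4", K["s4"], g_desyn_bi if linear else 1.0))
    for _ in range(2):
        rows.append(row("RDF", "b4", 1.0 / K["b4"], g_diss))

    return EnergyLandscape(params.variant, ref_dna_nM, ref_protein_nM,
                           temperature_K, rows)
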