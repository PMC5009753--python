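"""Reaction networks for integrase-mediated site-specific recombination.

Builds the full reversible mass-action network of a model variant: solution
pre-equilibria (integrase dimerization, RDF loading of the dimer), sequential
per-site binding of int2 / int2rdf1 / int2rdf2 to the att sites (with
identical-sites statistical factors 2:1), synapsis/desynapsis, strand
exchange, the Model-1 synapse modification steps, and tetramer inhibition of
att sites on the attP/attB substrate.

Species naming
--------------
Solution species: ``int``, ``int2``, ``rdf``, ``int2rdf1``, ``int2rdf2``.
Open (non-synapsed) plasmid species encode the occupancy of the two att
sites as a sorted letter pair, e.g. ``PB:ei`` = pPB with one empty site and
one int2-bound site.  Letters: ``e`` empty, ``i`` int2, ``m`` int2rdf1,
``r`` int2rdf2, ``t`` int2 tetramer (synapsis-blocked).  Familiar aliases
exist: ``PB`` = ``PB:ee``, ``PB-int`` = ``PB:ii``, ``LR-int-rdf`` =
``LR:rr`` etc.  Synaptic complexes keep their scheme names: ``PB-int_s``,
``LR-int_s1``, ``LR-int_s2``, ``LR-int-rdf_s``, ``PB-int-rdf_s1``,
``PB-int-rdf_s2``.  The linear variant uses per-fragment species such as
``attP:i`` instead of site pairs, and synapsis is bimolecular.

Only plasmids whose two sites both carry bare int2 can synapse through s1,
and only those whose two sites both carry int2rdf2 through s3; every mixed
or partially RDF-loaded occupancy is synapsis-incompetent (unproductive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .params import ParameterSet, Variant

# occupancy letter -> (binding unit species, int monomers, rdf monomers)
_UNIT_OF_LETTER = {"i": "int2", "m": "int2rdf1", "r": "int2rdf2"}
_INT_OF_LETTER = {"e": 0, "i": 2, "m": 2, "r": 2, "t": 4}
_RDF_OF_LETTER = {"e": 0, "i": 0, "m": 1, "r": 2, "t": 0}

#: synaptic complex names (model-1 superset)
SYNAPSES_NO_RDF = ("PB-int_s", "LR-int_s1", "LR-int_s2")
SYNAPSES_RDF = ("LR-int-rdf_s", "PB-int-rdf_s1", "PB-int-rdf_s2")

#: friendly aliases -> canonical species names (plasmid variants)
ALIASES = {
    "PB": "PB:ee", "PB-int1": "PB:ei", "PB-int": "PB:ii",
    "LR": "LR:ee", "LR-int1": "LR:ei", "LR-int": "LR:ii",
    "PB-int-rdf1": "PB:er", "PB-int-rdf": "PB:rr",
    "LR-int-rdf1": "LR:er", "LR-int-rdf": "LR:rr",
}

SUBSTRATES = ("pPB", "pLR", "linear_PB")


@dataclass(frozen=True)
class Step:
    """One reversible reaction step (first or second order each way)."""

    name: str          # unique, e.g. "b1[ee+i]"
    kind: str          # scheme step name: b1..b4, s1..s4, r1, r2, mod, modr, ii, ir, inh
    reactants: Tuple[Tuple[str, int], ...]
    products: Tuple[Tuple[str, int], ...]
    kf: float
    kr: float

    @property
    def K_eff(self) -> float:
        """Effective equilibrium constant kf/kr (includes statistical factors)."""
        return self.kf / self.kr


class ReactionNetwork:
    """Species + reversible mass-action steps, compiled for fast ODE work."""

    def __init__(self, variant: Variant, params: ParameterSet,
                 species: Sequence[str],
                 compositions: Mapping[str, Mapping[str, int]],
                 steps: Sequence[Step]):
        self.variant = variant
        self.params = params
        self.species: List[str] = list(species)
        self.index: Dict[str, int] = {s: i for i, s in enumerate(self.species)}
        self.steps: List[Step] = list(steps)
        self.compositions = {
            s: {m: c for m, c in compositions[s].items() if c != 0}
            for s in self.species}
        self.moieties: List[str] = sorted(
            {m for c in self.compositions.values() for m in c})
        self._compile()

    # ------------------------------------------------------------------
    def _compile(self) -> None:
        n, m = len(self.species), len(self.steps)
        dummy = n  # index of a virtual concentration fixed at 1.0
        self._r = np.full((m, 2), dummy, dtype=np.intp)
        self._p = np.full((m, 2), dummy, dtype=np.intp)
        self._kf = np.empty(m)
        self._kr = np.empty(m)
        S = np.zeros((n, m))
        for j, st in enumerate(self.steps):
            ridx = [self.index[s] for s, c in st.reactants for _ in range(c)]
            pidx = [self.index[s] for s, c in st.products for _ in range(c)]
            if len(ridx) > 2 or len(pidx) > 2:
                raise ValueError(f"step {st.name} is higher than second order")
            self._r[j, :len(ridx)] = ridx
            self._p[j, :len(pidx)] = pidx
            self._kf[j] = st.kf
            self._kr[j] = st.kr
            for s, c in st.reactants:
                S[self.index[s], j] -= c
            for s, c in st.products:
                S[self.index[s], j] += c
        self.stoichiometry = S
        # conservation matrix: moiety count of each species
        A = np.zeros((len(self.moieties), n))
        for i, sp in enumerate(self.species):
            for mo, c in self.compositions[sp].items():
                A[self.moieties.index(mo), i] = c
        self.conservation = A

    # ------------------------------------------------------------------
    def fluxes(self, conc: np.ndarray) -> np.ndarray:
        """Net flux of every step (nM/s), forward minus reverse."""
        c = np.append(conc, 1.0)
        fwd = self._kf * c[self._r[:, 0]] * c[self._r[:, 1]]
        rev = self._kr * c[self._p[:, 0]] * c[self._p[:, 1]]
        return fwd - rev

    def rhs(self, t: float, conc: np.ndarray) -> np.ndarray:
        """Time derivative of all species concentrations (nM/s)."""
        return self.stoichiometry @ self.fluxes(conc)

    def jacobian(self, t: float, conc: np.ndarray) -> np.ndarray:
        c = np.append(conc, 1.0)
        m, n = len(self.steps), len(self.species)
        dR = np.zeros((m, n + 1))
        rows = np.arange(m)
        np.add.at(dR, (rows, self._r[:, 0]), self._kf * c[self._r[:, 1]])
        np.add.at(dR, (rows, self._r[:, 1]), self._kf * c[self._r[:, 0]])
        np.add.at(dR, (rows, self._p[:, 0]), -self._kr * c[self._p[:, 1]])
        np.add.at(dR, (rows, self._p[:, 1]), -self._kr * c[self._p[:, 0]])
        return self.stoichiometry @ dR[:, :n]

    # ------------------------------------------------------------------
    def totals(self, conc: np.ndarray) -> Dict[str, float]:
        """Conserved moiety totals (nM of DNA units / protein monomers)."""
        vals = self.conservation @ conc
        return dict(zip(self.moieties, vals))

    def formation_log_constants(self, tol: float = 1e-7) -> np.ndarray:
        """log formation 'constant' g of each species relative to the basis.

        At equilibrium ``log c_i = g_i + A_i . x`` where ``A_i`` is the
        moiety composition of species *i* and ``x`` the log concentrations
        of the basis species (one free species per moiety).  Solvable
        exactly iff the network is thermodynamically closed; a residual
        above *tol* raises, which doubles as a network-level Wegscheider
        check including every cycle through solution complexes.
        """
        n, m = len(self.species), len(self.steps)
        basis = self._basis_species()
        rows, b = [], []
        for st in self.steps:
            row = np.zeros(n)
            for s, c in st.reactants:
                row[self.index[s]] -= c
            for s, c in st.products:
                row[self.index[s]] += c
            rows.append(row)
            b.append(np.log(st.kf / st.kr))
        for sp in basis:
            row = np.zeros(n)
            row[self.index[sp]] = 1.0
            rows.append(row)
            b.append(0.0)
        Amat, bvec = np.asarray(rows), np.asarray(b)
        g, *_ = np.linalg.lstsq(Amat, bvec, rcond=None)
        resid = Amat @ g - bvec
        if np.max(np.abs(resid)) > tol:
            raise ValueError(
                "network is not thermodynamically closed: max cycle residual "
                f"{np.max(np.abs(resid)):.3e} in log space")
        return g

    def _basis_species(self) -> List[str]:
        """One reference species per conserved moiety (free DNA / monomers)."""
        basis = []
        for mo in self.moieties:
            for cand in ("int", "rdf", "PB:ee", "attP:e", "attB:e"):
                if cand in self.index and {
                        k: v for k, v in self.compositions[cand].items()
                        if v} == {mo: 1}:
                    basis.append(cand)
                    break
            else:
                raise RuntimeError(f"no basis species for moiety {mo}")
        return basis

    # ------------------------------------------------------------------
    def step_table(self):
        """Human-readable step table as a pandas DataFrame."""
        import pandas as pd

        def side(pairs):
            return " + ".join(s if c == 1 else f"{c} {s}" for s, c in pairs)

        return pd.DataFrame(
            [{"step": st.name, "kind": st.kind,
              "reactants": side(st.reactants), "products": side(st.products),
              "kf": st.kf, "kr": st.kr, "K_eff": st.K_eff}
             for st in self.steps])

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ReactionNetwork({self.variant.value}: "
                f"{len(self.species)} species, {len(self.steps)} steps)")


# ======================================================================
# network assembly
# ======================================================================

def build_network(variant: Variant, params: ParameterSet, *,
                  include_rdf: bool = True,
                  include_inhibition: bool = True,
                  inhibit_all_sites: bool = False,
                  allow_unclosed: bool = False) -> ReactionNetwork:
    """Assemble the reaction network of a model variant.

    ``include_rdf=False`` builds the reduced -RDF-only network (useful for
    oracle cross-checks); ``include_inhibition`` toggles the tetramer-blocked
    att sites, which by default form only on the attP/attB substrate.
    Unclosed parameter sets are rejected unless ``allow_unclosed`` is set
    (diagnostic what-goes-wrong builds).
    """
    variant = Variant(variant)
    if params.variant is not variant:
        raise ValueError(
            f"parameter set is for {params.variant.value}, not {variant.value}")
    if not (allow_unclosed or params.is_closed()):
        a, b = params.closure_log_products()
        raise ValueError(
            "parameter set violates Wegscheider closure "
            f"(log residuals {a:.3e}, {b:.3e}); pass allow_unclosed=True "
            "for a diagnostic build")
    if variant.is_linear:
        return _build_linear(variant, params, include_rdf, include_inhibition)
    return _build_plasmid(variant, params, include_rdf, include_inhibition,
                          inhibit_all_sites)


def _solution_species_steps(params, include_rdf):
    species = ["int", "int2"]
    comps = {"int": {"int": 1}, "int2": {"int": 2}}
    kf_ii, kr_ii = params.kf["ii"], params.kr("ii")
    steps = [Step("ii", "ii", (("int", 2),), (("int2", 1),), kf_ii, kr_ii)]
    if include_rdf:
        species += ["rdf", "int2rdf1", "int2rdf2"]
        comps.update({"rdf": {"rdf": 1},
                      "int2rdf1": {"int": 2, "rdf": 1},
                      "int2rdf2": {"int": 2, "rdf": 2}})
        kf_ir, kr_ir = params.kf["ir"], params.kr("ir")
        # identical-sites statistical factors on the two RDF sites of a dimer
        steps += [
            Step("ir[0->1]", "ir", (("int2", 1), ("rdf", 1)),
                 (("int2rdf1", 1),), 2.0 * kf_ir, kr_ir),
            Step("ir[1->2]", "ir", (("int2rdf1", 1), ("rdf", 1)),
                 (("int2rdf2", 1),), kf_ir, 2.0 * kr_ir),
        ]
    return species, comps, steps


def _pair_name(plasmid: str, pair) -> str:
    return f"{plasmid}:{''.join(sorted(pair))}"


def _build_plasmid(variant, params, include_rdf, include_inhibition,
                   inhibit_all_sites) -> ReactionNetwork:
    species, comps, steps = _solution_species_steps(params, include_rdf)

    units = ["i"] + (["m", "r"] if include_rdf else [])
    alphabet = {"PB": ["e"] + units, "LR": ["e"] + units}
    if include_inhibition:
        alphabet["PB"].append("t")
        if inhibit_all_sites:
            alphabet["LR"].append("t")

    # open plasmid species
    for plasmid in ("PB", "LR"):
        for pair in combinations_with_replacement(sorted(alphabet[plasmid]), 2):
            name = _pair_name(plasmid, pair)
            species.append(name)
            comps[name] = {
                "dna": 1,
                "int": sum(_INT_OF_LETTER[x] for x in pair),
                "rdf": sum(_RDF_OF_LETTER[x] for x in pair),
            }

    # synaptic complexes
    syn = list(SYNAPSES_NO_RDF if variant.is_model1 else SYNAPSES_NO_RDF[:2])
    if include_rdf:
        syn += list(SYNAPSES_RDF if variant.is_model1 else SYNAPSES_RDF[:2])
    for s in syn:
        species.append(s)
        comps[s] = {"dna": 1, "int": 4, "rdf": 4 if "rdf" in s else 0}

    # sequential site binding with statistical factors
    binding_K = {("PB", "i"): "b1", ("LR", "i"): "b2",
                 ("PB", "m"): "b4", ("LR", "m"): "b3",
                 ("PB", "r"): "b4", ("LR", "r"): "b3"}
    for plasmid in ("PB", "LR"):
        for pair in combinations_with_replacement(sorted(alphabet[plasmid]), 2):
            n_empty = pair.count("e")
            if n_empty == 0:
                continue
            for u in units:
                tgt = tuple(sorted(_replace_one(pair, "e", u)))
                kind = binding_K[(plasmid, u)]
                kf = params.kf[kind] * n_empty
                kr = params.kr(kind) * tgt.count(u)
                steps.append(Step(
                    f"{kind}[{_pair_name(plasmid, pair)}+{u}]", kind,
                    ((_pair_name(plasmid, pair), 1), (_UNIT_OF_LETTER[u], 1)),
                    ((_pair_name(plasmid, tgt), 1),), kf, kr))
    # tetramer inhibition: a second int2 docks onto an i-occupied site
    if include_inhibition:
        for plasmid in ("PB", "LR"):
            if "t" not in alphabet[plasmid]:
                continue
            for pair in combinations_with_replacement(sorted(alphabet[plasmid]), 2):
                n_i = pair.count("i")
                if n_i == 0:
                    continue
                tgt = tuple(sorted(_replace_one(pair, "i", "t")))
                kf = params.kf["inh"] * n_i
                kr = params.kr("inh") * tgt.count("t")
                steps.append(Step(
                    f"inh[{_pair_name(plasmid, pair)}]", "inh",
                    ((_pair_name(plasmid, pair), 1), ("int2", 1)),
                    ((_pair_name(plasmid, tgt), 1),), kf, kr))

    # synapsis, strand exchange, modification
    def uni(kind, src, dst):
        steps.append(Step(kind, kind, ((src, 1),), ((dst, 1),),
                          params.kf[kind], params.kr(kind)))

    uni("s1", "PB:ii", "PB-int_s")
    uni("r1", "PB-int_s", "LR-int_s1")
    if variant.is_model1:
        uni("mod", "LR-int_s1", "LR-int_s2")
        uni("s2", "LR-int_s2", "LR:ii")       # desynapsis direction
    else:
        uni("s2", "LR-int_s1", "LR:ii")
    if include_rdf:
        uni("s3", "LR:rr", "LR-int-rdf_s")
        uni("r2", "LR-int-rdf_s", "PB-int-rdf_s1")
        if variant.is_model1:
            uni("modr", "PB-int-rdf_s1", "PB-int-rdf_s2")
            uni("s4", "PB-int-rdf_s2", "PB:rr")   # desynapsis direction
        else:
            uni("s4", "PB-int-rdf_s1", "PB:rr")

    return ReactionNetwork(variant, params, species, comps, steps)


def _replace_one(pair, old, new):
    lst = list(pair)
    lst[lst.index(old)] = new
    return lst


def _build_linear(variant, params, include_rdf, include_inhibition):
    """Intermolecular variant: free att-site fragments, bimolecular synapsis.

    K_s1/K_s3 are association constants (1/nM) and K_s2/K_s4 desynapsis
    constants (nM), so the closure products stay dimensionless.
    """
    species, comps, steps = _solution_species_steps(params, include_rdf)

    units = ["i"] + (["m", "r"] if include_rdf else [])
    frag_moiety = {"attP": "Pfrag", "attL": "Pfrag",
                   "attB": "Bfrag", "attR": "Bfrag"}
    frag_alpha = {}
    for frag in ("attP", "attB", "attL", "attR"):
        letters = ["e"] + units
        if include_inhibition and frag in ("attP", "attB"):
            letters.append("t")
        frag_alpha[frag] = letters
        for x in letters:
            name = f"{frag}:{x}"
            species.append(name)
            comps[name] = {frag_moiety[frag]: 1, "int": _INT_OF_LETTER[x],
                           "rdf": _RDF_OF_LETTER[x]}

    syn = ["PB-int_s", "LR-int_s1", "LR-int_s2"]
    if include_rdf:
        syn += list(SYNAPSES_RDF)
    for s in syn:
        species.append(s)
        comps[s] = {"Pfrag": 1, "Bfrag": 1, "int": 4,
                    "rdf": 4 if "rdf" in s else 0}

    binding_K = {("attP", "i"): "b1", ("attB", "i"): "b1",
                 ("attL", "i"): "b2", ("attR", "i"): "b2",
                 ("attP", "m"): "b4", ("attB", "m"): "b4",
                 ("attL", "m"): "b3", ("attR", "m"): "b3",
                 ("attP", "r"): "b4", ("attB", "r"): "b4",
                 ("attL", "r"): "b3", ("attR", "r"): "b3"}
    for frag, letters in frag_alpha.items():
        for u in units:
            kind = binding_K[(frag, u)]
            steps.append(Step(
                f"{kind}[{frag}+{u}]", kind,
                ((f"{frag}:e", 1), (_UNIT_OF_LETTER[u], 1)),
                ((f"{frag}:{u}", 1),), params.kf[kind], params.kr(kind)))
        if "t" in letters:
            steps.append(Step(
                f"inh[{frag}]", "inh",
                ((f"{frag}:i", 1), ("int2", 1)), ((f"{frag}:t", 1),),
                params.kf["inh"], params.kr("inh")))

    steps += [
        Step("s1", "s1", (("attP:i", 1), ("attB:i", 1)), (("PB-int_s", 1),),
             params.kf["s1"], params.kr("s1")),
        Step("r1", "r1", (("PB-int_s", 1),), (("LR-int_s1", 1),),
             params.kf["r1"], params.kr("r1")),
        Step("mod", "mod", (("LR-int_s1", 1),), (("LR-int_s2", 1),),
             params.kf["mod"], params.kr("mod")),
        Step("s2", "s2", (("LR-int_s2", 1),),
             (("attL:i", 1), ("attR:i", 1)), params.kf["s2"], params.kr("s2")),
    ]
    if include_rdf:
        steps += [
            Step("s3", "s3", (("attL:r", 1), ("attR:r", 1)),
                 (("LR-int-rdf_s", 1),), params.kf["s3"], params.kr("s3")),
            Step("r2", "r2", (("LR-int-rdf_s", 1),), (("PB-int-rdf_s1", 1),),
                 params.kf["r2"], params.kr("r2")),
            Step("modr", "modr", (("PB-int-rdf_s1", 1),),
                 (("PB-int-rdf_s2", 1),), params.kf["modr"], params.kr("modr")),
            Step("s4", "s4", (("PB-int-rdf_s2", 1),),
                 (("attP:r", 1), ("attB:r", 1)), params.kf["s4"], params.kr("s4")),
        ]

    return ReactionNetwork(variant, params, species, comps, steps)


# ======================================================================
# states and readout classification
# ======================================================================

def initial_state(network: ReactionNetwork, substrate: str,
                  dna_conc: float, int_total: float,
                  rdf_total: float = 0.0) -> np.ndarray:
    """Initial concentration vector: free DNA plus free protein monomers.

    All protein starts as free monomer (concentrations refer to monomer);
    dimerization and RDF loading then evolve kinetically.  ``dna_conc`` is
    per plasmid for the plasmid variants and per fragment (each of attP and
    attB) for ``linear_PB``.
    """
    if substrate not in SUBSTRATES:
        raise ValueError(f"unknown substrate {substrate!r}; expected {SUBSTRATES}")
    for label, v in (("dna_conc", dna_conc), ("int_total", int_total),
                     ("rdf_total", rdf_total)):
        if v < 0:
            raise ValueError(f"{label} must be >= 0, got {v}")
    if rdf_total > 0 and "rdf" not in network.index:
        raise ValueError("network was built without RDF species")
    c = np.zeros(len(network.species))
    if substrate == "linear_PB":
        if not network.variant.is_linear:
            raise ValueError("linear_PB substrate requires the linear variant")
        c[network.index["attP:e"]] = dna_conc
        c[network.index["attB:e"]] = dna_conc
    else:
        if network.variant.is_linear:
            raise ValueError(f"substrate {substrate} requires a plasmid variant")
        c[network.index["PB:ee" if substrate == "pPB" else "LR:ee"]] = dna_conc
    c[network.index["int"]] = int_total
    if "rdf" in network.index:
        c[network.index["rdf"]] = rdf_total
    return c


def recombinant_readout(network: ReactionNetwork, substrate: str):
    """(numerator indices, denominator indices) for the recombinant fraction.

    For pPB substrate: every species carrying LR-configured DNA (including
    synapses) over total plasmid; symmetric for pLR.  For linear_PB: every
    attL-containing species over the total attB-derived fragment pool.
    """
    idx = network.index
    if substrate == "linear_PB":
        num = [i for s, i in idx.items()
               if s.startswith("attL:") or s in ("LR-int_s1", "LR-int_s2",
                                                 "LR-int-rdf_s")]
        den = [i for s, i in idx.items()
               if network.compositions[s].get("Bfrag", 0) > 0]
        return np.array(num), np.array(den)
    lr = [i for s, i in idx.items()
          if s.startswith("LR:") or s in ("LR-int_s1", "LR-int_s2",
                                          "LR-int-rdf_s")]
    pb = [i for s, i in idx.items()
          if s.startswith("PB:") or s in ("PB-int_s", "PB-int-rdf_s1",
                                          "PB-int-rdf_s2")]
    dna = sorted(lr + pb)
    if substrate == "pPB":
        return np.array(lr), np.array(dna)
    if substrate == "pLR":
        return np.array(pb), np.array(dna)
    raise ValueError(f"unknown substrate {substrate!r}")
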