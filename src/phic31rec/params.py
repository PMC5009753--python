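"""Named equilibrium and rate constants for the recombination models.

Units convention (used throughout the package): concentrations in nM, time in
seconds.  Bimolecular forward rate constants are 1/(nM*s), unimolecular ones
1/s.  Equilibrium constants are ratios of forward to reverse rate constants,
so ``kr = kf / K`` for every reaction step -- except the two solution
constants ``K_ii`` (integrase dimerization) and ``K_ir`` (integrase--RDF
binding), which are *dissociation* constants in nM, so there ``kr = kf * K``.

Sign convention for the synapse-stability steps (important!): ``s2`` and
``s4`` are written in the *desynapsis* direction (LR-int_s2 -> LR-int and
PB-int-rdf_s2 -> PB-int-rdf respectively), matching the arrows of the
reaction scheme.  ``K_s2`` and ``K_s4`` are therefore desynapsis equilibrium
constants; getting this sign wrong silently breaks the Wegscheider closure.
"""

from __future__ import annotations

import enum
import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping

import yaml


class Variant(str, enum.Enum):
    """Model variant identifiers."""

    MODEL0_PLASMID = "model0-plasmid"
    MODEL1_PLASMID = "model1-plasmid"
    MODEL1_LINEAR = "model1-linear"

    @property
    def is_model1(self) -> bool:
        return self is not Variant.MODEL0_PLASMID

    @property
    def is_linear(self) -> bool:
        return self is Variant.MODEL1_LINEAR


#: reaction steps whose K is a dissociation constant in nM (kr = kf * K)
DISSOCIATION_STEPS = ("ii", "ir")

#: steps present in every variant
_BASE_STEPS = (
    "ii", "ir",
    "b1", "b2", "b3", "b4",
    "s1", "s2", "s3", "s4",
    "r1", "r2",
    "inh",
)
#: extra conformational-change steps of Model 1
_MOD_STEPS = ("mod", "modr")

#: closure-derived constants (recomputed, never fitted directly)
DEFAULT_DERIVED = ("K_s2", "K_s4")

CLOSURE_TOL = 1e-9


def step_names(variant: Variant) -> tuple:
    """All reaction-step names required by *variant*."""
    if variant.is_model1:
        return _BASE_STEPS + _MOD_STEPS
    return _BASE_STEPS


@dataclass(frozen=True)
class ParameterSet:
    """One complete parameterization of a model variant.

    ``K`` maps step name -> equilibrium constant, ``kf`` maps step name ->
    forward rate constant.  Reverse rates are always derived (:meth:`kr`),
    so a ParameterSet can never be internally inconsistent about them.
    """

    variant: Variant
    K: Mapping[str, float] = field(default_factory=dict)
    kf: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "K", dict(self.K))
        object.__setattr__(self, "kf", dict(self.kf))
        required = step_names(self.variant)
        for table, label in ((self.K, "K"), (self.kf, "kf")):
            missing = [s for s in required if s not in table]
            if missing:
                raise ValueError(
                    f"{self.variant.value}: missing {label} for steps {missing}"
                )
            for s in required:
                v = table[s]
                if not (math.isfinite(v) and v > 0):
                    raise ValueError(
                        f"{self.variant.value}: {label}_{s} must be positive "
                        f"and finite, got {v!r}"
                    )

    # -- rate constants ---------------------------------------------------
    def kr(self, step: str) -> float:
        """Reverse rate constant of *step* (derived from kf and K)."""
        if step in DISSOCIATION_STEPS:
            return self.kf[step] * self.K[step]
        return self.kf[step] / self.K[step]

    # -- closure ----------------------------------------------------------
    def closure_log_products(self) -> tuple:
        """Signed log-sums of equilibrium constants around the two pathways.

        Returns ``(log_noRDF, log_RDF)``; each is 0 for a closed set.  The
        -RDF pathway runs free pPB -> ... -> free pLR releasing the same
        proteins (b1 twice, s1, r1, [mod], s2, then b2 twice in reverse);
        the +RDF pathway is the b3/s3/r2/[modr]/s4/b4 analogue.  Statistical
        site-binding factors cancel around each path and are excluded.
        """
        K = self.K
        no_rdf = (2.0 * math.log(K["b1"]) + math.log(K["s1"])
                  + math.log(K["r1"]) + math.log(K["s2"])
                  - 2.0 * math.log(K["b2"]))
        with_rdf = (2.0 * math.log(K["b3"]) + math.log(K["s3"])
                    + math.log(K["r2"]) + math.log(K["s4"])
                    - 2.0 * math.log(K["b4"]))
        if self.variant.is_model1:
            no_rdf += math.log(K["mod"])
            with_rdf += math.log(K["modr"])
        return (no_rdf, with_rdf)

    def is_closed(self, tol: float = CLOSURE_TOL) -> bool:
        a, b = self.closure_log_products()
        return abs(a) <= tol and abs(b) <= tol

    # -- convenience ------------------------------------------------------
    def with_updates(self, K: Mapping[str, float] | None = None,
                     kf: Mapping[str, float] | None = None) -> "ParameterSet":
        newK = dict(self.K)
        newK.update(K or {})
        newkf = dict(self.kf)
        newkf.update(kf or {})
        return replace(self, K=newK, kf=newkf)

    def free_parameter_names(self,
                             derived: Iterable[str] = DEFAULT_DERIVED) -> list:
        """Flat names (``K_<step>``, ``kf_<step>``) of the free parameters.

        The closure-derived constants (default K_s2, K_s4) are excluded:
        they are recomputed from the others whenever a free constant moves.
        """
        derived = set(derived)
        names = [f"K_{s}" for s in step_names(self.variant)
                 if f"K_{s}" not in derived]
        names += [f"kf_{s}" for s in step_names(self.variant)]
        return names

    def get_flat(self, name: str) -> float:
        table, step = _split_flat(name)
        return (self.K if table == "K" else self.kf)[step]

    def set_flat(self, name: str, value: float) -> "ParameterSet":
        table, step = _split_flat(name)
        if table == "K":
            return self.with_updates(K={step: value})
        return self.with_updates(kf={step: value})

    def as_flat_dict(self) -> Dict[str, float]:
        d: Dict[str, float] = {"variant": self.variant.value}
        for s in step_names(self.variant):
            d[f"K_{s}"] = float(self.K[s])
        for s in step_names(self.variant):
            d[f"kf_{s}"] = float(self.kf[s])
        return d

    def content_hash(self) -> str:
        """Short stable hash of the parameter values (for output metadata)."""
        text = ",".join(f"{k}={v!r}" for k, v in sorted(self.as_flat_dict().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _split_flat(name: str) -> tuple:
    for prefix in ("kf_", "K_"):
        if name.startswith(prefix):
            return prefix.rstrip("_"), name[len(prefix):]
    raise KeyError(f"not a parameter name: {name!r} (expected K_* or kf_*)")


# -- file I/O -------------------------------------------------------------

def params_from_flat_dict(d: Mapping[str, float]) -> ParameterSet:
    variant = Variant(d["variant"])
    K, kf = {}, {}
    for key, value in d.items():
        if key == "variant":
            continue
        table, step = _split_flat(key)
        (K if table == "K" else kf)[step] = float(value)
    return ParameterSet(variant=variant, K=K, kf=kf)


def load_parameters(path, require_closed: bool = True) -> ParameterSet:
    """Load a ParameterSet from a flat YAML file.

    With ``require_closed`` (default) the set must satisfy Wegscheider
    closure to 1e-9 in log space; pass ``require_closed=False`` only for
    diagnostic what-goes-wrong experiments.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variant" not in doc:
        raise ValueError(f"{path}: expected a flat mapping with a 'variant' tag")
    p = params_from_flat_dict(doc)
    if require_closed and not p.is_closed():
        a, b = p.closure_log_products()
        raise ValueError(
            f"{path}: parameter set violates Wegscheider closure "
            f"(log residuals {a:.3e}, {b:.3e}); pass require_closed=False "
            f"to load it for diagnostics"
        )
    return p


def save_parameters(params: ParameterSet, path) -> None:
    d = params.as_flat_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


_DATA_DIR = Path(__file__).parent / "data"
_REFERENCE_FILES = {
    Variant.MODEL0_PLASMID: "model0_plasmid.yaml",
    Variant.MODEL1_PLASMID: "model1_plasmid.yaml",
    Variant.MODEL1_LINEAR: "model1_linear.yaml",
}


def reference_parameters(variant: Variant = Variant.MODEL1_PLASMID) -> ParameterSet:
    """The package's reference parameter set for *variant*.

    These values were calibrated (see analysis/01_calibrate_parameters.py)
    against the published summary kinetics of the reactions and are shipped
    as plain YAML under ``phic31rec/data``.
    """
    return load_parameters(_DATA_DIR / _REFERENCE_FILES[Variant(variant)])
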