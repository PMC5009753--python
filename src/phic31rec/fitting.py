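"""Model-data agreement, constrained parameter estimation, robustness.

The experimental design this package works against is a table of
recombinant-fraction observations (substrate, [integrase], [RDF], time,
fraction, replicate SD, n).  The original study adjusted parameters
manually under thermodynamic and plausibility constraints; here the same
constraints drive a reproducible local least-squares fit: every candidate
parameter vector is re-closed through the Wegscheider-derived constants
(K_s2, K_s4) *before* it is evaluated, so no step of any fit can leave the
thermodynamically consistent manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import build_network, initial_state
from .params import DEFAULT_DERIVED, ParameterSet, Variant
from .simulate import HOUR, SimulationError, fraction_recombinant, simulate
from .thermo import close_parameters

DATA_COLUMNS = ["substrate", "int_total_nM", "rdf_total_nM", "time_h",
                "fraction_recombinant", "sd", "n"]

#: default association-rate bounds, 1/(nM*s)  (~1e3..1e9 1/(M*s))
KF_BOUNDS = (1e-6, 1.0)
K_BOUNDS = (1e-9, 1e9)


@dataclass
class ExperimentDataset:
    """Observation table plus provenance (real or synthetic(seed))."""

    table: pd.DataFrame
    provenance: str = "real"

    def __post_init__(self):
        t = self.table
        missing = [c for c in DATA_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        f = t["fraction_recombinant"].to_numpy(float)
        if np.any((f < 0) | (f > 1)) or not np.all(np.isfinite(f)):
            raise ValueError("fractions must lie in [0, 1]")
        sd = t["sd"].to_numpy(float)
        if np.any(sd < 0) or not np.all(np.isfinite(sd)):
            raise ValueError("sd must be finite and >= 0")
        bad = set(t["substrate"]) - {"pPB", "pLR", "linear_PB"}
        if bad:
            raise ValueError(f"unknown substrates {bad}")

    def __len__(self) -> int:
        return len(self.table)

    def conditions(self):
        """Unique (substrate, int, rdf) with their sorted observation times."""
        for key, grp in self.table.groupby(
                ["substrate", "int_total_nM", "rdf_total_nM"], sort=True):
            yield key, np.sort(grp["time_h"].unique())

    def to_csv(self, path, meta: Optional[Dict] = None, force: bool = False):
        from .io_utils import write_csv_with_meta
        meta = dict(meta or {})
        meta.setdefault("provenance", self.provenance)
        write_csv_with_meta(self.table, path, meta, force=force)

    @classmethod
    def from_csv(cls, path) -> "ExperimentDataset":
        from .io_utils import read_csv_with_meta
        table, meta = read_csv_with_meta(path)
        return cls(table, provenance=meta.get("provenance", "real"))


# ======================================================================
# objective
# ======================================================================

def predict(params: ParameterSet, dataset: ExperimentDataset,
            dna_conc: float = 10.0) -> np.ndarray:
    """Model fractions for every dataset row (one simulation per condition)."""
    preds = pd.Series(np.nan, index=dataset.table.index)
    net = build_network(params.variant, params)
    for (sub, int_t, rdf_t), times_h in dataset.conditions():
        mask = ((dataset.table["substrate"] == sub)
                & (dataset.table["int_total_nM"] == int_t)
                & (dataset.table["rdf_total_nM"] == rdf_t))
        c0 = initial_state(net, sub, dna_conc, int_t, rdf_t)
        pos = times_h > 0
        f = np.zeros_like(times_h, dtype=float)
        if int_t > 0 and pos.any():
            sim = simulate(net, c0, times_h[pos] * HOUR)
            f[pos] = fraction_recombinant(sim, sub)
        lut = dict(zip(times_h, f))
        preds[mask] = dataset.table.loc[mask, "time_h"].map(lut)
    return preds.to_numpy(float)


def residuals(params: ParameterSet, dataset: ExperimentDataset,
              weighted: bool = False) -> np.ndarray:
    """Per-observation (model - observed), optionally 1/sd weighted."""
    if not params.is_closed():
        raise ValueError("objective requires a Wegscheider-closed parameter set")
    r = predict(params, dataset) - dataset.table[
        "fraction_recombinant"].to_numpy(float)
    if weighted:
        sd = np.maximum(dataset.table["sd"].to_numpy(float), 1e-3)
        r = r / sd
    return r


def objective(params: ParameterSet, dataset: ExperimentDataset,
              weighted: bool = False) -> float:
    """Sum of squared residuals between simulated and observed fractions."""
    r = residuals(params, dataset, weighted=weighted)
    return float(r @ r)


# ======================================================================
# fitting
# ======================================================================

@dataclass
class FitResult:
    params: ParameterSet
    objective: float
    residuals: np.ndarray
    free_names: List[str]
    at_bounds: Dict[str, str]          # name -> "lower"/"upper"
    n_evaluations: int
    starts: List[Tuple[int, float]]    # (start index, final cost)
    sloppy_directions: List[Dict] = field(default_factory=list)
    message: str = ""


def fit_parameters(dataset: ExperimentDataset, init_params: ParameterSet,
                   free_names: Sequence[str],
                   bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                   seed: Optional[int] = None, n_starts: int = 1,
                   spread: float = 1.5, weighted: bool = False,
                   max_nfev: Optional[int] = None,
                   derived: Sequence[str] = DEFAULT_DERIVED) -> FitResult:
    """Constrained local least squares in log-parameter space.

    *free_names* are flat names (``K_r1``, ``kf_s1``, ...); the
    closure-derived constants are recomputed at every evaluation and must
    not be listed.  Additional starts (``n_starts > 1``) perturb the
    initial point log-normally by up to *spread*-fold using *seed*.
    Bounds default to 1e-6..1 1/(nM*s) for forward rate constants and wide
    positivity for equilibrium constants.
    """
    from scipy.optimize import least_squares

    free_names = list(free_names)
    for name in free_names:
        if name in derived:
            raise ValueError(
                f"{name} is closure-derived and cannot be fitted directly")
        init_params.get_flat(name)  # raises on unknown names
    bounds = dict(bounds or {})
    lo = np.array([np.log10(bounds.get(n, KF_BOUNDS if n.startswith("kf_")
                                       else K_BOUNDS)[0]) for n in free_names])
    hi = np.array([np.log10(bounds.get(n, KF_BOUNDS if n.startswith("kf_")
                                       else K_BOUNDS)[1]) for n in free_names])
    x_init = np.array([np.log10(init_params.get_flat(n)) for n in free_names])
    if np.any(x_init < lo) or np.any(x_init > hi):
        raise ValueError("initial parameters violate the bounds")

    n_eval = 0

    def realize(x) -> ParameterSet:
        p = init_params
        for name, v in zip(free_names, 10.0 ** np.asarray(x)):
            p = p.set_flat(name, v)
        return close_parameters(p, derived)

    def fun(x):
        nonlocal n_eval
        n_eval += 1
        try:
            return residuals(realize(x), dataset, weighted=weighted)
        except SimulationError:
            return np.full(len(dataset), 1e3)

    rng = np.random.default_rng(seed)
    starts = [x_init]
    for _ in range(n_starts - 1):
        jitter = rng.uniform(-np.log10(spread), np.log10(spread),
                             size=len(free_names))
        starts.append(np.clip(x_init + jitter, lo, hi))

    best, trace = None, []
    for k, x0 in enumerate(starts):
        sol = least_squares(fun, x0, bounds=(lo, hi), diff_step=1e-4,
                            max_nfev=max_nfev)
        trace.append((k, float(sol.cost * 2.0)))  # cost is 0.5*SSR
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    fitted = realize(best.x)
    at_bounds = {}
    for name, xv, l, h in zip(free_names, best.x, lo, hi):
        if xv - l < 1e-3:
            at_bounds[name] = "lower"
        elif h - xv < 1e-3:
            at_bounds[name] = "upper"

    sloppy = _sloppy_directions(best.jac, free_names)
    return FitResult(fitted, float(2.0 * best.cost), best.fun, free_names,
                     at_bounds, n_eval, trace, sloppy, best.message)


def _sloppy_directions(jac: np.ndarray, free_names, ratio: float = 1e-4):
    """Flag near-flat directions of the objective at the optimum."""
    out = []
    try:
        _, sv, vt = np.linalg.svd(np.atleast_2d(jac), full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover
        return out
    if sv[0] == 0:
        return out
    for s, v in zip(sv, vt):
        if s / sv[0] < ratio:
            weights = {n: float(w) for n, w in zip(free_names, v)
                       if abs(w) > 0.2}
            out.append({"singular_value_ratio": float(s / sv[0]),
                        "direction": weights})
    return out


# ======================================================================
# robustness
# ======================================================================

#: reaction conditions of the two permitted reactions (substrate, int, rdf)
PERMITTED_CONDITIONS = (("pPB", 400.0, 0.0), ("pLR", 400.0, 800.0))


def robustness_scan(params: ParameterSet, fold: float = 2.0,
                    conditions=PERMITTED_CONDITIONS,
                    t_max_h: float = 3.0, n_times: int = 60,
                    dna_conc: float = 10.0, mode: str = "reclose",
                    free_names: Optional[Sequence[str]] = None,
                    ) -> pd.DataFrame:
    """Effect of fold / 1-fold changes of every free parameter on yields.

    "Yield" is the maximum recombinant fraction over the first *t_max_h*
    hours of each permitted reaction.  With ``mode='reclose'`` (default)
    each perturbed set is re-closed through K_s2/K_s4, keeping it
    thermodynamically valid; ``mode='direct'`` perturbs without re-closing
    (diagnostic: networks are then built with the unclosed flag).
    """
    if mode not in ("reclose", "direct"):
        raise ValueError("mode must be 'reclose' or 'direct'")
    times = np.linspace(60.0, t_max_h * HOUR, n_times)

    def max_yields(p: ParameterSet) -> np.ndarray:
        net = build_network(p.variant, p, allow_unclosed=(mode == "direct"))
        out = []
        for sub, int_t, rdf_t in conditions:
            c0 = initial_state(net, sub, dna_conc, int_t, rdf_t)
            sim = simulate(net, c0, times)
            out.append(float(fraction_recombinant(sim, sub).max()))
        return np.asarray(out)

    base = max_yields(params)
    labels = [f"{s}({int(i)}/{int(r)})" for s, i, r in conditions]
    rows = []
    names = list(free_names) if free_names is not None else \
        params.free_parameter_names()
    for name in names:
        for f in (fold, 1.0 / fold):
            q = params.set_flat(name, params.get_flat(name) * f)
            if mode == "reclose":
                q = close_parameters(q)
            row = {"parameter": name, "fold": f, "error": ""}
            try:
                y = max_yields(q)
                for lab, b, v in zip(labels, base, y):
                    row[f"yield_{lab}"] = v
                    row[f"rel_change_pct_{lab}"] = 100.0 * (v - b) / b
                row["max_abs_rel_change_pct"] = float(
                    np.max(np.abs(y - base) / base) * 100.0)
            except SimulationError as exc:
                row["error"] = str(exc)
                row["max_abs_rel_change_pct"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["baseline_yields"] = dict(zip(labels, base))
    return df
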