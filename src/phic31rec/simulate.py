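"""Time-course simulation, equilibrium solving and concentration scans.

The networks are stiff (association at hundreds of nM on a seconds scale
next to synapse (de)stabilization on a days scale), so integration uses
scipy's BDF with the analytic Jacobian.  Requested readout times ("30 min",
"3 h") are exact evaluation points handed to the integrator, never nearest
samples.  Equilibria come from long-horizon integration followed by a
damped Newton polish of ``rhs = 0`` under the conservation constraints; an
independent algebraic route (:func:`algebraic_equilibrium`, a convex
free-energy/formation-constant solve) exists for cross-checking and never
shares code with the ODE path beyond the network definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, initial_state, recombinant_readout
from .params import ParameterSet, Variant

HOUR = 3600.0

#: solver defaults; concentrations are nM so atol 1e-12 is far below
#: any biologically meaningful occupancy
RTOL = 1e-8
ATOL = 1e-12

#: long-horizon endpoint used before the Newton polish (seconds); the
#: slowest relaxations in the reference models are ~1e5-1e6 s
T_EQUILIBRIUM = 1e8

_NEG_SLACK = -1e-9


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationResult:
    """Concentration trajectory with its provenance."""

    network: ReactionNetwork
    times: np.ndarray            # seconds
    conc: np.ndarray             # (n_times, n_species), nM
    initial: np.ndarray
    rtol: float
    atol: float

    @property
    def species(self):
        return self.network.species

    def trajectory_of(self, name: str) -> np.ndarray:
        return self.conc[:, self.network.index[name]]

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.conc, columns=self.species)
        df.insert(0, "time_s", self.times)
        return df


def _clip_negatives(conc: np.ndarray) -> np.ndarray:
    low = conc.min()
    if low < _NEG_SLACK:
        raise SimulationError(
            f"integrator produced concentration {low:.3e} nM below the "
            f"{_NEG_SLACK} slack; tighten tolerances")
    return np.clip(conc, 0.0, None)


def _check_conservation(network, initial, conc, rel_tol=1e-6):
    ref = network.conservation @ initial
    got = conc @ network.conservation.T
    scale = np.where(ref > 0, ref, 1.0)
    drift = np.max(np.abs(got - ref[None, :]) / scale[None, :])
    if drift > rel_tol:
        raise SimulationError(
            f"conservation totals drifted by {drift:.3e} relative "
            f"(> {rel_tol}); integrator tolerances too loose")
    return drift


def simulate(network: ReactionNetwork, initial: np.ndarray,
             times: Sequence[float], rtol: float = RTOL,
             atol: float = ATOL) -> SimulationResult:
    """Integrate the network from *initial* and return the trajectory.

    *times* (seconds) must be non-negative and strictly increasing; they
    become exact evaluation points.  Conservation of DNA, integrase and RDF
    totals is verified to 1e-6 relative along the whole trajectory.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be >= 0 and strictly increasing")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (len(network.species),):
        raise ValueError("initial state does not match the network species")

    t_eval = times
    prepend_zero = times[0] > 0
    if prepend_zero:
        t_eval = np.concatenate(([0.0], times))
    if times[-1] == 0.0:
        conc = np.asarray([initial])
        return SimulationResult(network, times, conc, initial, rtol, atol)

    sol = solve_ivp(network.rhs, (0.0, float(times[-1])), initial,
                    method="BDF", jac=network.jacobian,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"stiff integration failed: {sol.message} "
                              f"(nfev={sol.nfev}, njev={sol.njev})")
    conc = sol.y.T
    if prepend_zero:
        conc = conc[1:]
    conc = _clip_negatives(conc)
    _check_conservation(network, initial, conc)
    return SimulationResult(network, times, conc, initial, rtol, atol)


def fraction_recombinant(result: SimulationResult, substrate: str) -> np.ndarray:
    """Recombinant-configuration DNA fraction at every trajectory time.

    Counts every species carrying recombinant DNA, synaptic complexes
    included (the experimental readout deproteinizes and digests, so
    protein-bound and synapsed DNA all report).
    """
    num, den = recombinant_readout(result.network, substrate)
    total = result.conc[:, den].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total DNA: recombinant fraction undefined")
    return result.conc[:, num].sum(axis=1) / total


def state_fraction_recombinant(network: ReactionNetwork, conc: np.ndarray,
                               substrate: str) -> float:
    num, den = recombinant_readout(network, substrate)
    total = conc[den].sum()
    if total <= 0:
        raise ValueError("zero total DNA: recombinant fraction undefined")
    return float(conc[num].sum() / total)


# ======================================================================
# equilibrium: ODE route (long integration + Newton polish)
# ======================================================================

@dataclass
class EquilibriumResult:
    conc: np.ndarray
    max_rhs: float               # nM/s after polishing
    max_step_flux: float         # detailed-balance diagnostic, nM/s
    newton_iterations: int
    fraction_recombinant: Optional[float] = None


def equilibrium_composition(network: ReactionNetwork, initial: np.ndarray,
                            substrate: Optional[str] = None,
                            t_long: float = T_EQUILIBRIUM,
                            rtol: float = RTOL, atol: float = ATOL,
                            ) -> EquilibriumResult:
    """Steady state reached from *initial*: long integration, then polish.

    The polish is a damped Newton iteration on ``rhs = 0`` in
    log-concentration space (positivity for free) with the conserved-moiety
    totals appended as constraints.  For these detailed-balanced networks
    the steady state in a stoichiometric class is unique, so the result is
    independent of which substrate the system started from.
    """
    initial = np.asarray(initial, dtype=float)
    sim = simulate(network, initial, [t_long], rtol=rtol, atol=atol)
    c = sim.conc[-1].copy()
    totals_ref = network.conservation @ initial
    # species built from a moiety that is absent can only carry solver noise
    dead = (network.conservation[totals_ref == 0].sum(axis=0) > 0)
    c[dead] = 0.0

    active = c > 0
    floor = max(atol, 1e-300)
    y = np.log(np.maximum(c[active], floor))
    # all linear invariants of the active subsystem (moiety totals plus any
    # extra pairing invariants, e.g. attP - attB counts in the linear model)
    A = _invariants(network, active)
    b = A @ initial[active]
    bscale = np.abs(A) @ initial[active] + 1e-30
    cons_scale = 1e-4  # balances nM constraint rows against nM/s rate rows

    def residual(yv):
        cv = np.zeros_like(c)
        cv[active] = np.exp(yv)
        r = network.rhs(0.0, cv)[active]
        g = cons_scale * (A @ np.exp(yv) - b) / bscale
        return cv, np.concatenate([r, g])

    it = 0
    cv, F = residual(y)
    for it in range(1, 61):
        J_c = network.jacobian(0.0, cv)[np.ix_(active, active)]
        Jy = J_c * np.exp(y)[None, :]
        Gy = cons_scale * (A * np.exp(y)[None, :]) / bscale[:, None]
        Jfull = np.vstack([Jy, Gy])
        step, *_ = np.linalg.lstsq(Jfull, -F, rcond=None)
        lam, ok = 1.0, False
        for _ in range(30):
            y_try = y + lam * np.clip(step, -2.0, 2.0)
            cv_try, F_try = residual(y_try)
            if np.linalg.norm(F_try) < np.linalg.norm(F):
                y, cv, F = y_try, cv_try, F_try
                ok = True
                break
            lam *= 0.5
        if not ok or np.max(np.abs(F)) < 1e-14:
            break

    conc = np.zeros_like(c)
    conc[active] = np.exp(y)
    max_rhs = float(np.max(np.abs(network.rhs(0.0, conc))))
    if max_rhs > 1e-10:
        raise SimulationError(
            f"equilibrium polish did not converge: max |rhs| = {max_rhs:.3e}")
    max_flux = float(np.max(np.abs(network.fluxes(conc))))
    frac = None
    if substrate is not None:
        frac = state_fraction_recombinant(network, conc, substrate)
    return EquilibriumResult(conc, max_rhs, max_flux, it, frac)


# ======================================================================
# equilibrium: independent algebraic oracle
# ======================================================================

def _live_species(network: ReactionNetwork, initial: np.ndarray) -> np.ndarray:
    """Mask of species not built from an absent conserved moiety."""
    totals = network.conservation @ np.asarray(initial, dtype=float)
    dead = (network.conservation[totals <= 0].sum(axis=0) > 0)
    return ~dead


def _invariants(network: ReactionNetwork, mask: np.ndarray) -> np.ndarray:
    """Basis of all linear conservation laws of the *mask* subsystem.

    The moiety totals are always invariant, but some networks have more
    (in the linear-substrate model every synapse pairs one attP/attL
    fragment with one attB/attR fragment, so the P-minus-B occupancy
    difference is conserved too); the full left null space of the
    stoichiometry matrix captures them all.
    """
    from scipy.linalg import null_space
    steps_live = np.all(
        np.abs(network.stoichiometry[~mask]) == 0, axis=0)
    S = network.stoichiometry[np.ix_(mask, steps_live)]
    L = null_space(S.T).T
    if L.size == 0:   # fully connected system (no conservation): unusual
        raise SimulationError("network has no conserved totals")
    return L


def algebraic_equilibrium(network: ReactionNetwork,
                          initial: np.ndarray) -> np.ndarray:
    """Equilibrium composition from formation constants (no ODE involved).

    Thermodynamic closure makes the log formation constant ``g_i`` of every
    species well-defined up to the conserved directions, so the equilibrium
    manifold is ``c = exp(g + L^T x)`` with ``L`` the conservation-law
    basis and one unknown per law, fixed by the initial totals.  Those
    equations are the gradient of a strictly convex function, minimized
    here by damped Newton.  Detailed balance holds at the result by
    construction.
    """
    initial = np.asarray(initial, dtype=float)
    sp = _live_species(network, initial)
    steps_live = np.all(np.abs(network.stoichiometry[~sp]) == 0, axis=0)

    # min-norm particular solution of the per-step equilibrium relations
    N = network.stoichiometry[np.ix_(sp, steps_live)].T  # steps x species
    logK = np.array([np.log(st.kf / st.kr)
                     for st, keep in zip(network.steps, steps_live) if keep])
    g, *_ = np.linalg.lstsq(N, logK, rcond=None)
    resid = N @ g - logK
    if resid.size and np.max(np.abs(resid)) > 1e-7:
        raise SimulationError(
            "network is not thermodynamically closed: max cycle residual "
            f"{np.max(np.abs(resid)):.3e} in log space")

    L = _invariants(network, sp)
    b = L @ initial[sp]
    scale = np.abs(L) @ np.full(sp.sum(), max(initial.max(), 1e-12))

    x = np.zeros(L.shape[0])

    def conc_of(xv):
        return np.exp(np.clip(g + L.T @ xv, -700, 700))

    # minimize psi(x) = sum_i c_i(x) - b.x  (strictly convex in x)
    for _ in range(300):
        cvec = conc_of(x)
        grad = L @ cvec - b
        if np.max(np.abs(grad) / scale) < 1e-14:
            break
        H = (L * cvec[None, :]) @ L.T
        H.flat[:: H.shape[0] + 1] += 1e-14 * max(np.max(cvec), 1e-30)
        step = np.linalg.solve(H, -grad)
        psi0 = cvec.sum() - b @ x
        lam = 1.0
        for _ in range(60):
            x_try = x + lam * step
            psi = conc_of(x_try).sum() - b @ x_try
            if psi < psi0:
                x = x_try
                break
            lam *= 0.5
        else:
            break
    else:
        raise SimulationError("algebraic equilibrium did not converge")

    out = np.zeros(len(network.species))
    out[sp] = conc_of(x)
    return out


# ======================================================================
# convenience runs and scans
# ======================================================================

def run_reaction(params: ParameterSet, substrate: str, int_total: float,
                 rdf_total: float, times_s: Sequence[float],
                 dna_conc: float = 10.0, network: ReactionNetwork = None,
                 **build_kw):
    """Build (or reuse) a network, simulate one reaction, return result."""
    from .network import build_network
    if network is None:
        network = build_network(params.variant, params, **build_kw)
    c0 = initial_state(network, substrate, dna_conc, int_total, rdf_total)
    return simulate(network, c0, times_s)


def concentration_scan(variant: Variant, params: ParameterSet, substrate: str,
                       int_grid: Iterable[float], rdf_grid: Iterable[float],
                       t_hours: float = 3.0, dna_conc: float = 10.0):
    """3-h (by default) endpoint yields over an integrase x RDF grid.

    Returns a tidy DataFrame (int_total_nM, rdf_total_nM, substrate,
    time_h, fraction_recombinant, error).  Failures at single grid points
    are flagged in the ``error`` column and do not abort the scan.
    """
    import pandas as pd
    from .network import build_network

    network = build_network(variant, params)
    rows = []
    for int_total in int_grid:
        for rdf_total in rdf_grid:
            if int_total < 0 or rdf_total < 0:
                raise ValueError("grid concentrations must be non-negative")
            row = {"int_total_nM": float(int_total),
                   "rdf_total_nM": float(rdf_total),
                   "substrate": substrate, "time_h": float(t_hours),
                   "fraction_recombinant": np.nan, "error": ""}
            try:
                if int_total == 0:
                    row["fraction_recombinant"] = 0.0
                else:
                    c0 = initial_state(network, substrate, dna_conc,
                                       int_total, rdf_total)
                    sim = simulate(network, c0, [t_hours * HOUR])
                    row["fraction_recombinant"] = float(
                        fraction_recombinant(sim, substrate)[-1])
            except (SimulationError, ValueError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
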