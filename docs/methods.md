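# Methods

## Reaction networks

Three model variants share one construction (`phic31rec.network`).

**Solution phase.**  Integrase monomers dimerize (`ii`, dissociation
constant `K_ii` = 25 nM) and the dimer binds two RDF monomers sequentially
(`ir`, per-site dissociation `K_ir` = 5 nM), giving int2, int2rdf1 and
int2rdf2.  Protein complexation is evolved kinetically from free monomers
rather than pre-equilibrated; at the reference association rate
(0.01 1/(nM·s) ≈ 1e7 1/(M·s)) solution binding relaxes in seconds, far
below the readout times, so the distinction is immaterial for every
quantity the package reports.

**DNA binding.**  Plasmid species are the unordered occupancy of the two
att sites over {empty, int2, int2rdf1, int2rdf2, int2-tetramer}; both sites
of a substrate share one per-site constant (`K_b1` for pPB sites with int2,
`K_b2` for pLR, `K_b3`/`K_b4` for the RDF-loaded dimer on pLR/pPB) with
identical-sites statistical factors (first dimer on at 2·kf, second at kf;
reverse mirrored).  These factors cancel around every closed pathway and
are excluded from closure bookkeeping.  int2rdf1 binds with the affinity of
the RDF-loaded unit for that substrate — a modelling choice; only its
unproductive role matters.

**Productive and unproductive complexes.**  Only a plasmid with *both*
sites carrying bare int2 synapses through `s1` (pPB) or is reachable by
desynapsis `s2` (pLR); only one with both sites carrying int2rdf2 uses
`s3`/`s4`.  Every mixed or partially RDF-loaded occupancy is
synapsis-incompetent, which is what makes the +RDF yield collapse below a
1:1 RDF:integrase ratio and plateau above it.  Tetramer inhibition (a
second int2 docking onto an int2-occupied site, association `K_inh`)
applies to the attP/attB substrate by default (`inhibit_all_sites` extends
it), producing the mild yield decline at high integrase.

**Core pathway.**  `s1 → r1 → mod → s2` (−RDF) and `s3 → r2 → modr → s4`
(+RDF), with `s2`/`s4` *named in the desynapsis direction* — their K are
desynapsis constants.  This sign convention is load-bearing: with it, the
closure products read `K_b1²·K_s1·K_r1·K_mod·K_s2 = K_b2²` (and the b3/s3
analogue), re-closing after a K_r1 or K_mod perturbation *lowers* K_s2, and
the compensated perturbations raise the product yield.  Model 0 omits
`mod`/`modr` and desynapses `LR-int_s1`/`PB-int-rdf_s1` directly.  The
linear variant replaces the plasmid by four independent fragments with one
site each; synapsis is bimolecular (`K_s1`, `K_s3` in 1/nM; `K_s2`, `K_s4`
in nM), so the closure products stay dimensionless.  Antiparallel
(exchange-incompetent) synapses are not distinct species; they are absorbed
into the effective rate of `r1`.

The linear network has a fifth conservation law beyond the four moiety
totals (P-fragments, B-fragments, integrase and RDF monomers): every
synapse pairs one P-type with one B-type fragment, so the attP−attB
occupancy-state difference is invariant.  All equilibrium solvers therefore
work with the full left null space of the stoichiometry matrix, not just
the moiety totals.

## Thermodynamics

`wegscheider_residuals` reports the absolute signed log-sum of equilibrium
constants along each pathway; a set is "closed" below 1e-9.  `K_s2` and
`K_s4` are the closure-derived constants everywhere (fits, robustness,
perturbations) because the natural perturbation experiments compensate
through them.  Re-closing preserves every forward rate and rederives
reverse rates, so a closure operation never changes kinetics except through
the re-derived constant.  Free energies use ΔG = RT·ln(Γ/K_eq) with every
DNA-containing species at 10 nM and every unbound protein complex at
200 nM; temperature defaults to 303.15 K (the reactions' 30 °C), and ΔG
scales linearly in T as it must.

## Simulation and equilibria

The networks are stiff (second-scale binding next to ~1e-6 1/s synapse
turnover), so `simulate` uses scipy's BDF with the analytic Jacobian,
rtol 1e-8 / atol 1e-12 nM.  Requested readout times are exact evaluation
points.  Concentrations below −1e-9 nM abort; smaller negative excursions
are clipped to zero.  Conservation drift above 1e-6 relative anywhere on a
trajectory is an error, not a warning.

Equilibria are computed two independent ways.  The production route
integrates to 1e8 s (≈ 200× the slowest relaxation) and polishes with a
damped Gauss–Newton iteration on rhs = 0 in log-concentration space under
the conservation constraints, accepting only max |rhs| < 1e-10 nM/s; at the
accepted state every individual step flux is below 1e-12 nM/s (detailed
balance — these closed reversible networks have a unique equilibrium per
stoichiometric class, which is also why pPB- and pLR-started systems land
on the same composition).  The independent oracle
(`algebraic_equilibrium`) never integrates: closure makes log formation
constants well-defined, the equilibrium manifold is `c = exp(g + Lᵀx)`
with one unknown per conservation law, and the totals equations are the
gradient of a strictly convex function minimized by damped Newton.  Tests
require the two routes to agree to 1e-6 relative (they agree to ~1e-14).

## Parameters

The published per-step values for this system are not redistributable
here, so the shipped reference sets are *calibrated reconstructions*
(`analysis/01_calibrate_parameters.py`): the binding scaffold is fixed at
literature-scale values (association 0.01 1/(nM·s); per-site affinities
K_b1 = K_b3 = K_b4 = 0.05 1/nM with attL/attR twice attP/attB, K_b2 = 0.1;
K_s1 = K_s3 = 10; K_ii = 25 nM, K_ir = 5 nM; K_inh = 5e-4 1/nM), and the
twelve synapsis/exchange/modification constants and rates are fitted to the
published summary outputs of the final model: 68%/75% for P × B (−RDF) at
30 min/equilibrium, <0.2% at 1 h and 25% at equilibrium for L × R (−RDF),
62%/67% for L × R (+RDF), 3.2% at 60 min and 33% at equilibrium for
P × B (+RDF), the 3-h yields at 200/800 nM, and the compensated-perturbation
equilibrium yields (86% and 80%).

Two calibration facts worth knowing.  First, the baseline P × B
equilibrium is set to 75.3% as the compromise between the quoted 75%/25%
equilibrium pair and the 76% baseline of the perturbation analysis.
Second, with the equilibrium at that level the re-closed doubling of K_r1
or K_mod can raise it to at most ≈ 2× the baseline odds (85–86%); the
calibrated set reaches 85.1% (K_r1) and 84.8% (K_mod).  The fitted
K_mod ≈ 21 makes the stable synapse LR-int_s2 dominate LR-int_s1 at
equilibrium more strongly than a mid-range K_mod would; yield data alone
only pin the closure-constrained combination (the fitter flags the
K_mod–K_s2 direction as sloppy).

Free parameters number 28 (13 equilibrium constants after removing the two
closure-derived ones, plus 15 forward rates).  Fit bounds default to
1e-6–1 1/(nM·s) for forward rate constants (≈1e3–1e9 1/(M·s)) and wide
positivity for K.

## Robustness and perturbations

`robustness_scan` doubles and halves every free parameter, re-closes
(default; a `direct` diagnostic mode skips re-closure and builds the
network unclosed), and records the change in maximal product fraction over
the first 3 h of the two permitted reactions (400 nM integrase, 800 nM RDF
for L × R, 10 nM plasmid).  On the reference set the largest change is
≈25% (halving K_r2), all below 33%, with the strand-exchange and
modification constants dominating — consistent with those being the steps
whose engineering should raise conversion.

## Synthetic data

`default_design()` is a 92-cell reconstruction of the underlying study
design: two 16-point triplicate time courses (pPB at 400 nM integrase; pLR
at 400+800 nM), a 12-point 2-fold integrase titration (0.39–800 nM, −RDF)
and a 12×4 integrase-by-RDF-ratio grid (ratios 0.25–2), all endpoints at
3 h, all cells at 10 nM plasmid.  The exact published split of the 92
points and the grid axes are not in the main text; these values are
package defaults, documented as such.  Noise is additive Gaussian on the
fraction scale, sd 0.03 (the scale of the published triplicate error
bars), truncated to [0, 1]; each cell records the mean and sample SD of
n = 3 replicates, so an unweighted SSR against cell means has expectation
(cells)·sd²/3 under the truth.  Not emulated: gel-quantitation artefacts,
within-course covariance, protein-activity drift.  Passing recovery tests
therefore validate the estimator under the stated noise model, not against
those real-data error sources.

## Problem sizes and runtimes

The plasmid networks have 36 (Model 1) / 34 (Model 0) species and ~43
steps; the linear network 29 species.  A 3-h stiff integration runs in
tens of milliseconds, the full robustness scan (112 simulations) in ~15 s,
and the complete acceptance recomputation in about a minute on one CPU.
Analysis scripts use these sizes throughout; the calibration script is the
only long-running piece (minutes).

## Known limitations

DNA topology (supercoiling energetics, knotting) and integrase
inactivation are deliberately out of scope.  The unproductive-complex and
tetramer-inhibition stoichiometries are minimal schemes consistent with
the qualitative record, not structures; the int2rdf1 DNA affinity is an
assumption.  Model 0's parameter set is a qualitative reconstruction used
to exhibit its failure modes, not a fit.  The +RDF 3-h yields at 200 nM
integrase land a few points below the experimentally quoted 70%/12%
(65.5%/8.3%): with this scheme those endpoints trade off against the
exactly-quoted 400 nM model outputs, and the calibration favours the
latter.
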