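# Methods

## Community model and problem formulation

Each member organism is a constraint-based metabolic network: stoichiometric
matrix S, flux vector v (mmol/gDW/h), bounds LB ≤ v ≤ UB, one biomass
reaction whose flux is the specific growth rate.  Exchange reactions touch
exactly one metabolite and follow the COBRA sign convention (negative flux =
uptake).  A community joins members through a shared extracellular pool: each
member exchange is rewired into a transfer between the member's boundary
metabolite and the pool species, and the pool trades with the environment
through community exchange reactions that carry the medium bounds.

Balanced growth means every member grows at the common community rate μ.
Member fluxes are expressed in absolute units (mmol/h per unit of total
community biomass), so capacity bounds scale with the member's biomass
fraction X_k and the biomass flux couples as V_biomass,k = μ·X_k.  Members
with zero abundance are permitted: the scaled bounds force their entire flux
vector to zero.  Total abundance is normalized to 1, making the X_k the
relative abundances that are measured experimentally; the absolute-flux basis
(per unit total community biomass) follows from that normalization.

For fixed μ the whole system — member steady states, scaled bounds, biomass
coupling, pool balances, abundance normalization — is a linear program.  All
LPs are solved with HiGHS (scipy front end) at a primal/dual feasibility
tolerance of 1e-9.

## Optimization sequence

**Maximum balanced growth.**  μ* is the largest μ for which the fixed-μ LP is
feasible.  It is located by bisection over [0, 10] h⁻¹ to a tolerance of
1e-6 h⁻¹.  Feasibility of the bracket top raises an "unbounded growth" error
(some uptake must be limiting); infeasibility at μ = 0 is reported as such.

**Minimal fiber uptake at fixed growth.**  With μ pinned at the observed
community growth rate, the community's fiber uptake magnitude is minimized.
This is the dual view of maximizing growth at fixed fiber consumption, and
the pair of solves is verified against each other in the test suite.  Because
the LP optimum is typically degenerate in the flux space, the reported
distribution additionally minimizes the total absolute member exchange flux
at the optimal fiber uptake (auxiliary magnitude variables, one extra LP);
any single-valued "optimal flux" table needs such a tie-break rule to be
reproducible.

**Suboptimal relaxation.**  The fiber budget u′ is the minimal uptake that
would support (1+ε)·μ_exp, with ε = 0.05 by default.  Downstream analyses fix
growth back at μ_exp and constrain fiber uptake by the *inequality*
uptake ≤ u′.  The inequality (rather than pinning uptake at u′) is the design
choice here: the scenario grants headroom, it does not force its use.  On a
linear yield chain u′ = (1+ε)·u_min exactly, which the tests exploit.

**Flux variability.**  Each requested abundance or exchange flux is minimized
and maximized over the suboptimal polytope (two LPs per quantity).  Witness
solutions and sampled points are asserted to lie inside their ranges within
1e-6.

## Flux sampling

Once μ is fixed the feasible set is a bounded convex polytope.  Sampling uses
artificial-centering hit-and-run over the full variable space: directions are
differences between a randomly chosen previously seen point (warm-up or
retained sample) and the running center, projected onto the null space of the
equality block; the next state is drawn uniformly from the feasible chord.
The state is re-projected onto the affine subspace through an anchor point at
every step, so floating-point drift in the equality residuals cannot
accumulate — without the projection, near-duplicate warm-up points can turn
solver residuals (~1e-9) into order-one constraint violations after
normalization.  Retained samples are every thinning-th state.

Defaults follow the study configuration: 200,000 retained points with
thinning 100.  Warm-up uses min/max extremes of each coordinate in a seeded
random order plus random dense objectives, 2×dimension points capped at
2,000.  The chain is fully deterministic under a fixed seed (bit-identical
replay).  Tests and the acceptance script run 2,000–10,000 retained points —
problem sizes chosen so the whole suite re-derives every property in minutes
on one core — with thinning preserved at the study value where the scenario
polytope is sampled.

Calibration checks: per-coordinate means of a unit-box sample within 3 Monte
Carlo standard errors of 1/2; split-half column-mean consistency; feasibility
of every retained row within 1e-6.

## Exchange statistics

A (member, metabolite) exchange is classified from its sampled flux column:
*produced* if the median is positive and significantly different from zero,
*consumed* if negative and significant, *indeterminate* otherwise.
Significance uses the one-sample Wilcoxon signed-rank test against zero at
α = 0.01.  The question is a one-sample median-versus-zero comparison, which
is the signed-rank test's domain; the two-sample rank-sum test does not apply
to a single flux distribution, so the signed-rank form is used deliberately.
Zeros are dropped per the classical procedure; an all-zero column is reported
indeterminate with p = 1 and flagged.  No multiple-testing correction is
applied; the α = 0.01 threshold is interpreted per raw test.

Coupling between exchanges is measured by Pearson correlation (Spearman
available behind a flag); constant columns are excluded and logged.  A
secreted metabolite whose pool has no environment exchange must be absorbed
by the partner flux-for-flux, which forces a coefficient of exactly −1 — an
algebraic identity the tests assert to machine precision.  Because retained
Markov-chain samples are autocorrelated, nominal p-values overstate
significance; every report carries this caveat, and the classification is
applied to the retained samples as configured rather than to an
effective-sample-size correction.

Density summaries (fixed-width histograms over the observed range, median,
central 95% interval) share the median computation with the classifier, so
the two reports agree exactly.

## Media, fibers and curation

Media are defined by positive uptake magnitudes per exchange reaction plus a
single designated carbon source.  Applying a medium closes every
carbon-containing exchange that the medium does not list (lower bound 0) and
opens carbon-free nutrients at an excess value of 1000 mmol/gDW/h — "in
excess" made concrete, large enough never to bind in any shipped scenario.
Carbon is counted by parsing element counts from metabolite formula strings;
metabolites without formulas are treated as carbon-free and logged.

Dietary fibers are modeled as average-length homopolymers: a fiber species of
degree of polymerization DP carries DP × (monomer carbon) carbon atoms, and
its degradation reaction fiber → DP·monomer must balance carbon exactly in
integer arithmetic.  This normalization makes uptake fluxes of fibers with
different chain lengths comparable per carbon, which the tests verify as an
invariant (equal growth per carbon across DP on a yield-only model).

Curation edits (add/remove reaction, set bounds, set formula) apply
atomically in file order from YAML, keep an audit log, and are invertible;
apply-then-revert is tested to be the identity.

## Synthetic study community

The toy community emulates the degrader/butyrogen topology of fiber
fermentation: a degrader hydrolyzes a DP-5 fiber into 6-carbon monomers and
ferments them to lactate (1.0 per monomer), succinate (0.3) and acetate
(0.6), with biomass yield 0.02 gDW/mmol monomer; a butyrogen grows on
lactate (yield 0.05 gDW/mmol) with 0.5 acetate co-consumed and 0.7 butyrate
secreted per lactate.  Both members carry a carbon-balanced lactate→acetate
rerouting reaction (3 C → 1.5 × 2 C), giving the suboptimal polytope genuine
width beyond the abundance axis.  The community lactate pool is closed to the
environment by default, so lactate is fully coupled between the members; the
acetate pool stays open, so its coupling is strong but imperfect — the same
qualitative pattern reported for the real consortium.  Fiber uptake is capped
at 1 mmol/h.

These choices give closed forms (module docstring of
`steadycross.synthetic`): μ* = 0.35 h⁻¹, optimal abundances 2/7 and 5/7 with
the butyrate producer dominant, u_min(μ) = μ/0.35, and u′ = 1.05·u_min.  The
scenario growth rate 0.3 h⁻¹ sits below μ*, as an experimentally observed
rate would.  Biomass carbon is whatever the fermentation stoichiometry leaves
of the monomer (30 and 24 mmol C/gDW for the two members — physiological
magnitudes); parameter sets that emit more carbon than they take up are
rejected at construction.

What the generator does *not* emulate: genome-scale network size and
redundancy (members have ≤ 15 reactions), thermodynamic or regulatory
constraints, maintenance ATP, multiple fibers per scenario, and biological
noise.  Passing tests therefore demonstrate correctness of the optimization,
sampling and statistical machinery on analytically known ground truth — not
predictive accuracy on real organisms, which depends on the quality of the
curated input reconstructions.

## File formats and provenance

Models read and write as SBML Level 3 + FBC v2 (via libsbml; biomass and
exchange reactions annotated with their SBO terms) and as a JSON dialect that
mirrors the FBC content model field-for-field; JSON output is canonically
ordered, making read→write→read a byte-level fixed point.  Sample matrices
are stored as CSV with a JSON metadata side-car (seed, config, scenario
fingerprint) rather than HDF5, keeping all artifacts plain text.  Pipeline
runs write a manifest with the config snapshot, seed, package version,
per-stage timings and a SHA-256 checksum per file; identical config and seed
reproduce all outputs byte-identically (provenance headers included).

## Known limitations

- Bisection assumes feasibility is monotone in μ, which holds for the
  SteadyCom constraint family but not for arbitrary extra constraints.
- The secondary minimum-|exchange| objective picks one optimal flux
  distribution; other tie-break rules would report different single values
  inside the same FVA ranges.
- Hit-and-run mixing is not diagnosed beyond the calibration checks; strongly
  elongated polytopes may need more thinning than the default.
- The Wilcoxon test on thinned chain samples still underestimates
  uncertainty; classifications near the α threshold should be read with the
  autocorrelation caveat in mind.
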