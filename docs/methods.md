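# Methods

## Problem setting

Continuous (chemostat) cultures provide, per growth condition, one steady
state: measured metabolite concentrations, exchange rates derived from
influent/effluent differences, and a balanced internal flux distribution.
The package treats that snapshot as a constraint set and samples the space
of kinetic models compatible with it. Each retained model is a complete
elementary-rate-constant parameterisation that reproduces the reference
steady state exactly and is thermodynamically consistent; the ensemble of
such models expresses the remaining kinetic uncertainty. Metabolic control
analysis (MCA) on each model, summarised by per-pair ensemble medians,
yields condition-specific control patterns.

## Model layer

A model is a set of compartments (id, pH, volume fraction), metabolites
(compartment, measured flag, fixed flag) and reactions (signed
stoichiometry, mechanism label, drain flag, regulators). *Fixed* species —
protons pinned at 10^-pH and extracellular pools — appear in rate laws and
Gibbs energies but are excluded from mass balance and from the dynamic
state. *Drains* (uptake, secretion, per-metabolite balancing sinks) are
exempt from thermodynamic constraints and follow first-order mass action in
the species their flux direction consumes, calibrated to the reference
flux; a drain with no non-fixed substrate is a constant-rate supply.

The packaged yeast central-carbon network (`kincontrol.yeast_ccm()`,
`data/yeast_ccm_synthetic.json`) is a curated reconstruction of the iMM904
central-carbon subnetwork — glycolysis, pentose phosphate pathway,
fermentation/glycerol branches, TCA cycle, lumped respiration
(P/O folded into one reaction), exchange and balancing drains — sized at
82 reactions, 52 metabolites and 3 compartments (cytosol pH 7.2,
mitochondria pH 7.5, extracellular), with 4 allosteric reactions: PFK
(ATP inhibition, inorganic-phosphate activation), PYK (FBP activation),
G3PD1ir (inorganic-phosphate inhibition) and ICDHxm (AMP activation). Some
steps are deliberately lumped to stay inside the published dimensions
(e.g. succinate dehydrogenase + fumarase); per-reaction mechanism labels
follow the generic ordered-binding convention described below. The file is
synthetic in the sense that it was assembled from textbook network
structure, not exported from any external model file.

## Processing of measurements

Concentration bounds (molar): a measured cytosolic metabolite with value c
gets [0.5c, 1.5c]; a measured mitochondrial metabolite gets
[1e-15, 100 x 1.5c] — the 100-fold relaxation covers the extreme in which a
whole-cell measurement is localised entirely in the ~1 % mitochondrial
volume, and the reading of "100-fold" as multiplying the default upper
bound is configurable; a species present in both cytosol and mitochondria
keeps a 1e-15 M lower bound in both; unmeasured metabolites get the
non-informative [1e-15 M, 10 M] box. The reference concentration is the
measured value (geometric mean of the bounds when unmeasured). Protons are
pinned at 10^-pH per compartment. Compartment volumes enter only these
bound rules, never flux balancing (fluxes are per-cell quantities).

Exchange rates follow the chemostat balance q = D (c_out - c_in) / X
(mmol gDW^-1 h^-1; positive = secretion), with dilution rate D (1/h) and
biomass density X (gDW/L). Internal fluxes are consumed as a table — the
package does not re-derive them by flux balance analysis. Drain balancing
then closes every internal metabolite's mass balance: any metabolite with
nonzero net production gets (or re-uses) a single-metabolite sink drain
carrying the closing flux; the returned reference flux vector satisfies
|S_internal v| <= 1e-9 relative to the flux scale.

## Thermodynamic layer

With R = 8.314e-3 kJ mol^-1 K^-1 and T = 303.15 K (30 degC), the reaction
Gibbs energy at concentrations x is dG = dG0 + RT sum_i s_ij ln x_i.
Standard ranges [dG0_lo, dG0_hi] are inputs (eQuilibrator-style tables,
kJ/mol); attainable ranges over a concentration box take per-species box
extrema by stoichiometric sign. One thermodynamic sample draws ln x
uniformly in its box, then per reaction draws dG uniformly from the
subinterval of its attainable range that opposes the flux sign (truncated
sampling — equivalent to accept/reject on a uniform dG0 draw but cheaper);
dG0 is recovered from the identity, so dG = dG0 + RT sum s ln x holds
exactly. An empty subinterval raises a structured infeasibility naming the
reaction and counts as one failed sampling attempt; these dominate the
attempt overhead in practice. Fluxes are fixed at the condition's balanced
reference vector — one steady-state data point per condition — rather than
sampled from intervals.

## Kinetic sampler

Every non-drain reaction expands into a cycle of elementary steps over
enzyme forms: ordered substrate binding (one step per stoichiometric unit),
one catalytic interconversion, ordered product release. Essential
activators wrap the cycle (bind first, release last); competitive
inhibitors occupy dead-end branches off the free enzyme. Fixed species
bind like any other species, with their pseudo-first-order factor constant.
Concentrations are normalised to the reference (u = x/x_ref = 1 at
reference), which makes the rate-constant solve closed-form:

1. step reversibilities: a flat Dirichlet weight vector w partitions the
   reaction's Gibbs energy onto the cycle steps, dG_i = w_i dG, so each
   step's reverse/forward unidirectional ratio is r_i = exp(dG_i / RT) and
   every step inherits the overall direction;
2. enzyme-form abundances e are a flat Dirichlet draw over all forms
   (dead-end forms included);
3. per cycle step, f_i = v_ref / (1 - r_i) and b_i = r_i f_i give net flux
   v_ref through every step, hence the sampled e is exactly a quasi-steady
   state; k+_i = f_i / e_source, k-_i = b_i / e_target. Dead-end steps get
   zero net flux with a log-uniformly sampled exchange rate. |dG_i| is
   floored at 1e-9 kJ/mol so near-equilibrium steps stay finite; a
   zero-flux reaction is treated as at equilibrium (f = b).

The construction enforces the Haldane relation exactly: the product of
k+/k- around the cycle times the reference mass-action ratio equals
exp(-dG0/RT) (verified to 1e-6 relative in the tests, limited only by the
dG floor).

Allosteric reactions are modulated by a concerted (MWC-style) active
fraction rho(x) = 1 / (1 + L_eff(x)) with
L_eff = L0 prod_inh (1 + x/K)^n / prod_act (1 + x/K)^n; L0 is log-uniform
over [1e-2, 1e2], each effector's half-saturation K log-uniform within the
effector's concentration bounds, and n the reaction's subunit count
(default 4). The catalytic cycle is calibrated against v_ref / rho(x_ref),
so the reference state is still reproduced exactly. This K-type modulation
does not attempt conformation-specific substrate binding.

Rates at arbitrary concentrations solve the linear King–Altman system for
the enzyme-form distribution (the generator matrix of the form-transition
graph has a unique positive stationary vector) and evaluate the net
catalytic-step rate, scaled by enzyme level and active fraction. Net rate
sign always equals the thermodynamic driving-force sign, so sign
consistency holds automatically away from the reference too.

## Stability and control analysis

The dynamic state is u (internal metabolites, normalised); conserved
moieties are removed by the link decomposition S = L S_R (independent rows
found by pivoted QR). The reduced Jacobian S_R (dv/du) L is evaluated with
central differences in ln u (step 1e-6; only metabolites a rate law can
depend on are perturbed). An instance is stable when max Re(lambda) is
strictly below 1e-5 in reciprocal time units of the flux scale — the small
positive threshold tolerates numerically-zero modes on top of the moiety
reduction, and the strictness direction at exactly the threshold is
documented as unstable. Filtering is on by default and can be disabled
(the ensembles then annotate rather than discard).

Scaled flux control coefficients use the standard matrix identities with
dv_j/dE_k = delta_jk v_j / E_k (rates linear in enzyme level):
dxi/dE = -(S_R' eps L)^-1 S_R' dv/dE and dJ/dE = dv/dE + eps L dxi/dE,
scaled by E_k / J_i. The summation theorem (rows sum to 1) is an algebraic
consequence and is asserted to 1e-6 per instance. Zero-flux rows are
undefined (NaN) and excluded from medians. One numerical subtlety: because
sampled reference concentrations can span ~12 decades (the mitochondrial
bound relaxation reaches down to 1e-15 M), the 1/x_ref-scaled residual is
catastrophically ill-conditioned; steady-state residuals and the MCA linear
solve therefore use the unscaled stoichiometric rows (same independent-row
selection), while the scaled pair defines the dynamics and its conserved
manifold.

The independent oracle re-solves the steady state after scaling one enzyme
by (1 + delta), delta = 1e-6, via damped Newton on the reduced coordinates
(positivity-preserving line search, convergence at 1e-12 of the residual
scale, stall acceptance at the floating-point noise floor) with an
LSODA-integration fallback, and differences the log fluxes. Analytic and
finite-difference coefficients agree to 1e-4 absolute on all fixtures;
linearly unstable instances are refused by the finite-difference route
(their perturbed states are not attractors), never silently reported.

## Ensemble campaign

Per condition, sampling attempts repeat until the retention quota
(default 100) of feasible, stable instances is met, executing at least 120
attempts; surplus acceptances during post-quota mandatory attempts are
logged, not retained. Each attempt's generator is seeded from (base seed,
CRC32 of the condition label, attempt index), so attempt streams are
auditable and independent of acceptance history, and entire campaigns are
bit-reproducible. Rejections are counted per stage (thermodynamic
infeasibility, kinetic solve failure, instability); an acceptance rate
below 0.5 % after ten times the minimum attempts aborts with diagnostics.
Condition summaries are per-pair ensemble medians (long-format tables ready
for heat-map rendering); cross-condition comparison uses the two-sample
two-sided Kolmogorov–Smirnov test per pair, with Benjamini–Hochberg
adjusted p-values reported alongside the raw ones.

## Synthetic data generator

The generator stands in for the chemostat dataset with known ground truth.
Templates: `linear_chain(n)`; `branched_glycolysis_mini` — a reversible,
saturable glucose transporter (the uptake drive), an ATP-coupled
hexokinase-like step with competitive product inhibition, a fermentative
branch (1 ATP per unit flux) carrying an allosteric ATP inhibition
(PFK-like, n = 4), a respiratory branch (2 ATP), a first-order maintenance
ATPase and secretion drains, with the adenylate pair as a conserved moiety;
`two_compartment_mini` (distinct pH per compartment); and
`atp_competition_mini` (the branched template plus a trehalose-like storage
branch that competes with the kinase for internal glucose *and* ATP). The
transporter, not a constant-rate drain, carries the uptake: with a
zeroth-order supply the kinase would have structurally zero control over
every flux, making control comparisons vacuous.

Reference condition: the highest dilution rate (uptake enzyme level 1);
reference fluxes are a hand-balanced distribution (uptake 1.0 mmol/gDW/h,
fermentative : respiratory split 0.6 : 0.4) and concentrations are
realistic molar scales (ATP 2 mM, ADP 0.5 mM, intermediates 0.2–2 mM).
Each non-drain reaction is assigned a ground-truth driving force of
-7 kJ/mol at reference (sign following the flux), from which the true dG0
follows; the published-style input table brackets it at +/-3 kJ/mol. The
generating kinetic instance is drawn by the same sampler the pipeline uses
(redrawn, bounded retries, until it is stable and every condition
converges); a hand-written reversible mass-action system
(`MassActionSystem`) implementing the same evaluation protocol breaks the
circularity of testing the sampler against itself.

Conditions: the dilution sweep 0.05, 0.11, 0.16, 0.22, 0.30 1/h scales the
transporter level by D / 0.30 (warm-started continuation solves each
steady state); the four nutrient-limitation variants run at D = 0.11 with
limitation-specific maintenance multipliers (phosphate 1.3, ammonia 1.15,
leucine 0.85, uracil 0.7) — chosen once as plausible energy-demand shifts.
Measurements multiply the true steady-state concentrations by lognormal
noise (sigma = 0.2 by default; concentrations only — fluxes derive from
balances and stay noiseless), then pass through the exact bound rules used
for real data.

What the generator does *not* emulate: correlated measurement error across
metabolites, flux uncertainty, missing measurements beyond an all-or-none
subset flag, condition-dependent network structure (e.g. true Crabtree
regime switching), or the real dataset's quantitative values. Passing
tests therefore demonstrate the pipeline's internal correctness and
recovery behaviour under its own generative assumptions, not agreement
with any wet-lab measurement.

On the purpose-built `atp_competition_mini` template, the ground-truth
control of the kinase over the storage flux flips sign with supply
(-0.79 at D = 0.05 to +0.15 at D = 0.30 for the default generator seed):
at low drive the substrate competition dominates, at high drive the ATP
coupling through the producing branches wins. In any *linear* mass-action
pathway this orientation is impossible — at low supply the network is in
its linear regime where the marginal ATP yield of extra carbon equals the
average yield, which must cover the kinase's own ATP cost — so the flip is
a genuinely saturation-driven effect, which is why it is asserted on a
sampled elementary-kinetics instance rather than on a mass-action fixture.

## Problem sizes and determinism in the test suite

The default campaign (9 conditions x quota 100, >= 120 attempts each) runs
in a few seconds on one core; the convergence diagnostic grows one
condition's ensemble to 1000. All tests and the acceptance script are
seeded and deterministic; the ensemble-median convergence check (medians at
n = 100 vs n = 1000 within 0.05 for >= 95 % of pairs) sits close to the
sampling error of a median at n = 100 for the transporter-enzyme pairs
(IQR up to ~1), so it is assessed at the package defaults (generator seed
0, base seed 0, the mid-sweep glucose-limited condition) and can land
either side of the bar at other seeds.

## Known limitations

* Mechanism assignments beyond the generic ordered convention (random-order
  bi-bi, ping-pong) are not implemented; the mechanism label is carried but
  all cycles are built ordered.
* The MWC treatment modulates the whole cycle by an active fraction; it
  does not distinguish R/T-state binding affinities.
* Drains are first-order (or constant) by construction; saturable
  transporters should be modelled as non-drain reactions.
* Flux measurement uncertainty is not propagated — fluxes are point values
  per condition, as in the single-steady-state setting the pipeline
  targets.
* Concentration control coefficients and response coefficients are out of
  scope (flux control only).
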