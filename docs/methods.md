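# Methods

## The problem

During the first half hour of a 30 °C → 39 °C heat shock, baker's yeast
rearranges its sphingolipid metabolism: the six readily measured species —
dihydrosphingosine (DHS), phytosphingosine (PHS), their 1-phosphates
(DHS-P, PHS-P) and the two ceramides (DHC, PHC) — rise several-fold and
return to baseline, while the enzyme activities that drive them change
persistently. The activities themselves are not measurable on this time
scale. `sphingodyn` solves the resulting dynamic inverse problem: given
sparse, replicated fold-change time courses of the six species and a
power-law ODE model of the pathway, infer piecewise-constant fold-change
profiles for the enzyme activities that reproduce the data, quantify which
profiles the data actually determine, and run the validation computations
that probe the inferred regulatory program.

## Model formalism

Models are General Mass Action (GMA) systems in the Biochemical Systems
Theory tradition. Every process rate is

    v_j = γ_j · Π_i X_i^{f_ij},

with rate constant γ_j > 0 and real kinetic orders f_ij. Dependent
variables (metabolite pools) obey ODEs assembled from the stoichiometry of
these fluxes; independent variables (enzyme activities, clamped pools) are
held constant within each 1-minute interval of an activity schedule and
reset at interval boundaries. Enzyme activities are stored as fold changes
relative to baseline; absolute activity = fold × baseline.

Two model sources exist. `load_full_model` imports the full yeast model
(25 ODEs, 41 independent variables) from an SBML file restricted to the
power-law subset; the SBML reader is implemented over the standard-library
XML parser because no SBML library is available in the runtime environment,
and kinetic laws that are sums of power-law terms are split into one flux
per term (reversible laws become a forward/backward flux pair). The model
archive itself is a journal supplement and is not bundled.

`build_core_model` constructs a self-contained reduced model: 10 species
(3-KDHS, the six measured species, IPC, MIPC, M(IP)₂C) and 14 enzymes wired
per the pathway map — SPT entry, reductase, kinase/phosphatase pairs,
ceramide synthase, the two alkaline ceramidases, 4-hydroxylase, the
lyase/remodelase exits and the complex-sphingolipid chain with its
IPCase retrieval route. All baselines are normalized to 1 except 3-KDHS,
which is kept small (0.05) and fast-turning (rate constant 20/min):
the reductase step is physiologically very fast and its toxic substrate
never accumulates, and without this the entry enzyme's activity is
invisible to the data within an interval. Rate constants are a positive
steady-state circulation, so the unstressed model is an exact steady state
(residual < 1e-15), and the DHS node reproduces the full model's
three-influx/three-efflux topology.

## Data preparation

Observations are duplicate fold changes at t = 0, 5, 10, 15, 20, 25,
30 min. Replicates are averaged arithmetically; each species' mean series
is fitted with a cubic smoothing spline whose penalty is chosen by
generalized cross-validation (`scipy.interpolate.make_smoothing_spline`,
override via `lam`; `lam=0` interpolates) and evaluated on the 31-point
per-minute grid. Curves are floored at 1e-6 fold because DHS-P sits near
zero absolutely and must never smooth to a non-positive value. Replicate
scatter is retained (`ObservationSet.replicate_stats`) and is what the
synthetic generator's noise level emulates. The spline family and level are
a documented choice — the original analysis names only "a standard spline
technique" — and results for features faster than the 5-minute sampling are
sensitive to it (see Limitations).

## Piecewise inference

For each interval [t, t+1) the optimizer seeks free-enzyme folds minimizing

    Σ_species ((sim(t+1) − target(t+1)) / baseline)²,

i.e. residuals in fold space, which reproduces the fold-amplification of
the tiny DHS-P pool. The dependent state carries forward from the
simulation across intervals (a data-reset variant sits behind
`reset_to_data`); interval 0 starts from a log-uniform random draw on
[0.25, 4] (spanning the plausible immediate Arrhenius activation up to
about four-fold), later intervals warm-start from their predecessor
(`warm_start=False` redraws each interval). Bounds are [0, 10].

The inner solver is `scipy.optimize.least_squares` (TRF, bound-constrained,
2-point finite differences with `diff_step=1e-3`, ≤ 100 objective
evaluations per interval). The objective's endpoint simulation runs on a
numba-compiled Dormand–Prince RK45 with adaptive steps (rtol 1e-9,
atol 1e-12); the user-facing `simulate()` uses scipy's stiff-capable LSODA
(rtol 1e-8, atol 1e-10) and a property test pins the two integrators to
each other at 1e-6. Two numerical details matter: the finite-difference
step must dominate integrator noise, or the solver stalls on a false
plateau; and states are floored at 1e-12 before power-law evaluation, with
a warning when the integrator dips below zero persistently.

Ensembles repeat the run from seeds derived deterministically (< 2³¹) from
one base seed. Candidates are scored by SSE over the 30 post-baseline grid
points and by AICc, n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1), with n the number
of residuals (6 × 30) and k by package convention the number of free enzyme
*profiles*: counting each per-interval fold value individually would make
n − k − 1 negative and AICc undefined at these problem sizes. Since every
candidate carries the same k, AICc ranking coincides with SSE ranking; the
top-48-of-100 desk-scale selection (the published 2004-of-4144 retention
fraction) therefore overlaps 100% between the two criteria. `compute_aicc`
accepts explicit n and k and raises when n − k − 1 ≤ 0.

## Ensemble summary and identifiability

The selected candidates are reduced per enzyme to a pointwise mean and a
pointwise 2.5%/97.5% quantile envelope ("enclosing 95% of the results" read
per time point, not per curve). The relative band width is the grid-average
of (upper − lower)/max(mean, 1); the normalization floor of one baseline
fold prevents identifiable shutdown profiles (mean activity ≈ 0) from
dividing their way into spurious non-identifiability. Enzymes with mean
relative width below 0.75 classify "tight", else "loose"; both numbers are
package defaults with config overrides, the published classification being
qualitative. Identifiability here is a statement about observability: with
six measured species, six observable core-controlling enzymes form a
generically determined per-interval system and classify tight, while
enzymes acting only on unmeasured complex-lipid pools retain the full
spread of their random initializations.

## Validation computations

* **Mean-activity refit** — simulate under the ensemble-mean schedule and
  compare its SSE against the selected members' median (pass factor 2 by
  default): averages of good fits are not automatically good fits.
* **Complex-lipid flatness** — the inferred activities must leave IPC,
  MIPC and M(IP)₂C within ±0.25 fold of baseline; these species never
  enter the objective, making this an out-of-sample check.
* **Negative control** — clamp the identifiable core enzymes at fold 1,
  re-optimize everything else at equal seeds, and require the constrained
  best SSE to be strictly worse.
* **Cumulative precursor production** — the running integral of all
  3-KDHS-producing fluxes along a simulation; under baseline activities
  with constant entry flux it is exactly linear, and re-adding the
  consumption integral reproduces the net concentration change (flux
  bookkeeping identity). Under the stress schedule the curve starts
  steeper than baseline and flattens as entry shuts down.
* **Q10 estimation** — the immediate activity jump is read as a pure
  Arrhenius effect of the 9 °C step: Q10 = (peak early fold)^(10/9), peak
  over the first 3 minutes (the spike precedes deactivation by only a few
  minutes). A fold of 4 maps to Q10 ≈ 4.67.

## Synthetic data: what it emulates and what a green test means

The generator states the world the pipeline is tested in: per-enzyme
activity archetypes with the reported qualitative shapes (spike-then-
shutdown, spike with a late transcriptional rise after ~26 min, sustained
hyper-activity for ~20 min, triphasic, flat), simulated through the model,
sampled at the seven design times in duplicate, with multiplicative
log-normal noise of σ = 0.1 (≈ 10% CV, a conventional lipidomics replicate
scatter; the study never quantifies its own). Everything derives from one
master seed.

The default recovery design frees the six observable core-controlling
enzymes {X57, X36, X41, X34, X54, X43} plus two unobservable probes
{X35, X55}; the truth moves exactly those, keeping it inside the inference
class. This choice is deliberate: freeing all 14 enzymes gives each
1-minute problem a 5–6-dimensional null space (verified by SVD of the
endpoint sensitivity), after which ensembles reproduce the data with
arbitrary flux throughput and "recovery" is undefined — which is itself
the observability asymmetry the analysis is about. A green recovery test
therefore establishes that the pipeline recovers what the data determine;
it does not establish that real, underdetermined runs recover the cell's
true activities.

Known structural limits, measured at desk scale (100 runs, top 48,
σ = 0.1, seed 0):

* The 7-point sampling cannot resolve the sub-5-minute activity spike;
  inferred early folds track the spline's smooth rise, not the true sharp
  peak. Mean-vs-truth correlations are ≈ 0.84–0.93 for the well-conditioned
  enzymes but ≈ 0.7 for the two whose sensitivity directions are weakest
  (X41, X43).
* All ensemble members fit the *same* noisy dataset, so determined
  directions carry a shared bias with near-zero member spread: pointwise
  member envelopes are tight around a slightly wrong curve and cover the
  truth at far fewer than 90% of grid points. Envelope width measures
  non-identifiability, not estimation error; a parametric bootstrap over
  noise realizations, not ensemble spread, would be the right uncertainty
  for determined directions.
* For the same reason, raising σ does not widen envelopes (it shifts
  them); what grows monotonically with σ is the best attainable SSE.

## Degenerate inputs and tie-breaks

Selection ties break by run order (seed order). Fold 0 is a legitimate
knocked-out activity (0^k = 0 for k > 0); zero state under a negative
kinetic order is a domain error. Simulation failures inside the objective
return a large penalty residual; a failed run is recorded and skipped, not
fatal. `select_top` refuses empty candidate lists and over-long selections.

## Limitations

The reduced core model is structurally, not numerically, faithful to the
full 25-ODE yeast model: kinetic orders default to 1, parameters are a
normalized steady-state circulation, and conclusions about specific yeast
rate constants cannot be drawn from it. The full model import is exercised
against a synthetic SBML stand-in only, since the published archive cannot
be redistributed. Per-interval optimization carries no smoothness prior
linking adjacent intervals, matching the original procedure; inferred
profiles are therefore free to be rough at the 1-minute scale.
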