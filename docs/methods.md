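# Methods

## Scope and model family

`halotaxis` implements a ladder of deterministic ODE models of sensory
excitation and adaptation in *Halobacterium salinarum* photo- and
chemotaxis. The biological system: methyl-accepting transducers (Htr) form
receptor–transducer–CheW–CheA (R-TWA) complexes with the photoreceptors SRI
(orange light, attractant) and SRII (blue light, repellent) or with
chemoreceptor binding proteins (BasB/BasT). The active conformation of a
complex drives CheA autophosphorylation and phosphotransfer to CheY; CheYp
controls flagellar motor switching. Adaptation is carried by reversible
methylation of transducer glutamates; demethylation releases methanol,
which the flow assay measures as [methyl-³H]-methanol in timed fractions.

The ladder:

1. **Model 1** — one SRI–HtrI population, a single (activating) methylation
   site class, demethylation rate proportional to activity, constant
   methylation rate.
2. **Model 2** — an antagonistic site pair per transducer (methylation of
   one site favors the active conformation, the other the inactive one),
   linear rates `dm_A = k_dm·A`, `dm_I = k_dm·I`.
3. **Model 3** — nonlinear rates: quadratic in activity, or one of the
   CheY/CheB feedback mechanisms (`fbm1`–`fbm5`).
4. **Model 4** — stimulated and unstimulated transducer populations that
   are conformationally independent but coupled through diffusible CheY;
   the overall signaling activity is their expression-weighted mean.
5. **Model 5** — one cooperative R-TWA signaling unit of `N_tot`
   conformationally coupled heterologous complexes (SRI, SRII, chemo);
   complex-bound CheY (TWAY) regulates demethylation.
6. **Model 6** — Model 5 plus the measurement model: ³H-label bookkeeping,
   ligand inflow lag `T_in`, transport dead time `T_delay`, methanol
   outflow lag `T_out`, and fraction sampling every `T_S` seconds.

## Cluster activity

A signaling unit is a two-state (MWC) system: all complexes are
simultaneously active or inactive. The activity is a Boltzmann weight

    A = Z_act / (Z_act + Z_inact),   Z_x = Π_c Σ_s p_s · exp(−E_x(c, s)),

where the product runs over complexes, the sum over the receptor's
intermediates (photocycle states, or ligand bound/unbound weighted by the
quasi-steady-state occupancy `Lig/(K_D+Lig)`), and the conformational
energies carry a structural offset `F0` plus the methylation term
`2·(m_A·ΔF_act + m_I·ΔF_inact)` (two transducers per complex, mean-field
over sites). This factorizes into `A = 1/(1+exp(Σ_c δ_c))` with per-complex
log balances δ; `enumerate_unit_activity` evaluates the same sum by
explicit enumeration of the joint receptor-state space and agrees with the
factorized form to machine precision — it is the oracle for the fast path.

Methylation enters as the mean methylated fraction per site class: the
deterministic, population-averaged ODE state cannot resolve per-site
combinatorics, and the two-state sum only needs the mean occupancy.

## Photocycles

SRI is a two-state cycle (ground SRI_587 ⇌ long-lived attractant
intermediate SRI_373; uv excitation not modeled); SRII a three-state cycle
SRII_487 →(light)→ SRII_360 → SRII_540 → SRII_487 with both long-lived
intermediates as repellent signaling states. Excitation rates are linear in
photon flux, `k_exc = σφ·I`, with a single excitation-efficiency constant
per receptor (cm²). Short-lived intermediates are omitted.

## Methylation, feedback, and label bookkeeping

Methylation proceeds at a constant per-site rate `k_m` (activity-
independent); demethylation of the two site classes depends on conformation
and, per mechanism, on CheY/CheYp or CheB/CheBp. The favored mechanism
(`fbm2`) uses Michaelis–Menten factors in the regulating unphosphorylated
CheY quantity Y (free CheY in Models 3–4, complex-bound TWAY in 5–6):

    dm_A = k_dm·A·(1 + k_dmY·K_Y/(K_Y+Y)),
    dm_I = k_dm·I·(1 + k_dmY·Y/(K_Y+Y)).

The functional form is constrained by its limits: in a cheY deletion
`dm_A → k_dm·A·(1+k_dmY)` and `dm_I → k_dm·I`; at saturating CheY the roles
exchange. Any form meeting these limits is admissible; the tests assert the
limits, not the formula. Note the sum rule `φ_A + φ_I = 2 + k_dmY`: every
site-symmetric observable depends on `k_dm·(2+k_dmY)` only, which has
consequences for identifiability (below).

For the measurement model every site class splits into labeled/unlabeled
pools; new methyl groups draw on the labeled fraction of a constant
methionine store (`Met_tot`), whose labeled part decays with `k_Met` and is
consumed by methylation; demethylating a labeled site releases one molecule
of [methyl-³H]-methanol. With `k_Met = 0` the labeled pool (methionine +
transducer-bound + cumulative methanol) is closed, which the conservation
tests exploit. Aberrant site numbers (1–3 per transducer) are not modeled.

## Two-component cascade

Mass action with strict conservation: `CheAp` (autophosphorylation gated
multiplicatively by activity), `CheYp` (phosphotransfer from CheAp to free
CheY, first-order hydrolysis), reversible CheY binding to R-TWA complexes
(`TWAY`, tracked dynamically because it drives the feedback), optional CheB
phospho-cycle, optional CheC phosphatase. CheC hydrolysis is saturable
(Michaelis–Menten, `V = k_chec·CheC_tot`, constant `k_m_chec`): a
phosphatase clamp that is near zero-order at the low adapted CheYp level
but saturates during an excitation transient. This is what produces the
severalfold repellent CheYp overshoot in the CheC variant — with strictly
first-order hydrolysis the fold would be capped by the ratio of peak to
adapted activity (≈2).

## Measurement model

The instantaneous labeled-release rate passes a first-order outflow filter
(`T_out`), is integrated over right-open `T_S` windows (partial trailing
windows dropped), and converts to scintillation counts via the specific
activity (75 Ci/mmol ⇒ 4.608·10⁻⁹ decays·molecule⁻¹·s⁻¹) and counting
efficiency 0.5. The chemo-stimulus is delayed by `T_delay` and low-passed
by `T_in`; photostimuli act instantaneously. Exact bookkeeping:
`Σ fractions + T_out·M_out(t_f) = cumulative release(t_f)` at the last
complete fraction edge, verified to <10⁻⁶ relative.

## Numerical choices

States are integrated with LSODA (stiff-capable), rtol 10⁻⁸ / atol 10⁻¹⁰,
with integration restarts at every protocol switch time (piecewise-constant
inputs break smoothness assumptions of adaptive steppers). Pre-equilibration
integrates under constant background until the scaled residual
`max|dy|/max(|y|,1)` falls below 10⁻⁹. Activity is clamped to [0,1] and
pool fractions clipped inside the right-hand side to guard against
tolerance-level excursions. Fraction integrals use trapezoidal quadrature
on the output grid with interpolated window edges; the consistency tests
use a 0.2 s output grid.

## Curated default parameters

The source study's fitted values are not published in the article body, so
the shipped defaults are this package's own working point, found by coarse
numerical search so that the whole scenario ladder holds simultaneously.
Key choices (units: molecules/cell for copy numbers, s⁻¹ for rates, kT for
energies):

* Copy numbers `A_tot = 2000`, `Y_tot = 2000`, `B_tot = 300`; transducers
  `Htr_tot = 7000` (one activating + one inactivating site each).
* Methylation `k_m = 10⁻³`–`2·10⁻³`, `k_dm` per mechanism so that the
  adapted methylated fractions sit mid-range (the adaptation time constant
  is a few hundred seconds, matching the minutes-scale transients of the
  flow assay).
* Free energies: stimulus increments ±2 kT per signaling intermediate
  (±1.2 for the single-complex Model 1); methylation increments ±12 to
  ±16 kT per site, and −30 for Model 1's single site. These are larger than
  per-methyl energies used for enteric-bacteria receptor arrays because
  cooperativity here comes from `N_tot = 3` complexes per unit rather than
  10–20; the product (sites × energy) plays the same role. High methylation
  gain is what makes CheYp adaptation precise (<5 % residual) in a model
  without structural integral feedback.
* Feedback gain `k_dmY = 12` with `K_Y` set at the adapted regulator level,
  so the two Michaelis factors are balanced at rest and swing oppositely
  during transients. The Halobacterium-type release transient is a
  second-order (bilinear) effect `ΔA·Δφ`, so it needs both a sizable
  activity excursion and a sizable regulator swing; the models 5/6 cascade
  (`k_pt = 4.9·10⁻²`, `k_hy = 1`, small high-affinity TWA pool
  `TWA_tot = 1000`, `K_d = 100`… molecules) was chosen to give the CheYp
  pool a large dynamic range.
* Scenario photon fluxes 10¹⁵ photons·cm⁻²·s⁻¹ drive roughly half of the
  receptor pool into the signaling intermediates.

Models 1–4 and 5–6 ship with per-model defaults (`default_params`),
mirroring the source's practice of tuning each conceptual model separately.

## Pattern classification

The flow-assay literature distinguishes release patterns by eye; the
classifier makes this operational: baseline = mean over a 120 s pre-window
(which must be quasi-stationary, CV < ε), response = signed extremal
deviation over the post-window, flat below ε = 0.05 relative. Labels:
*halobacterium* (every transition a transient increase), *ecoli*
(attractant ↓ / repellent ↑, off-transitions mirrored), *ecoli_inverted*,
*flat*, *other*. ε, windows, and the flat/other taxonomy are artifact
choices; the shipped suite's claims are stable for ε ∈ [0.02, 0.10]
(scenarios whose claim is "not Halobacterium-type" keep that claim, though
a near-flat trace may move between *flat* and *other* across the band).
CheYp adaptation is "precise" when the level returns to within 5 % of its
pre-stimulus baseline (an artifact threshold; the observations are
qualitative).

## Synthetic data and parameter recovery

The generator simulates the final model, collects fractions, and applies
Poisson counting noise. Because the assay counts decays from an ensemble of
cells, the Poisson statistics act on `gain × counts` with the noisy series
reported per cell; `gain` folds the effective cell number and counting
conversion into one factor. Gaussian relative noise is available for
digitized traces.

The standard recovery experiment estimates `k_dm` and `k_dmY` by bounded
nonlinear least squares on per-fraction counts. In the wildtype these two
are practically degenerate (the `φ_A+φ_I` sum rule above; compensated
parameter pairs change the clean trace by <2 %), so the experiment uses a
cheY-deletion strain, where the limiting rate forms separate the
combinations — the in-silico analogue of choosing the informative mutant
assay. Conditions: one saturating chemoattractant step and one saturating
blue-light step (1200 s each), 30 s fractions, counting gain 40 (≈2.7·10³
effective counts per fraction), bounds spanning the truth by ×/÷4, start
offset from the truth, and five replicate noise realizations summarized by
the median relative error per parameter. Typical medians are ~1 % for
`k_dm` and ~10 % for `k_dmY`; single realizations occasionally wander to
~30–40 % in `k_dmY` along its flat direction, which is why the experiment
reports a replicate median. The `identifiability_report` (finite-difference
loss sensitivities) flags inert parameters, e.g. `k_chec` with the CheC
variant disabled.

## What the synthetic data do not emulate

Digitization error, scintillation background and dead time, day-to-day
labeling variability beyond the `f_met`/`f_htr` start fractions, cell-to-
cell heterogeneity, and ligand depletion in the chamber. Passing recovery
tests therefore demonstrate estimator correctness under the stated noise
model, not robustness to real-assay systematics.

## Known limitations

* Adaptation is high-gain proportional, not integral: CheYp returns to
  within a few percent of baseline, not exactly; precision degrades for
  stimuli much stronger than the defaults.
* The MWC factorization treats photocycle states as continuous population
  fractions; for saturating stimuli the approximation error is negligible,
  but single-unit stochasticity and ligand depletion are out of scope.
* Qualitative model variants (fbm1, fbm4/fbm5, the CheBp modifier) are
  implemented and unit-tested but ship without a tuned scenario parameter
  set of their own.
* The flagellar motor switch is not modeled; CheYp is the terminal output.
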