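# halotaxis

Deterministic kinetic models of stimulus-induced transducer methylation and
CheY-dependent feedback in *Halobacterium salinarum* photo- and chemotaxis.

## The problem

Halobacteria steer by modulating flagellar motor switching through a
two-component system: methyl-accepting transducers (Htr) complexed with the
sensory rhodopsins SRI (orange light, attractant) and SRII (blue light,
repellent) or with chemoreceptor binding proteins form
receptor–transducer–CheW–CheA (R-TWA) complexes whose active conformation
drives CheA autophosphorylation and phosphotransfer to CheY. Adaptation is
carried by reversible methylation of the transducers, and demethylation is
observable in real time: each removed methyl group leaves the cell as
methanol, which a flow assay collects in timed fractions as
[methyl-³H]-methanol. Wildtype cells release methanol transiently at
*every* stimulus transition (attractant or repellent, on or off — the
*Halobacterium*-type pattern), a *cheY* deletion shows the *E. coli*-type
pattern instead (release drops on attractant, rises on repellent), and a
mutant whose stimulated transducer carries no methylation sites still
adapts and still releases methanol.

This package implements the ladder of ODE models (Models 1–6) that explains
those observations, ending in a quantitative final model whose essential
ingredients are:

* **Cooperative signaling units** — `N_tot` conformationally coupled R-TWA
  complexes of different receptor specificity; the probability of the unit
  being active is a two-state (MWC) Boltzmann weight,
  `A = 1/(1 + exp(Σ_c δ_c))`, with per-complex free-energy balances δ_c set
  by photocycle state, ligand occupancy, and methylation
  (an exact enumeration oracle validates the factorized form);
* **Antagonistic methylation sites** — one site class whose methylation
  favors the active conformation, one the inactive, with constant
  methylation rate `k_m` and conformation-dependent demethylation;
* **CheY feedback on demethylation** — unphosphorylated (complex-bound)
  CheY inhibits demethylation of the activating site and enhances that of
  the inactivating site by Michaelis–Menten kinetics,
  `dm_A = k_dm·A·(1 + k_dmY·K_Y/(K_Y+Y))`,
  `dm_I = k_dm·I·(1 + k_dmY·Y/(K_Y+Y))`;
* **The measurement model** — ³H-label bookkeeping against a decaying
  labeled-methionine pool, ligand inflow lag, methanol outflow lag, and
  fraction sampling, so simulations produce exactly what the assay prints.

The package also ships an in-silico genetics layer (cheY deletion,
methylation-deficient HtrI, inverted-response SRI mutants, CheB
phosphorylation and CheC phosphatase variants), a methanol-release pattern
classifier, a synthetic-data generator with Poisson counting noise, and a
least-squares calibration toolchain.

## Worked example

Simulate the final model (Model 6, wildtype) under an attractant
orange-light step followed by a repellent blue-light step, and classify the
resulting methanol-release pattern:

```
halotaxis classify --config examples/model6_wildtype.toml
```

prints

```json
{
  "pattern": "halobacterium",
  "transitions": [
    {"t": 200.0,  "direction": "attractant_on",  "response": "positive", "amplitude": 0.131},
    {"t": 800.0,  "direction": "attractant_off", "response": "positive", "amplitude": 0.283},
    {"t": 1400.0, "direction": "repellent_on",   "response": "positive", "amplitude": 0.330},
    {"t": 2000.0, "direction": "repellent_off",  "response": "positive", "amplitude": 0.156}
  ],
  "che_yp": {
    "peak_sign": -1,
    "peak_amplitude": 876.3,
    "precision": 0.963,
    "half_time": 12.0,
    "adapted": true
  }
}
```

Reading: every stimulus transition produces a transient *increase* of
methanol release (13–33 % over baseline) — the Halobacterium-type pattern —
while the attractant step transiently *lowers* CheYp by ~876 molecules/cell
(peak_sign −1) and the methylation system returns it to within 4 % of the
pre-stimulus level (precision 0.963, adapted). Rebuilding the same scenario
with `genotype = ["delta_cheY"]` flips the pattern to `"ecoli"`, and with
`genotype = ["htrI_nonmethylatable"]` the cooperative unit still yields the
wildtype behavior — the three experimental observations the model family
was built to explain. `halotaxis ladder` runs all fifteen scenario/genotype
combinations at once.

`halotaxis simulate --config … --out prefix` writes the full trajectory
(activity, CheYp, release rate, state columns) as CSV and the fraction
series as TSV; `halotaxis synth` generates Poisson-noised synthetic
fraction data; `halotaxis fit` calibrates named rate constants against an
observed fraction series.

The library surface mirrors the CLI: `build_model`, `pre_equilibrate`,
`simulate`, `classify_pattern`, `generate_synthetic_fractions`,
`fit_parameters`, … — see `docs/methods.md` for the model definitions,
parameter choices, and numerical methods.

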