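# Methods

## The model

Oral bioavailability is composed from two sequential first-pass survivals,

    F_pred = F_int × F_liver,

with all F-like quantities handled internally as fractions in [0, 1] and
converted to percent only at I/O boundaries.

**Gut stage.** The absorbed fraction is the minimum of a dissolution-limited
and a permeability-limited term: `f_abs = min(f_diss, f_abs_eff)` with
`f_abs_eff = f_abs,p × efflux_penalty` when the compound is an MDR-1 or BCRP
substrate, raised to `max(f_abs_eff, active_uptake_floor)` for quinolones and
beta-lactams (classes with strong active intestinal uptake) — the dissolution
cap still applies after the floor.  Gut-wall extraction is a constant
fraction: `gut_extraction_cyp3a4` for CYP3A4 substrates, `gut_extraction_phenol`
for phenols (conjugating mucosal enzymes); when both fire the larger applies.
`F_int = f_abs × (1 − E_gut)`.  The combining algebra (min rule,
multiplicative penalty, additive floor, constant extraction) is a design
choice: the endpoint inputs of the gut stage are established, their
composition is not, and these forms are the simplest that preserve the
required monotonicities and bounds.

**Liver stage.** The classical well-stirred model:
`fu_b = f_u / (C_bl/C_pl)`, `CL_h = Q·fu_b·CL_int / (Q + fu_b·CL_int)`,
`E_total = min(1, (CL_h + CL_bile)/Q)`, `F_liver = 1 − E_total`.  Biliary
clearance is treated as blood-referenced and additive to metabolic clearance
inside the extraction ratio, clamped so the total extraction never exceeds 1.
Note that `(CL_h + CL_bile)/Q` is the extraction ratio; the fraction escaping
the liver is its complement — implemented that way because F_liver must
*decrease* with clearance.

**Endpoint models.** Nine endpoints feed the two stages.  Learners and latent
dimensions: f_abs,p — SVM; CL_int — SVM; CYP3A4 — SVM classification; f_u —
PLS(7); f_diss — PLS(5); MDR-1 — PLS-DA(4); BCRP — PLS-DA(5); CL_bile —
PLS(6); C_bl/C_pl — PLS(8).  Bounded endpoints (f_abs,p, f_u, f_diss) are
modelled on the logit scale with ε = 0.005 clipping; positive endpoints
(CL_int, CL_bile, C_bl/C_pl) on the log10 scale with a 10⁻³ floor — the
inverse transforms guarantee each endpoint's range invariant, and residual
out-of-range values are clipped with a warning.  C_bl/C_pl gets log10 because
its only hard invariant is positivity.

**SVM training.** RBF kernel, exhaustive (gamma, cost) grid search under
seeded k-fold cross-validation (10 folds by default).  Classification selects
by pooled CV accuracy; regression by pooled CV Q² — the natural score for
each task.  Default grid: powers of two, 2⁻¹⁰…2¹⁰ in steps of 2² (11 × 11
points); ε-SVR uses ε = 0.1.  Ties go to the first grid point in iteration
order, making selection deterministic.  Fold assignment is a seeded shuffled
split, stratified by class for classification and by response quartile
(rank-based) for regression.

**PLS-DA decision.** The 0/1-coded response is thresholded at 0.5; an exact
tie counts as non-substrate, the conservative direction since substrate flags
only ever penalise absorption or add extraction.

**Descriptors.** Signature descriptors: for every heavy atom and height
h = 0…H (H = 3 maximum, 2 by default in run configs), the atom's depth-h
neighborhood is unfolded into a tree (never stepping back over the traversed
bond) and serialized with branches sorted lexicographically; atom labels are
element symbol, aromaticity and formal charge, bond labels the four bond
orders.  Sorted serialization makes the string canonical by construction —
invariant under atom renumbering — and prefix-consistent across heights, so
the number of distinct signatures can only grow with h.  Feature matrices are
count matrices over the training vocabulary with unit-variance column scaling
(zero-variance columns untouched); signatures unseen at training time
contribute nothing at prediction time, and a descriptor with no known
signature falls back to the model's baseline (zero-count) prediction.

**Prediction path and persistence.** scikit-learn performs the fits, but
prediction is computed from extracted parameter arrays (support vectors/dual
coefficients/intercept for SVM; the linear coefficient vector for PLS) both
at training time and after reload, so a persisted JSON bundle reproduces
predictions bit-identically; JSON float round-tripping is exact.

## Structural alerts and applicability domain

Alerts are SMARTS patterns in an editable file (one named pattern per line):
phenol = hydroxyl on an aromatic carbon; beta-lactam = 4-membered cyclic
amide; quinolone = 4-oxo-1,4-dihydroquinoline-3-carboxylate core, written to
match both the quinoline and naphthyridine variants and both aromatic and
kekulized ring perception.  The exact quinolone scaffold breadth is a
documented default, editable in the pattern file.

Domain rules: *metal* = any element outside {H, B, C, N, O, F, Si, P, S, Cl,
Se, Br, I}, evaluated on the full input including stripped salt fragments;
*quaternary amine* = positively charged nitrogen with four non-hydrogen
single-bonded substituents; MW bounds inclusive at 100 and 700 Da.
Hydrolysis sensitivity and blood-flow modulation have no reliable structural
rule, so they are caller-supplied flags.  Metals, quaternary amines and parse
failures yield no estimate at all; every other out-of-domain compound still
gets a flagged estimate.  The descriptor-range check (log P −6.4…7.6, ≤19
H-bond donors/acceptors, via RDKit Crippen/Lipinski) is advisory by default
("warn"), because those ranges describe the training domain rather than a
hard validity boundary.  Multi-fragment inputs keep the largest fragment and
record a warning — salts are routine in compound tables.

## Evaluation metrics

Q² = 1 − Σ(pred−obs)² / Σ(obs−mean(obs))², with the denominator anchored to
the evaluation set's own observed mean (configurable; no training-set
reference mean exists here).  Both a linear-scale and a logit-scale variant
are provided, with values clipped into [ε, 1−ε], ε = 0.001, before the logit.
R² is the squared Pearson correlation.  Fold error = max(p,o)/min(p,o);
exact zeros are replaced by ε = 0.001 so the ratio stays finite, while small
non-zero values count at face value (observed absorbed fractions down to
2·10⁻⁴ occur in real data and must not be floored away).  The
intercept diagnostic is an ordinary least-squares fit of *predicted on
observed*, reported in percentage points.  The head-to-head comparison
computes, per species, the animal-vs-human R² and the in-silico Q² on the
id-matched compound subset.  Go/no-go concordance is a 2×2 table at a 20 %
bioavailability threshold; the incorrect-stop fraction (predicted < 20 %,
observed ≥ 20 %) is the costlier error in candidate selection.

## Synthetic data

The generators stand in for proprietary training and benchmark data, so what
the tests demonstrate is the machinery — training, selection, integration,
evaluation — not chemical accuracy on real endpoints.

*Endpoint sets*: the latent signal is a sparse linear function (6 active
features) of signature counts, standardized over the bundled 236-drug panel,
plus Gaussian noise (default SD 0.05 in latent-SD units), squashed into each
endpoint's natural range (logistic for fractions, 10^(offset+width·z) for
clearances and the blood/plasma ratio).  Active features are restricted to
signatures present in ≥10 % of the panel: QSAR signal concentrated on
recurrent substructures is the realistic case, and it keeps the mapping
within the 4–8 latent-component budget of the PLS endpoints, so parameter
recovery is well-posed.  Classification endpoints drop samples within 0.5
latent-SD of the boundary, which is what "separable classes" means here.
The true mapping is stored for recovery tests.  Compounds are sampled from
the panel with replacement, so large n implies repeated structures — fine
for recovery tests, unlike real chemistry.

*Benchmarks*: observed F is a three-region scaled-Beta mixture whose region
weights are exactly the target tail probabilities P(F>0.90) = 0.28 and
P(F>0.65) = 0.50 (configurable; infeasible combinations are rejected).
Prediction series with a target Q², and animal series with a target
interspecies R², are produced by deterministic bisection on a noise scale
applied to fixed seeded normals with clipping into [ε, 1−ε]; the bisection
hits the target essentially exactly, so calibration claims are by
construction, not by luck.

The drug panel (`data/drug_panel.smi`) contains public, well-known drug
structures (a few entries are close analogs, marked `_like`/`_frag` in the
id); a separate hand-labelled fixture panel of 30 molecules carries ground
truth for all alert and domain rules.

## Numerical choices and degenerate inputs

Constant responses and single-class labels raise training errors rather than
fitting silently.  PLS component counts are validated against
n − ⌈n/folds⌉ and the feature count.  Zero-variance feature columns scale by
1.  The extraction-ratio clamp (E_total ≤ 1) is the only non-smooth point of
the liver model; F_liver = 0 beyond it.  All randomness flows from explicit
integer seeds; grid iteration, vocabulary order (sorted) and JSON
serialization (sorted keys) are deterministic, which is what makes
byte-identical reruns possible.

## Problem sizes

Default verification sizes: 10⁴-point closed-form grid, 10³ random profiles,
100 random series for metric oracles, n = 500 / 5 % noise for PLS recovery,
n = 200 for SVM grid-search checks, n = 10⁵ for benchmark tail calibration.

## Known limitations

Gut-wall extraction is a constant per alert class rather than a
CL_int-dependent mechanism; no enterohepatic recirculation, transporter
kinetics, dynamic (ODE) PBPK, tautomer handling or 3D conformers.  Log P /
log D are used only as advisory range checks via RDKit's estimators, not
predicted.  The synthetic generators do not emulate real structure–endpoint
relationships, activity cliffs, assay noise structure, or inter-lab
variability; passing recovery tests shows the pipeline recovers what it is
told exists, not that real endpoints are predictable to the same accuracy.
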