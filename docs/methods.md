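# Methods

## Data

The packaged table holds the 41-compound anthranilamide FXR-agonist series:
micromolar EC50 values, their pEC50 = 6 − log10(EC50/µM) conversion, a
fixed 31/10 train/test split, and the two published per-compound prediction
columns (linear model and field model).  Structures are encoded as SMILES
from the series' R-group descriptions on a 2-(arylsulfanyl)-N-aryl/alkyl-
benzamide scaffold; the R-group table is the only machine-readable source
of structure, so these encodings are the package author's, and descriptor
values computed from them are engine-specific (see *Limitations*).  A second
small table carries the nine designed analogues and the template compound
with their published predictions.

Statistics that depend only on the experimental and prediction columns
(train/test R² and RMSE for both models, the F statistic, the warning
leverage, residual standardization) are exactly reproducible and serve as
the package's reference checks.  Statistics that depend on a descriptor or
field engine (coefficients, Q², field contributions, designed-compound
scores) are engine-specific; the pipeline reports printed-columns mode and
refit mode side by side to keep that separation explicit.

## Conventions that matter

* **RMSE** is the population form sqrt(SSE/n) throughout.  This convention,
  not sqrt(SSE/(n−p−1)), reproduces the published training (0.219) and test
  (0.534) errors from the shipped columns.
* **R² between observed and predicted** (including R²_test) is the squared
  Pearson correlation; this reproduces the published 0.902 / 0.892 exactly.
* **Q²_LOO = 1 − PRESS/SST** with SST about the full-sample training mean;
  leave-one-out predictions use the hat-matrix identity e_i/(1−h_i), which
  is algebraically exact for OLS (verified against explicit refits to 1e−8).
* **F statistic** from R²: (R²/p)/((1−R²)/(n−p−1)); critical values by
  inverse incomplete-beta via `scipy.stats.f.isf`.
* **Leverage** h = x'(X'X)⁻¹x with the intercept included; test compounds
  are scored against the training (X'X)⁻¹.  Warning leverage h* = 3(m+1)/n.
  Standardized residuals divide by the training RMSE for train and test
  alike.  X outliers: h > h*; Y outliers: |standardized residual| > 3.

## Descriptor engine

* Conformers: 10 ETKDG distance-geometry embeddings per molecule, each
  MMFF94-minimized, lowest energy kept; deterministic per (structure, seed).
  Gasteiger charges (switchable), Bondi radii (1.20 Å for H).
* b_rotN counts non-ring single bonds whose end atoms each bind ≥ 2 heavy
  atoms; amide bonds are *not* excluded.  The series' published flexibility
  orderings (compound 16 > 15; 38 > 36 > 35) hold under this rule; absolute
  counts differ from the original engine's by a constant.
* RPC⁻ = (most negative atomic charge)/(sum of negative charges); 0 when no
  atom is negative.
* opr_leadlike evaluates MW ≤ 450, −3.5 ≤ logP ≤ 4.5, rings ≤ 4, rotors
  ≤ 10, donors ≤ 5, acceptors ≤ 8 (a published lead-likeness criteria set,
  fixed in one place so it can be swapped); returns 1 iff violations < 2.
* SlogP_VSA2 sums per-atom Labute VSA over atoms with Crippen logP
  contribution in the half-open bin (−0.2, 0] (the standard subdivision;
  equal to the RDKit binned descriptor for that range, which the tests use
  as an independent oracle).
* ASA: Shrake–Rupley quadrature with a deterministic 960-point Fibonacci
  sphere per atom and a 1.4 Å water probe; ~1% quadrature error against the
  single-sphere closed form.  Exactly coincident duplicate atoms are counted
  once so the complete-overlap limit is well defined.

## Stepwise selection

Classical forward/backward stepwise OLS on partial-F p-values (the squared-t
identity), defaults α_enter = 0.05, α_remove = 0.10, ties broken by column
order, empty selection returns the intercept-only model.  Two statistical
facts shape the recovery tests: (i) with k inactive candidate columns the
family-wise false-entry probability is ≈ 1−(1−α_enter)^k per sweep, so
exact-support assertions use a stricter α_enter (0.005–0.01) than the
modelling default; (ii) sequential entry tests lose power when several
comparable effects remain unexplained, so support recovery is only a sharp
property when each active descriptor carries a comparable, individually
detectable share of signal — the regime the synthetic generator (below) is
calibrated to.

## Y-randomization

k seeded permutations of the response, OLS refit on the already-selected
columns (a flag enables full re-selection per shuffle), recording recall R²
and Q²_LOO.  Under the null, E[R²] = p/(n−1) ≈ 0.167 at n = 31, p = 5; the
tests assert the k = 500 mean within ±0.05 and the collapse of shuffled
R²/Q² at k = 10 relative to the true-response fit.

## Field model

* Lattice: axis-aligned, 2.0 Å spacing (config), extending ≥ 4 Å beyond
  every atom of every aligned conformer.
* Steric field: Lennard-Jones 6-12 against an sp³-carbon probe (R 1.52 Å,
  ε 0.107 kcal/mol), r_min,ij = R_i + R_probe, ε_ij = sqrt(ε_i ε_probe)
  with per-element well depths from a standard small-molecule force-field
  table; truncated at +30 kcal/mol (a grid point inside an atom reports the
  cutoff).
* Electrostatic field: 332.0636·q_i·q_probe/(ε(r)·r) with the
  distance-dependent dielectric ε(r) = r, truncated to ±30 kcal/mol; grid
  points buried in a molecule's vdW envelope take the across-molecule
  column mean of unburied values (two-pass fill).
* Column filter: across-molecule population SD ≥ σ_min = 6 kcal/mol, i.e.
  the "minimum sigma" reading of the published filtering value; an energy
  range variant is selectable.
* PLS: NIPALS PLS1 on mean-centred data; CoMFA-standard block scaling
  (each field block weighted by the inverse of its overall SD) by default,
  `none`/`auto` selectable.  Coefficients are returned in original units;
  at full rank the fit equals OLS (tested to 1e−6).  Field contributions
  are the normalized Σ|coefficient·column SD| mass per block.  Components
  are chosen by the highest leave-one-out Q² over 1..10 with ties to the
  smaller count; column filtering is fixed before the LOO loop.
* Contours: STDEV×COEFF per lattice point; the favored threshold is the
  80th percentile of a field's positive values, the disfavored the 20th
  percentile of its negative values; grids export as OpenDX text.

Applied to the packaged series with this package's own alignment (maximum
common substructure onto the most active compound, Kabsch superposition)
the field model reaches R²_train ≈ 0.74 and Q²_LOO ≈ 0.23 — well below the
original values, as expected when alignment, charges and force-field
parameters all differ; the packaged prediction column, not a refit, is the
reference for the published field-model statistics.

## Synthetic generators

The linear generator draws descriptor columns from configurable
distributions and forms y = intercept + Xβ + N(0, σ).  Defaults emulate the
study regime: n = 31, the five published coefficients, descriptor scales
ASA ~ N(400, 20), RPC⁻ ~ N(0.2, 0.025), SlogP_VSA2 ~ N(20, 4),
b_rotN ~ N(8, 1), opr_leadlike ~ Bernoulli(0.5), and σ = 0.185, set so that
(i) realized signal R² ≈ 0.92–0.93 and (ii) each descriptor contributes a
comparable, individually detectable share of signal variance.  Point (ii)
is a deliberate idealization: in the real series one descriptor dominates
the signal and the weakest published coefficient is within ~1.2 standard
errors of zero, a regime in which no selection procedure can recover the
full support reliably — the generator tests the machinery, not that
particular data pathology.

The field generator builds point-atom "molecules" sharing a rigid scaffold
with one sampled option (vdW radius = bulk, partial charge) per variable
site, and y = steric·(total bulk, centred) + electrostatic·(total charge)
+ N(0, 0.1), with 24 molecules by default.  Because all molecules share
scaffold coordinates they are aligned by construction.  What passing tests
show: the field/PLS chain detects where and with which sign localized bulk
and charge drive activity.  What they do not show: robustness to alignment
error, conformational flexibility, or correlated substituent effects —
none of which the generator emulates.

## Numerical choices and degenerate inputs

Rank-deficient designs raise with the dependent columns named; constant
columns are rejected by the collinearity report; a leverage of 1 on any
training row aborts LOO with that row named; an all-filtered field block
advises lowering σ_min; zero-variance response is rejected by PLS and
Y-randomization; NIPALS truncates cleanly when the residual is exhausted.
All randomness flows from explicit integer seeds; generators are
bit-reproducible per seed.

## Limitations

* Descriptor values are not interchangeable with other engines' (different
  charge models, radii, surface quadrature); only printed-column statistics
  and published orderings are reproduced numerically.
* The published field-model statistics depend on the original alignment and
  are out of numeric reach by design; field machinery is validated on
  closed forms, oracles and synthetic ground truth instead.
* Stepwise inference p-values are nominal, not selection-adjusted.
* Docking and any receptor-structure computation are out of scope.
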