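# Methods

## Scope and data model

`bigsol` analyses intrinsic aqueous solubility (log S₀, log₁₀ molar, 25 °C)
of drug-like compounds, with the small/big demarcation at MW = 800 Da.
A compound record carries melting point (°C), clogP, molecular weight, H-bond
acceptor/donor counts, rotatable-bond count (nROT), the five Abraham solute
descriptors (A, B, Sπ, E, V), an ionization class (acid / base / neutral /
ampholyte), and optionally an enthalpy of solution. Each solubility entry is
a per-compound averaged log S₀ with an estimated measurement SD. All
packaged statistics are per-compound (n = 31 for the big reference set);
entries lacking an SD default to 0.5 log — a typical interlaboratory
reproducibility for solubility data — configurable at load time.

The ionization labels of the packaged big-molecule table are package
annotations assigned from the standard acid–base behaviour of the drugs (the
two iodinated contrast-agent diacids are the only acids). They feed only the
indicator variables of the enthalpy model.

## Weighting and fitting

Measurement heteroscedasticity is handled by inverse-variance weighting,
w_i = 1 / max(sd_i, 0.05)². The 0.05-log floor stops a single ultra-precise
entry from dominating a fit. Weighted MLR goes through statsmodels WLS and
reports coefficient standard errors.

PLS (used where descriptors are strongly collinear, i.e. the basicity
exponent scan) is a PLS1 NIPALS implemented in-package without internal
centering: the data are weighted-centered and row-scaled by √w first, which
makes full-component PLS on a full-rank design *exactly* equal to weighted
MLR (asserted to 1e-8 in the tests). Off-the-shelf PLS implementations
center unweighted and accept no sample weights, which breaks that identity.
The component count is chosen by 10-fold cross-validated weighted RMSE with
a fixed shuffle seed; exact ties break toward fewer components.

Metrics follow the field's conventions: RMSE; r² = max(0, 1 − SSres/SStot)
(floored — a model predicting worse than the observation mean reports 0);
bias = mean(obs − calc); SD of the observations (population form);
F = ((n − p − 1)/p)·SStot/SSres with p supplied by the caller; and MPP, the
percentage of absolute residuals ≤ 0.5 log. MPP is reported to integer
percent and the other metrics to two decimals in serialized reports, full
precision internally.

## GSE

Classic coefficients (0.5, −0.01, −1) are a frozen preset; the melting-point
term documents its origin in Walden's rule (ΔS_m = 0.0565 kJ/mol·K,
2.3RT = 5.706 kJ/mol at 25 °C). The big-molecule preset `gse-big-2020` is
(−1.77, −0.01, −0.4); its mp coefficient is carried at the classic −0.01
(the refit values are only known to be close to it). Predictions for mp
below 25 °C are computed as-is with a logged warning, since the solid-phase
premise weakens there. `fit_gse` is a three-parameter weighted MLR on
(1, mp − 25, clogP); `gse_crossover` solves two GSE lines for equal
prediction at fixed mp and raises on parallel lines. No preset is shipped
for the small-set refit: its constants are not reliably available, and the
generic fitter covers that use.

## ABSOLV

`predict_absolv` evaluates c₀ + c_A·A + c_B·B + c_S·Sπ + c_E·E + c_V·V +
c_AB·A·B (+ c_Bz·B^z when configured). B^z is defined as 0 at B = 0 for all
z > 0 (the limit is 0; this avoids 0⁰ ambiguity).

The `absolv-2020` preset was **reconstructed, not transcribed**: the
published small-molecule-trained coefficient vector is recovered by
over-determined least squares of the 31 reference ABSOLV predictions on the
31 descriptor rows (7 unknowns, 31 equations). The reconstruction reproduces
every reference prediction to < 0.005 log, well inside the 0.05 cross-check
tolerance, and shows the expected near-zero A·B coefficient. Users with the
published equation can supply their own `AbsolvCoefficients`.

The exponent scan refits (A, B, Sπ, E, V, A·B, B^z) by weighted PLS for each
z on a 0.90–2.00 grid (step 0.01) and returns the z minimizing the fit RMSE,
ties toward smaller z. Whether to weight the scan is switchable
(`weighted=False`); weighting is the default, consistent with the rest of
the pipeline. On noiseless synthetic data the scan recovers the generating
exponent exactly on its grid point; at noise 0.3 and n = 2000 it recovers
z = 1.3 within 0.05.

The rotatable-bond correction is an **unweighted** OLS of the residual
(obs − ABSOLV) on nROT over big compounds — no weighting is defensible for a
purely empirical residual trend — applied additively as
prediction + intercept + slope·nROT. On the packaged big set this is
0.75 + 0.13·nROT (r² = 0.44), cutting RMSE from 3.3 to 1.6 and the bias from
2.5 to ~0. The SEBM–nROT trend shares this implementation (log SEBM *is*
that residual).

## Random forest

500 trees, a third of the features tried per split, unlimited depth — the
classic defaults, which are near-optimal for solubility QSPR without tuning;
all exposed as arguments. The 70/30 split is seeded and made at the compound
level (one row per compound), avoiding leakage between duplicate
measurements of one compound. Importances are mean decrease in impurity,
normalized to sum 1, reported descending. All-zero descriptor columns are
dropped before fitting and logged. When no structural descriptors are
available (no SMILES, no precomputed CSV), the model falls back to the
reduced mp + Abraham feature set with a warning — usable, but expect weaker
validation performance than a full 2D-descriptor table.

## Temperature normalization and enthalpy of solution

Van't Hoff normalization:
log S₀(T_ref) = log S₀(T) − (ΔH_sol·1000 / (2.303·R))·(1/T_ref − 1/T), with
ΔH_sol in kJ/mol, R = 8.314 J/(mol·K). The ln-10 factor is carried as 2.303
to match the printed arithmetic of the source equations; the difference from
ln 10 is < 0.001 log in every packaged case. The round trip is exact. A
positive (endothermic) ΔH_sol means solubility falls on cooling; most big
molecules are exothermic dissolvers and become *less* soluble with rising
temperature — consistent with 'molecular chameleon' conformational
behaviour.

ΔH_sol prediction from descriptors is linear in (A, B, Sπ, E, V) plus
ionization indicators (I_B, I_N, I_Z; acid is the all-zero reference). The
packaged `dh-sol-big31-synthetic` preset is a stand-in fitted to the 31
fixture enthalpies (RMSE ≈ 2.3 kJ/mol, max error ≈ 6.4 kJ/mol on those
compounds); the published prediction equation should be transcribed for
production use, and calling the predictor without any preset raises a
configuration error saying so.

## SEBM

SEBM = 10^(obs − ABSOLV), kept at full precision internally and printed as
an integer (round half away from zero; ratios below 1 print as the
placeholder 1, matching the reference-table convention). The GSE-based
zoning labels a compound 'enhancement' when the observation exceeds the
classic-GSE prediction and 'attenuation' otherwise; exact ties are labelled
attenuation (the conservative flag for formulation risk) with a logged note.

## Synthetic data

The training database behind the small-molecule models is not
redistributable, so a generator emulates its statistical structure:

* **Small set** (MW truncated-normal 280 ± 80 on [120, 799] Da): clogP
  normal 1.89 ± 1.8; mp truncated-normal on [40, 350] °C with mean 198 ± 55,
  chosen so the GSE generating law with the clogP marginal lands near the
  −3.12 mean log S₀ of the emulated training data; measurement SDs uniform
  on (0.05, 0.7).
* **Big set** (MW 1034 ± 250 on [800, 2000] Da): clogP 3.17 ± 3.0, nROT
  uniform on [3, 53], generating law log S₀ = −1.77 − 0.01(mp−25) − 0.4·clogP.
* Abraham descriptors ride a shared latent size factor (half their variance
  from standardized MW), so bigger molecules carry more H-bond acceptor
  strength — reproducing the small/big NHA and B separation. A/B/V are
  floored at small positive values.
* **Nonlinear-basicity set**: the descriptor law plus c_Bz·B^z_true
  (default c_Bz = 1), with the B marginal widened to 3 ± 2 so the draw spans
  the small-to-big basicity range over which the exponent is identifiable.

Noise is heteroscedastic and *coherent with the declared SDs*: each entry's
noise SD is its simulated measurement SD rescaled so the average noise level
equals `noise_sd` (default 0.5 log, matching the ~0.5-log reliability the
MPP threshold presumes). This makes the declared SDs correct inverse-variance
weights up to scale, so weighted-fit standard errors are consistent and 95 %
CIs achieve nominal coverage in the recovery tests; with `noise_sd = 0` the
generating identity is exact. One named random stream per draw category
(mw, mp, clogp, descriptors, counts, noise, sds) keeps earlier draws
invariant when later fields change; a fixed seed yields byte-identical
tables.

What the generator does **not** emulate: real chemical structures (no
SMILES), the true joint descriptor distribution of any real database (only
published marginal means/ranges), multiple entries per compound, or
non-Gaussian error tails. Passing recovery tests therefore demonstrates
correctness of the estimators under the assumed error model, not predictive
performance on real compounds.

## Problem sizes and determinism

The test suite and reproduction script use n = 500 big compounds for
coefficient-recovery and CI-coverage checks (100 replicate seeds), n = 2000
for the exponent scan and forest training, and n = 300 noiseless rows for
the exact-grid scan check — sizes at which every stochastic check is stable
at its documented tolerance. All stochastic stages take explicit seeds;
pipeline outputs contain no timestamps, so identical configurations
reproduce byte-identical files.

## Known limitations

* The `absolv-2020` reconstruction is exact only over the descriptor span of
  the 31 reference compounds; extrapolation beyond it inherits inversion
  error.
* The enthalpy preset is fixture-derived (see above) — adequate for
  demonstrating the temperature machinery, not a validated predictor.
* clogP is taken as given; no reconciliation between lipophilicity scales,
  though for flexible bRo5 compounds conventional octanol log P itself may
  be the wrong scale.
* Melting points are required inputs; compounds without mp fail loudly
  rather than being imputed.
* The big-molecule reference set is small (31 compounds) and
  natural-product-heavy; statistics derived from it carry the corresponding
  sampling uncertainty.
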