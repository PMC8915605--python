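# bigsol

Intrinsic aqueous solubility models across the Rule-of-5 boundary.

Equilibrium aqueous solubility of the neutral form of a drug — the intrinsic
solubility S₀, reported as log₁₀ molar — is a gatekeeper property in drug
discovery. The standard predictive models are trained on small molecules
(MW ≲ 500 Da), but an increasing share of new drugs are 'big' molecules from
beyond-Rule-of-5 chemical space (here MW ≥ 800 Da): macrocycles, peptides,
natural products. `bigsol` is a toolkit for asking, quantitatively, how far
small-molecule solubility models carry into that space, and for applying the
corrections that make them work better. It is aimed at physical/computational
chemists working on solubility QSPR and at formulation scientists triaging
bRo5 candidates.

## Models

**General Solubility Equation (GSE).** The classic two-parameter model

    log S₀ = 0.5 − 0.01 (mp − 25) − log P

with mp in °C and the octanol–water partition coefficient log P. On big
molecules its weighted refit flattens dramatically: the `gse-big-2020`
preset is log S₀ = −1.77 − 0.01 (mp − 25) − 0.4 clogP. The two lines cross
at clogP ≈ 3.78; the classic GSE overpredicts big-molecule solubility on the
hydrophilic side of the crossover and underpredicts on the lipophilic side.

**Abraham solvation model (ABSOLV).** The linear free-energy relationship

    log S₀ = c₀ + c_A·A + c_B·B + c_S·Sπ + c_E·E + c_V·V + c_AB·A·B

over the five Abraham solute descriptors, fitted by measurement-SD-weighted
regression. Extensions for big molecules: a nonlinear basicity term
c_Bz·B^z with the exponent chosen by a PLS RMSE scan over z ∈ [0.9, 2.0],
and an additive rotatable-bond correction 0.75 + 0.13·nROT that removes the
systematic underprediction of flexible big molecules.

**Random-forest QSPR**, combining mp and the Abraham descriptors with an
optional 2D (RDKit) descriptor block, with seeded 70/30 train/validation
splits and impurity-based feature importances.

**SEBM** (Solubility Enhancement–Big Molecules), the index
SEBM = S₀_obs / S₀_ABSOLV quantifying how much more soluble a big molecule
is than small-molecule training predicts, and **van't Hoff temperature
normalization** of log S₀ using predicted enthalpies of solution.

A 31-compound big-molecule reference table (properties, observed log S₀ and
model predictions) is packaged as a fixture, and a synthetic-data module
generates small/big/nonlinear-basicity datasets with the statistical
structure the analysis assumes, so every stage is testable without any
external database.

## Worked example

```python
import numpy as np
import bigsol as b

pairs = b.load_big31()                      # the packaged 31-compound big set
rec, ent = next((r, e) for r, e in pairs if r.id == "cyclosporine-a")
print(b.predict_gse(rec.mp, rec.clogp))     # classic GSE
print(b.predict_absolv(rec.abraham))        # small-molecule-trained ABSOLV

obs = np.array([e.log_s0 for _, e in pairs])
recs = [r for r, _ in pairs]
gse = np.array([b.predict_gse(r.mp, r.clogp) for r in recs])
print(b.evaluate(obs, gse).to_dict())

absolv = np.array([b.predict_absolv(r.abraham) for r in recs])
corr, _, line = b.fit_nrot_correction(recs, obs, absolv)
after = b.evaluate(obs, b.apply_nrot_correction(corr, recs, absolv))
```

Output (abridged):

```
cyclosporine A: obs -5.03, GSE -4.03, ABSOLV -7.12, SEBM 123
classic GSE on the big set: r2 = 0.0, RMSE = 2.96, MPP = 13%
residual vs nROT: 0.75 + 0.13 nROT (r2 = 0.44)
ABSOLV RMSE 3.3 -> 1.6, bias 2.5 -> -0.00
crossover clogP = 3.78
```

Reading: cyclosporine A is about 123× more soluble than the small-trained
Abraham model predicts (SEBM = 123). Over all 31 big molecules the classic
GSE has no predictive power (r² floored at 0, RMSE ≈ 3 log units, only 13 %
of predictions within 0.5 log). The ABSOLV error grows by ~0.13 log per
rotatable bond; adding the fitted nROT line halves the RMSE and removes the
2.5-log bias — molecular flexibility is what the small-molecule training
misses.

The same pipeline is available from the shell:

```
bigsol report --outdir run           # predictions, SEBM, metrics, manifest
bigsol simulate --set small --n 2000 --seed 1 --out syn.csv
bigsol fit --model gse --input syn.csv
bigsol normalize-temp --log-s0 -4.03 --dh-sol 29 --tmeas 310.15
```

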