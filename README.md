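# voripk

Population pharmacokinetics + machine learning for steady-state
**voriconazole trough concentrations in children under 2 years**.

Voriconazole is a first-line antifungal in immunocompromised children,
but it is only licensed from age 2, and infants clear it with enormous
between-patient variability. Clinicians dose off-label (4–10 mg/kg every
12 h orally) and correct with therapeutic drug monitoring (TDM) — which
means the first days of therapy are dosed nearly blind. `voripk`
implements an integrated workflow that predicts a child's steady-state
trough before the first TDM result is back:

1. a **one-compartment allometric mixed-effects model** for trough-only
   TDM data (CL/F = 17.9·(WT/70)^0.75 L/h, V/F = 788·(WT/70) L, Ka fixed
   1.19 h⁻¹, exponential inter-individual variability on CL with
   ω² = 0.674), estimated by FOCE-I conditional modes refined with
   adaptive Gauss–Hermite quadrature, with stepwise covariate search,
   bootstrap, VPC and η-shrinkage;
2. **empirical-Bayes individual CL and V** that become features, next to
   demographics, labs and co-medications, of
3. a **Boruta-selected** (200 iterations, Bonferroni p<0.01 against
   shadow features) comparison of six tree-ensemble regressors (XGBoost,
   LightGBM, GBDT, CatBoost, AdaBoost, RF) scored by MSE/RMSE/MAE/R² and
   RA20 (±20% relative accuracy), with
4. **Shapley attributions** (exact path-dependent tree SHAP, implemented
   here and verified against coalition enumeration) explaining each
   prediction.

Because no patient-level data are public, the package ships a
**synthetic cohort generator** that emulates the study population (76
infants, ~110 trough samples, median weight 8.05 kg at 11 months,
Table-style laboratory marginals, TDM-informed dose titration, BQL
censoring at 0.25 mg/L) so the entire pipeline is testable end-to-end.
See `docs/methods.md` for the model, the estimation choices and the
generator's known limitations.

## Worked example

```python
import voripk as vp

# 1. a synthetic study: 76 infants, ~110 steady-state troughs
df = vp.simulate_study(vp.CohortSpec(n_subjects=76, seed=5))

# 2. population fit and empirical-Bayes individual parameters
fit = vp.fit_population(df)
print(fit.params_hat.theta_cl, fit.params_hat.theta_v)

# 3. features -> split -> six learners
feats = vp.build_feature_matrix(df, fit.ebes)
train, val = vp.split_data(feats, seed=5)
cmp = vp.compare_models(train, val, seed=5)
m = cmp.val_metrics[cmp.selected_best]
print(cmp.selected_best, round(m.r2, 2), round(m.rmse, 2))

# 4. explain the chosen model
best = cmp.models[cmp.selected_best if cmp.selected_best != "AdaBoost" else "XGBoost"]
attr = vp.shap_values(best, train[best.feature_names_])
print(vp.rank_features(attr)[:3])
```

On the seed shown this prints (clearance in L/h/70kg, volume in L/70kg):

```
23.09 2000.0
RF 0.7 0.55
[('CL', 0.569), ('TDOSE', 0.079), ('SCR', 0.042)]
```

The single-cohort clearance estimate sits above the simulation truth of
17.9 and the volume lands on its physiological search bound —
trough-only sampling leaves (CL, V) on a flat likelihood ridge, so
individual refits scatter widely while the median across replicate
cohorts stays near truth (quantified by the acceptance checks; the V/F
dispersion mirrors the 94.8–1050.85 L/70kg bootstrap interval of the
original analysis). The best learner's validation R² near 0.7-0.8 and
the dominance of the empirical-Bayes clearance feature in the Shapley
ranking reproduce the qualitative findings on synthetic data.

A typical 11 kg toddler illustrates the allometric model directly:

```python
vp.typical_params(vp.PopPKParams(), 11.0)   # -> (4.47 L/h, 123.83 L)
```

A thin CLI mirrors the stages: `voripk simulate | preprocess | fit |
select | train | explain` (see `voripk --help`).

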