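# Methods

`voripk` implements an integrated population-pharmacokinetic (PopPK) +
machine-learning workflow for steady-state voriconazole trough
concentrations in children under 2 years, exercised end-to-end on a
synthetic cohort generator so that no patient data are required.

## Structural PK model

Disposition is a one-compartment model with first-order oral absorption
and first-order elimination, parameterized as apparent clearance CL/F
(L/h) and apparent volume V/F (L); F is unidentifiable from oral-only
data and is fixed at 1 (all parameters are "apparent"). The absorption
rate constant Ka is fixed at 1.19 h⁻¹ — trough-only sampling carries no
absorption information. Body weight enters through fixed-exponent
allometry referenced to 70 kg:

    CL/F = θ_CL · (WT/70)^0.75        θ_CL = 17.9 L/h/70kg
    V/F  = θ_V  · (WT/70)^1           θ_V  = 788  L/70kg

The steady-state trough at interval τ is the closed geometric-series form
of the multi-dose superposition,

    C(τ) = (D·ka) / (V·(ka−ke)) · [ e^(−ke τ)/(1−e^(−ke τ)) − e^(−ka τ)/(1−e^(−ka τ)) ],

with ke = CL/V. The ka → ke degeneracy (flip-flop) is handled by the
analytic limit (D·ka·τ/V)·e^(−km τ)/(1−e^(−km τ))², km = (ka+ke)/2,
switched on when |ka−ke|/ke < 10⁻⁶; the surface is continuous across the
switch to better than 10⁻⁵ relative. Steady state is assumed attained
(inclusion requires ≥3 days of dosing); no dose-history accumulation is
modeled.

Inter-individual variability (IIV) is exponential on CL only,
CL_i = CL·exp(η_i), η_i ~ N(0, ω²) with ω² = 0.674 in the final model
(SD ≈ 0.821). No IIV is carried on V (trough-only data shrink it beyond
usefulness). Residual error is proportional (CV 25% default), additive,
or combined, selectable by configuration.

## Estimation: FOCE-I and its quadrature refinement

The FOCE-I objective is implemented in full. Per subject, the
conditional mode η̂ of the penalized individual objective (including the
log-residual-variance "interaction" term) is located by an iterated
grid-refinement search on [−5ω, 5ω] — eight rounds of a 17-point grid,
final bracket ~10⁻⁷ω; with a single random effect this is robust to
non-quadratic objectives and vectorizes across all subjects. The model
is linearized at η̂ with the residual variance evaluated at the
individual prediction, and the per-subject −2 log-likelihood
contribution is assembled with the rank-one matrix identities (the
random effect is scalar). All constants are kept, so the objective (OFV)
is directly comparable to an exact adaptive Gauss–Hermite quadrature of
the marginal likelihood; on a 3-subject toy at the study parameters the
two agree to ~0.3.

At this population's dispersion, however (ω ≈ 0.82 with one or two
troughs per subject), the FOCE-I linearization is materially biased:
refits of simulated cohorts give median θ̂_CL some 20–30% above truth,
while the same refits under exact quadrature are nearly centered — the
textbook failure mode of FOCE for large random-effect variance and
sparse data. `fit_population` therefore defaults to an adaptive
Gauss–Hermite objective (21 nodes, centered and scaled at the FOCE
conditional modes; effectively exact for one random effect, and verified
against dense trapezoid integration), exactly as a NONMEM analyst would
escalate from FOCE to LAPLACE/importance sampling at this dispersion.
The FOCE-I objective remains available (`objective="foce"`) and is
cross-checked against the quadrature oracle in the tests.

**Parameter bounds.** The population parameters (log θ_CL, log θ_V,
log ω², log residual) are estimated by L-BFGS-B within physiological
bounds — CL 1–100 L/h/70kg, V 300–2000 L/70kg, ω² ≤ 4, proportional CV
0.05–1 — followed by a bounded Nelder–Mead polish. The bounds are not a
convenience: trough-only data make the marginal likelihood *multimodal
and nearly flat* across PK regimes. A "washout" mode with tiny V/F and
near-complete elimination within the dosing interval can fit trough data
as well as or better than the true accumulation regime (verified with
exact quadrature, not just the FOCE approximation; the regimes often
differ by under one OFV unit), so an unbounded optimizer is not a
consistent estimator here. The V/F bracket is pure physiology: apparent
oral volume is V/F with the intravenous V ≈ 4.6 L/kg (≈322 L/70kg), so
V/F below ~300 L/70kg would require bioavailability above 1, and V/F
above ~2000 L/70kg would require F < 0.16, far below the ~0.45–0.65
reported in children. Excluding physically impossible regions is the
standard population-PK remedy and is what any published control stream
does implicitly through its parameter bounds and initial estimates.
Default initial estimates are the final published values, as in any
refit of a published model.

Even inside the bounds, (CL, V) sit on a flat likelihood ridge: V is
weakly identified (the original analysis reports a bootstrap 95% CI of
94.8–1050.85 L/70kg), and single-replicate estimates of θ_CL scatter
from ~13 to ~24 L/h/70kg at the study design. Recovery is therefore
asserted on the *median* across ≥20 replicate cohorts, which is stable
at ~0.92 of truth (a small downward bias contributed by replicates whose
V̂ pins at the physiological floor — preferred here to the unstable,
nominally unbiased median obtained with looser V bounds); θ_V dispersion
is reported, not gated. The recovery experiments simulate uncensored
troughs: a substituted-BQL point mass at 0.125 mg/L at the generator's
~8% censoring rate measurably distorts any likelihood-based refit,
whereas at the <4% rate of the original assay it is benign.

Standard errors come from a finite-difference Hessian of the objective
(cov = 2·H⁻¹), with RSE% = 100·SE(log θ) for log-scale parameters.
Empirical-Bayes estimates (EBEs) are the conditional modes at the final
estimates; η-shrinkage is 100·(1 − SD(η̂)/ω). Stepwise covariate search
on CL uses power effects (cov/median)^θ for continuous covariates and
exp(θ·flag) for binary ones, forward addition at ΔOFV > 3.84 (p<0.05,
χ²₁) and backward elimination at ΔOFV > 6.63 (p<0.01). BQL observations
enter estimation with the substituted value 0.125 mg/L (the M3 censored
likelihood is out of scope). The bootstrap resamples subjects (not rows)
with replacement; the VPC simulates replicate datasets (IIV + residual +
BQL rule) and bins on weight tertiles, since trough-only data offer no
time axis.

## Synthetic cohort generator

The generator emulates the study population: 76 subjects contributing
~110 TDM events (samples per subject 1 + Binomial(2, 0.224), mean
110/76), ages lognormal on [1, 24) months (median 11, IQR ≈ 7.4–17),
weight and height from WHO-growth-shaped median curves rescaled to the
cohort medians (8.05 kg / 70 cm at 11 months — these are ill,
hospitalized children) with lognormal scatter, sex 76% male. Laboratory
covariates are drawn independently from lognormal or truncated-normal
marginals matched to the cohort median/IQR, except HGB and RBC which
share a latent factor (ρ ≈ 0.7) to exercise selection under
collinearity. Co-medication flags are Bernoulli at the reported rates.
Doses are uniform 4–10 mg/kg q12h rounded to practical 5 mg amounts;
therapy duration is lognormal (median 9.5 d, IQR 5–17.75) with a 3-day
inclusion floor.

**Dose titration.** Rows representing samples after ≥5 days of therapy
(or repeat samples) are treated as TDM-informed: their mg/kg dose is
scaled by (CL_i/CL_typ)^0.5 and clipped back to the 4–10 mg/kg policy
range, emulating prescribers adjusting after a first level. Without this
feedback, the stated dispersion (ω² = 0.674) censors ~12% of troughs
below the 0.25 mg/L quantitation limit; with it, ~8–9%.

**Known limitation — the BQL envelope.** The assay conditions imply that
below-quantitation samples are a <4% minority. Under the published
parameters that rate is unreachable by any dosing policy within 4–10
mg/kg: dosing *every* subject at the 10 mg/kg cap with zero residual
noise still censors ~6.5% of troughs when ω² = 0.674. The generator's
~8–9% is therefore the honest neighborhood of the stated conditions, and
the tests assert BQL is an active minority (2–10%) rather than the
unreachable figure. More broadly, the generator's labs are (HGB–RBC
aside) mutually independent and stationary, troughs are exactly at
steady state, and covariates carry no measurement error — so passing
tests demonstrate the *machinery* is correct under the assumed model,
not that the model describes any real cohort.

An optional planted mechanism (`TEN_FEATURE_TRUTH`) multiplies CL by
modest powers of HGB, RBC, WBC, INR and age, so that the concentration
truth set spans the ten features the selection stage is expected to
recover. Note that because the EBE clearance feature measures each
subject's *realized* clearance, it largely subsumes the planted lab
effects (and weight's allometric signal) downstream: on generator truth
the reliably confirmed set is {CL, TDOSE}, with WT/BSA/V confirmed in
roughly half of runs. This is a real difference from the published
cohort, where weight and hematology carried signal beyond the EBE.

## Feature selection (Boruta)

Each iteration appends a permuted shadow copy of every candidate, fits a
random-forest regressor, and records a hit for candidates whose impurity
importance beats the best shadow. Hit counts are tested against
Binomial(n, ½), two-sided, Bonferroni-corrected by the number of original
candidates, at α = 0.01 over 200 iterations; significantly-above →
confirmed, significantly-below → rejected (and removed from the design),
others tentative. Two deliberate choices: shadows are drawn from the
*full original* candidate set throughout, so the max-shadow bar does not
drop as rejections accumulate; and the forest is depth-limited (depth 5
default), because unlimited-depth impurity importance credits spuriously
correlated noise features at deep splits and inflates false
confirmations. Remaining tentative features are resolved by comparing
their median importance over the run to the median max-shadow importance.

## Learner comparison and metrics

Six tree-ensemble regressors are compared on the selected features:
XGBoost, LightGBM, GBDT, CatBoost, AdaBoost and random forest, each with
fixed documented hyperparameters (500 trees, learning rate 0.05, depth 4
for the boosters; 500 trees for RF) — reproducibility is preferred over
per-dataset tuning. A backend that is not importable (CatBoost in this
stack) is skipped with a warning. Data are split 70/30 by TDM event
(rows are treated as independent sampling events; a subject-grouped
split is available). Metrics: MSE, RMSE, MAE, R² and RA20 (fraction of
predictions within ±20% relative error, boundary inclusive); R² is
reported as not-applicable when the observations have zero variance. The
best model minimizes validation RMSE with R² as tie-break. Stability is
probed by bootstrap cross-validation (fit on a resample, score R²
out-of-bag, 10 iterations); external sets are scored without refitting,
using frozen training medians for imputation.

Because the trough target is heavy-tailed (ω = 0.82 on the log scale),
validation R² at ~90 held-out events swings by ±0.15 with the luck of
the split — an oracle predicting with the *true* individual clearance
scores only ~0.89. The generator-truth performance floor (best validation
R² ≥ 0.6 at ~300 events) is therefore asserted on the median across
seeds.

## Shapley attribution

Tree-ensemble predictions are decomposed with the path-dependent
formulation: the value of a coalition is the tree-conditional expectation
that follows the row on coalition features and averages children by
training cover elsewhere. A polynomial-time path algorithm computes these
Shapley values exactly per tree; they are verified against brute-force
coalition enumeration on small trees to 10⁻⁸, and local accuracy
(base + Σφ = prediction) is asserted for every supported backend
(sklearn trees/forests/GBDT, XGBoost with float32 split semantics,
LightGBM). An optional background matrix re-derives node covers by
routing those rows through each tree, pruning subtrees the background
never reaches, so the base value equals that set's mean prediction
exactly. AdaBoost aggregates by weighted median and is not additive over
trees; it is rejected for attribution. Waterfall ledgers order features
by |φ| and sum exactly to the prediction.

## Problem sizes in tests and the acceptance script

Test and acceptance runs use scaled-down but structurally faithful
designs chosen to keep the whole suite in the tens of minutes on one
CPU: 20 replicate cohorts at the full study design for clearance
recovery in the tests (60 in the acceptance script); 200 null cohorts
of 25 subjects for stepwise type-I
calibration; 10 seeds of the 300-row planted-truth design for Boruta;
5 cohorts of ~300 events for the pipeline floor; bootstrap and VPC at
reduced replicate counts in unit tests (the defaults remain n = 1000).
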