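# Methods

This note documents the models, the synthetic-data generator, the
numerical machinery and the design choices behind `twinlag`, in enough
detail that every number the package produces can be re-derived.

## 1. The data model

The sampling unit is the twin pair. A panel holds, per pair: zygosity
(MZ/DZ), per-twin sex (0 = male, 1 = female), and per-twin scores for a
set of traits over three waves, with missing cells as NaN. Twin order
within a pair is arbitrary; every estimator in the package is required
(and tested) to be invariant to swapping twin 1 and twin 2. The CSV
layout is wide, one row per pair (`<trait>_<wave>_t<1|2>`), because the
pair is the unit of the likelihood.

## 2. Biometric RI-CLPM

For traits k ∈ {personality, psychopathology} and waves t ∈ {1,2,3},
each twin's score is

    y[k,t] = μ[k,t] + RI[k] + w[k,t]
    w[t+1] = B[t] · w[t] + u[t+1]

with random intercepts RI (loadings fixed at 1 across waves:
time-invariant stability) and a within-person process w whose
per-interval 2×2 dynamics B[t] carry the autoregressive (diagonal) and
cross-lagged (off-diagonal) paths. Every latent part — RI, the wave-1
within component, each innovation u[t] — splits into an additive-genetic
part A and a non-shared-environment part E. A parts correlate 1.0
across MZ co-twins and 0.5 across DZ co-twins (the standard biometric
assumption, applied to the within-process innovations and the RIs
alike); E parts are independent between co-twins. Shared environment C
is deliberately absent from this model (the twin correlations it is
meant for show the DZ ≈ ½·MZ pattern). The A and E streams of the
within-person process share the same B: there is one within-person
process per trait, observed as an A + E mixture; giving the two streams
separate dynamics would double the dynamic parameters with no
corresponding moment structure to identify them.

Free parameters (38): eight 2×2 covariance blocks (A and E for: RI,
wave-1 within, two innovations) = 24; two free 2×2 dynamics matrices
= 8; six means. Means are free per variable but equal across twins,
sexes and zygosity groups because the model's inputs are
sex-residualized scores.

**Implied moments.** Propagating each stream gives a 6×6 within-twin
covariance M_A + M_E (trait-major variable order); the cross-twin block
is r·M_A with r the zygosity genetic correlation. The 12×12 pair
covariance is [[W, rM_A], [rM_A, W]]. The builder is verified against
Monte-Carlo covariances of the generator at n = 10⁶ pairs, for both
zygosities.

**Derived quantities.** With Var(w_k(t)) propagated through B:
ri_share[k,t] = Var(RI_k)/(Var(RI_k)+Var(w_k(t)));
A_share_RI[k] = varA_RI/(varA_RI+varE_RI);
rA_RI = covA_RI/√(varA_RI[1]·varA_RI[2]); a standardized path from
source s at t to target g at t+1 is B[t][g,s]·SD(w_s(t))/SD(w_g(t+1)).

**Cross-lag tests.** Each of the four cross-lagged coefficients is fixed
to zero in turn and the model refit (warm-started from the full
estimates); the −2lnL difference on 1 df is the likelihood-ratio test.
Simulation at the null shows the nominal 5% level is attained (the
test-suite calibration study runs 100 replicates × 4 paths).

## 3. Cholesky ACE/AE

A = aaᵀ, C = ccᵀ, E = eeᵀ with lower-triangular paths (PSD by
construction); within-twin covariance A+C+E, cross-twin A+C (MZ) or
½A+C (DZ); sex-specific means per variable. The AE model sets c = 0.
AIC = −2lnL + 2k; BIC = −2lnL + k·ln(N) with N the number of *pairs* —
pairs, not individuals, are the independent units. For bivariate fits
the percentage of a trait's genetic variance shared with the other is
reported as 100·rA² (symmetric in the two traits; identical to the
path-based a₂₁²/(a₂₁²+a₂₂²) for the second-ordered trait — an algebraic
identity of the Cholesky factorization), with the order-dependent
convention available as an option.

## 4. Likelihood machinery (FIML)

All likelihood-based fits use the same core: rows are grouped by
(model-moment key, missing pattern) — zygosity and sex pair for the
Cholesky models, zygosity for the RI-CLPM — and each group is reduced
once to (n, mean, scatter). The multivariate-normal −2lnL is then

    Σ_g n_g · [ d_g·log 2π + log|Σ_g| + tr(Σ_g⁻¹ S_g) + δ_gᵀ Σ_g⁻¹ δ_g ]

over observed sub-vectors, which is an exact reformulation of the
per-row density sum (tested to 1e-8 relative against brute-force
summation) and makes each objective evaluation independent of the
sample size. Missing data therefore enter through their observed
sub-vectors — full-information ML, no imputation — in all twin models;
the imputation stage exists only ahead of the factor-score stage.

Optimization is multi-start L-BFGS-B on unconstrained
parameterizations: log-Cholesky factors for every covariance block
(variances positive, blocks PSD by construction; a uniqueness driven to
its bound is flagged as a Heywood case), raw entries for paths and
means. Convergence tolerances are tight (ftol 1e-11, gtol 1e-7)
because likelihood-ratio statistics compare −2lnL values of nested
fits; looser defaults leave optimization gaps of the same order as the
χ² values being tested (observed as deflated null rejection rates
before tightening). Starting values are method-of-moments: the
double-entry MZ cross-twin covariance estimates M_A, the pooled
within-twin covariance the total; RI blocks come from the lag-2 wave
block, dynamics from lagged-covariance regression; all intermediate
blocks are eigenvalue-floored to keep the start interior. Replicate
simulation studies in the test suite start the optimizer at the
generating values — a standard simulation-study device that changes
nothing about the optimum, only the path to it.

**Fit indices.** The saturated model is an unstructured mean vector and
covariance per zygosity group, fitted by EM over missing patterns (the
E-step works on the same grouped sufficient statistics, so complete
data converges in one sweep to the closed-form MLE). The baseline is
per-group independence: free means and variances, zero covariances,
whose MLE is closed-form because the likelihood factorizes. With
χ²_M = −2lnL_model − (−2lnL_sat), CFI, TLI are standard;
RMSEA = √(G·max(χ²_M−df_M, 0)/(df_M·N)) with G = 2 groups and N the
total pair count. These conventions differ across software; they are
fixed here so results reproduce bit-for-bit given the definition.

## 5. Measurement stage

Indicators are z-standardized over pooled individuals before factor
analysis because the constituent scales have heterogeneous ranges. The
constrained model is one factor per wave, factors correlated (Φ free,
3×3), loadings shared bit-identically across waves by parameterization
(a single λ vector), uniquenesses free per indicator and wave, factor
variances 1. Estimation is ML on the 3k×3k covariance; the factor
sign is oriented so the anchor indicator (extraversion; depressive
symptoms) loads positively. Explained variance is the mean over
indicators and waves of λ²/(λ²+ψ).

Factor scores are regression (Thurstone) scores computed *per wave*
from that wave's indicators only: λᵀΣ_t⁻¹z_t with Σ_t = λλᵀ + Ψ_t.
Scoring a wave from all 21 indicators jointly (the other natural
convention) lets each wave's score borrow cross-wave information
through the inter-wave factor correlations; in generator-recovery runs
this inflated the apparent random-intercept share of variance (a
between/within decomposition downstream is only meaningful if the
occasion-specific part of each score comes from that occasion), so the
per-wave convention is used. Missing indicators are handled through
the observed sub-vector's implied covariance; a wave with no observed
indicator yields a missing score.

**Imputation.** Missing scale scores are imputed ahead of factor
analysis by chained equations (fully conditional specification) with
Bayesian linear models and posterior sampling, averaged over
`n_imputations` completed datasets (default 10, with 10 FCS sweeps
each) — i.e., mean scores enter the factor analysis. Co-twin variables
are not used as predictors; the twin models downstream handle
missingness by FIML anyway. Averaging m completed datasets shrinks the
imputed-cell variance by (1−1/m)(1−R²) of the conditional model, which
inflates correlations slightly (≈ +0.04 at 20% missingness and
wave-to-wave correlations near 0.75); this is a property of the
mean-score procedure itself, worth remembering when comparing
imputed-data descriptives with complete-data ones.

**Composites.** The cross-wave composite is the regression score of a
one-factor ML model over the three wave scores (capturing their shared
variance); twins with fewer than two observed waves get a missing
composite, and a factor implying less than ~2% shared variance between
every pair of waves is flagged as degenerate.

## 6. Descriptive correlations

Phenotypic correlations are pairwise-complete Pearson over pooled
individuals. Cross-twin correlations are double-entry: each pair
contributes in both twin orders, making the estimator exactly
order-invariant (the field's standard device given arbitrary within-pair
order). Under an AE generator, E[r_MZ] ≈ a² and E[r_DZ] ≈ a²/2, which
the tests verify. Descriptive layers use pairwise deletion; only the
likelihood-based stages use FIML.

## 7. Synthetic-data generator and its calibration

The generator produces exactly the structure the models assume:
jointly normal A/E components with the 1/0.5 cross-twin A correlation,
linear within-person dynamics, linear measurement with independent
unique errors, wave-level dropout plus cell-level MCAR. MZ pairs are
same-sex; DZ pairs mix same- and opposite-sex with independent sexes;
sex enters as an additive mean shift only.

Default generating conditions (`twinlag.calibration`): 577 MZ and 961
DZ pairs; RI variance shares per wave (53/58/64)% for personality and
(39/38/45)% for psychopathology; A shares of RI variance 70% / 83%; RI
genetic correlation −0.55; bivariate composite components a² =
0.63/0.57, e² = 0.37/0.43, rA = −0.513, rE = −0.374; the standard
loadings for both factors with uniqueness 1−λ²; wave participation
emulating 1393/1065/883 of 1538 pairs. Innovation covariances are
*solved* from the requested shares given the dynamics, so the target
shares hold exactly in the implied moments; a helper solves the fixed
point that sets one cross-lagged path to a requested *standardized*
value (the target trait's variance depends on the path itself).

Four generator quantities are not pinned down by any recovery target
and are package choices: within-process autoregression 0.35
(personality) / 0.45 (psychopathology), chosen so the implied
wave-to-wave stability correlations land near the familiar 0.64–0.78
range for these constructs; within-process cross-trait correlation
−0.40, placing the cross-sectional personality–psychopathology
correlation near −0.44; within-process A shares 0.30 / 0.40, placing
cross-sectional heritabilities near 0.50 / 0.57; RI E-correlation
−0.30. Sex mean effects default to +0.15 (personality) / −0.25
(psychopathology) SD for females, exercising the residualization stage
without affecting any covariance-based target.

**What the generator does not emulate** — and hence what passing
recovery tests do not establish about real data: non-normal and
floor-/ceiling-limited scale distributions; missingness related to the
phenotype (attrition correlated with problem behavior); sex differences
in variance components or genetic correlations below 0.5 for
opposite-sex pairs (sex enters means only); assortative mating, sibling
interaction, or shared-environment effects in the RI-CLPM; age
heterogeneity within wave; measurement non-invariance across waves
(equality of loadings holds by construction). Recovery results
demonstrate internal consistency of the chain under its own
assumptions, not robustness to their violation.

## 8. Simulation sizes and test design

Replicate studies in the test suite run at 1,500–3,000 pairs with
complete data, where the grouped-sufficient-statistics likelihood makes
each fit a fixed small cost; single dedicated tests exercise the
missing-data FIML path, imputation and the end-to-end pipeline at
study-scale n. The cross-lag type-I study uses 100 replicates × 4
paths (400 likelihood-ratio tests; tests within a replicate share the
full fit, so the effective Monte-Carlo error is slightly above pure
binomial). The fit-index study uses 100 replicates at 3,000 pairs.
The oracle studies use 10⁶ pairs. `scripts/acceptance.py` re-runs the
full simulate → fit chain for every reported quantity at 3,000 pairs
(1,500 for the cross-lag target; 20,000 individuals for the
measurement target), with all randomness derived from `--seed`.

## 9. Known limitations

- Two traits × three waves only; the moment builders are written for
  this design, not generalized panel shapes.
- No sex-limitation models beyond sex-specific means (Cholesky) or
  residualization (RI-CLPM); no dominance (D) component; no
  ordinal/threshold liability models — inputs are treated as continuous.
- Standard errors are not routinely computed (the analysis surface is
  point recovery plus likelihood-ratio tests); the optional
  finite-difference machinery is deliberately minimal.
- The RI-CLPM likelihood surface can be flat when RI variance shares
  are extreme; boundary estimates (a variance block collapsing) are
  flagged, not prevented.
- With heavy cell-level missingness the number of distinct missing
  patterns grows and the grouped likelihood loses its speed advantage
  (it remains exact).
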