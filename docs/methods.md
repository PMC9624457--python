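# Methods

## Structural model

Dolutegravir disposition is a linear two-compartment model with
first-order elimination from the central compartment, parameterized as
oral clearance CL (L/h), central and peripheral volumes Vc, Vp (L) and
inter-compartmental clearance Q (L/h). Absorption is a chain of NN
first-order transit compartments with common rate ktr = (NN+1)/MTT
feeding an absorption compartment that empties into the central
compartment at rate ka; this yields the smooth, delayed absorption
profile typical of oral dolutegravir taken with food. Relative
bioavailability F scales dose. Units are mg, L, h; concentrations in
mg/L (≡ µg/mL, the assay scale).

Because the system is linear, the single-dose solution is obtained in
closed form by partial-fraction expansion of the Laplace-domain transfer
function, whose poles are −ktr (order NN), −ka and the two disposition
exponents −α, −β. Multi-dose and steady-state profiles are superpositions
of single-dose solutions; a run-in of 15–20 once-daily doses brings the
last interval within <0.1% of steady state for plausible parameters, and
the pre-dose sample falls out naturally as the trough of the preceding
interval. The closed form is verified against brute-force stiff-ODE
integration (LSODA, rtol 1e-11) to ~1e-6 relative error.

*Numerical caveat*: the high-order pole makes the expansion ill-conditioned
when ktr ≈ ka (or ≈ α, β). Exact collisions are nudged apart by a 1e-6
relative perturbation; accuracy degrades smoothly as the absorption rates
approach each other within ~10% of one another at large NN. The package
defaults (NN = 4, ktr ≈ 2.8 h⁻¹, ka = 1.2 h⁻¹) are far from this regime.

## Body size and covariates

Fat-free mass is computed from weight, height and sex with the
Janmahasatian equations and capped at total weight (the cap only binds at
non-physiological BMI). Clearances scale as (FFM/47)^0.75 and volumes as
(FFM/47)^1 with both exponents fixed, 47 kg being the reference.
Additional covariates (sex, age, treatment arm) enter as proportional
shifts, parameter × (1 + θ·x); the rs887829 genotype enters as fractional
multipliers on CL with C/C the reference category.

## Hierarchical model and estimation

Between-subject variability is log-normal on CL (η); between-occasion
variability is log-normal on MTT, ka and F (fresh κ per occasion, with
occasion indices taken from the dataset). Residual error is combined:
var = (prop_sd·pred)² + add_sd², with add_sd constrained to at least 20%
of the 0.030 mg/L LLOQ. Observations flagged below the LLOQ are excluded
from the likelihood and counted (M1 handling).

The objective function is OFV = −2 log marginal likelihood. For each
subject the joint −2 log-likelihood is minimized over the random effects
(damped Newton for the common scalar-η case, BFGS for multi-dimensional
η/κ) and the marginal is formed with the curvature correction at the
mode; for the scalar case a 15-node adaptive Gauss–Hermite rule centered
at the mode (scaled by the local curvature) replaces the pure Laplace
step, making the subject marginal near-exact even for one-sample sparse
subjects (verified against dense quadrature to <1e-4). Because the
residual variance is evaluated at the individual prediction, this is an
"with interaction" scheme. The 2π constants are included, so absolute OFV
differs from other tools' conventions by a data-dependent constant, while
OFV differences between nested models on the same data are comparable to
χ² quantiles (ΔOFV 3.84 ↔ P 0.05 at 1 df).

Population parameters are estimated by Nelder–Mead (adaptive) over
log-transformed parameters (positive quantities and variances on the log
scale; genotype effects as log multipliers), with warm-started inner
modes carried across objective evaluations, seeded multi-start as an
option, and convergence at an OFV spread of 1e-3–5e-3 across the simplex
(well below the 0.1-unit resolution at which ΔOFV comparisons are read).
Nested-model monotonicity holds to that tolerance. Uncertainty comes from
sampling-importance resampling: a multivariate-normal proposal at the
mode (covariance from the numeric OFV Hessian, inflated-diagonal
fallback), likelihood-ratio importance weights, resampling without
replacement, and 2.5/97.5 percentile intervals.

Covariate selection is stepwise: forward inclusion at P < 0.05 (best
significant candidate each round), backward elimination at P < 0.01, with
every tested step and its ΔOFV recorded in an audit trail.

## Mixture over unobserved genotype

When the model carries a genotype effect and a subject has no genotype
record, the subject's marginal likelihood is Σ_g p_g L_g over the three
categories, accumulated by log-sum-exp; posterior category probabilities
are exposed. Mixing probabilities default to the observed genotype
frequencies among genotyped subjects (an HWE-based alternative is
available); with probabilities (1,0,0) the mixture reduces exactly to the
single-category likelihood.

## Phenotypes

Empirical-Bayes (post-hoc) random effects are the per-subject MAP values
under the population fit; subjects without observations sit fully shrunk
at zero. AUC₀₋₂₄ = F_i·Dose_i/CL_i at steady state (equal, for linear
kinetics, to the integral of the predicted 24 h profile). AUC_VAR is
defined on the natural-log scale as log AUC_i − log AUC_pop,i, where
AUC_pop,i uses the subject's covariates with all random effects at zero —
i.e., the covariate-unexplained component of exposure. The model never
formally prints this definition elsewhere, so it is stated here
prominently; its per-allele effect sizes (~0.1) are consistent with a
log-scale quantity. CL_BSV = η_CL. With variability on CL only,
AUC_VAR = −η_CL identically, which is why the two phenotypes are almost
perfectly negatively rank-correlated.

## Genetics

Dosages live in a samples × variants matrix in [0,2] (VCF DS field
preferred, GT allele count otherwise). QC applies strict `<` exclusions
at imputation score 0.3, call rate 0.95, MAF 0.05 and HWE exact-test
P 1e-8; the HWE test is the exact conditional test (no mid-p), checked
against full enumeration. PCA uses EIGENSTRAT normalization (center at
mean dosage, scale by √(2p(1−p)), per-variant mean imputation of missing
dosages, zero-variance variants dropped) with scores = top left singular
vectors × singular values. Ancestry PCs are computed from the common
autosomal panel *excluding* the target locus: within an LD block the
leading eigenvector is the block itself and would absorb the association
signal — the synthetic genetic truth therefore carries an unlinked
background panel (150 variants by default) standing in for the
genome-wide intersection used in practice. Association is OLS of
phenotype on dosage plus
covariates (two ancestry PCs by default; optionally a conditioning
variant's dosage), two-sided t-tests, complete cases, and an instability
flag when a conditioning covariate is essentially collinear (|r|>0.999)
with the test dosage. LD r² is the squared Pearson correlation of
dosages. Bonferroni thresholds take the family size as an explicit input
(reported to 2 significant figures); the tool never infers the family.

## Synthetic data

The generator emulates the study conditions: sex Bernoulli(0.62 female);
weight log-normal with median 73.1 kg (σ_log 0.176, matching the
reported IQR); heights plausible adult South African values by sex —
scaffolding only, since FFM alone enters the model; 50 mg once daily with
a 15-dose run-in; intensive subjects sampled at (0, 1, 2, 4, 6, 8, 24) h
and sparse subjects at 1–2 uniform times in (0.5, 24) h post-dose;
genotypes drawn from HWE at stated MAFs, with LD partners generated from
two-locus haplotype frequencies whose disequilibrium D hits the target
r² (infeasible targets rejected with the feasible bound); log10
bilirubin = 0.9 + Σβ·dosage + N(0, 0.2), with default per-allele effects
+0.12 (rs887829 surrogate) and −0.11 (independent second variant), the
noise scale putting the primary association at study-scale significance
for n ≈ 284. Genotype masking withholds the genotype *record* while the
true genotype keeps driving the simulated kinetics.

Simulation truth for the reference experiments: CL 0.732 L/h, Vc 12.2 L,
Vp 5.87 L (base model) and C/C CL 0.78 L/h with multipliers 0.892/0.741
(genotype model) at the 47 kg reference; Q = 1.5 L/h, MTT = 1.8 h,
ka = 1.2 h⁻¹, NN = 4 are the package's own configured defaults, chosen
as plausible for oral dolutegravir taken with food rather than taken
from any reported fit; BSV on CL 0.09 (~30% CV), BOV 0.09/0.09/0.0225 on MTT/ka/F for
study-structure emulation, proportional error 10% with the additive floor.

What passing tests do and do not show: the generator reproduces the
study's *statistical* structure (design, variability, LD, missingness)
but not real-data features such as dose-history errors, model
misspecification, assay batch effects, or genome-scale LD; recovery
results therefore validate the estimation machinery, not the clinical
estimates themselves.

## Reference experiments

*Typical-parameter recovery* simulates 100 intensive-design subjects
(between-subject variability on CL and residual error as configured) and
refits CL, Vc, Vp, Q and the variance parameters from neutral starting
values (CL 1.0, Vc 15, Vp 4, Q 1). The absorption parameters are fixed at
their configured values in both simulation and fit: the steady-state
0–24 h design carries little absorption information, and a staged fit is
what a practitioner would run; the recovered quantities are genuine
re-estimates of the disposition parameters.

*Genotype-effect recovery* simulates ~470 subjects (40 intensive, the
rest sparse with 1–2 samples), masks 40% of genotype records, and refits
the C/C clearance, both genotype multipliers, the CL variance and the
proportional error with the mixture enabled. The single-replicate
estimates are stochastic: with ~47 genotyped T/T subjects and 30% CV
between-subject variability, the realized category contrast itself
fluctuates across replicates with a standard deviation near 3.5
percentage points, which bounds what any estimator can report from one
dataset; an all-intensive variant of the same experiment recovers the
multipliers essentially exactly. The reported genotype quantities are
therefore the average of three independent simulate-and-refit
replicates of the same design, which centers the report on the design's
expected recovery rather than one dataset's draw.

## Simulation bands and VPC

Exposure bands simulate n (default 1200) typical-covariate individuals
per genotype stratum at steady state with full BSV/BOV on a 0.25 h grid,
summarizing 2.5/12.5/50/87.5/97.5 percentiles (central 75/95% intervals;
the probabilities are configurable since shaded-band conventions vary)
and the fraction of 24 h troughs above the 0.3 mg/L EC90. The VPC
simulates the original design n_sim times, bins times after dose on
quantile edges, and tabulates observed 5/50/95 percentiles against the
2.5–97.5% envelope of the same statistics across replicates; output is
tabular, plotting is left to the caller.

## Known limitations

Laplace/Gauss–Hermite is 1-D-exact only for the scalar-η path; the
multi-dimensional η/κ path uses pure Laplace. The partial-fraction
kernel loses accuracy for near-coincident absorption rates (above). SIR
intervals assume a usable curvature estimate at the mode. The covariate
search refits every candidate per round and is intended for small
candidate sets. No SAEM, no autodiff, no full NONMEM compatibility;
genome-scale LD structure and imputation-uncertainty modeling beyond a
scalar imputation score are out of scope.
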