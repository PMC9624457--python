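# poppkgx

Population pharmacokinetics and pharmacogenetics of dolutegravir exposure,
as a tested, reusable Python library.

HIV treatment programmes across sub-Saharan Africa rely on once-daily
50 mg dolutegravir. Its clearance runs through hepatic UGT1A1
glucuronidation, and promoter variants in strong linkage with the
Gilbert-trait allele (tagged by *UGT1A1* rs887829) reduce that capacity.
`poppkgx` implements the full two-stage analysis used to quantify such
effects when intensive sampling is only available for a small subset of a
trial cohort:

1. **Population PK model** — a nonlinear mixed-effects model with
   two-compartment disposition, transit-compartment absorption
   (`ktr = (NN+1)/MTT`), fat-free-mass allometry (exponents 0.75 on
   clearances, 1 on volumes, 47 kg reference), log-normal between-subject
   (η on CL) and between-occasion (κ on MTT, ka, F) variability, and
   combined additive + proportional residual error with the additive SD
   floored at 20% of the 0.030 mg/L LLOQ. The marginal likelihood
   (OFV = −2 log L) uses a Laplace/adaptive Gauss–Hermite approximation
   with η–ε interaction. Subjects without genotype enter a
   genotype-covariate model through a **mixture**: their likelihood is the
   genotype-frequency-weighted sum over C/C, C/T and T/T components.
   Empirical-Bayes (post-hoc) estimates yield the association phenotypes
   AUC₀₋₂₄ = F·Dose/CL_i, AUC_VAR = log AUC_i − log AUC_pop,i, and
   CL_BSV = η_CL.

2. **Genetic association** — genotype QC (imputation score < 0.3, call
   rate < 95%, MAF < 0.05, HWE exact P < 1e-8; strict `<` exclusion),
   EIGENSTRAT-normalized ancestry PCA, additive OLS association of the
   phenotypes (and log₁₀ bilirubin) with per-variant dosages adjusting for
   two principal components, conditional locus scans with LD r²
   annotation, and Bonferroni thresholds with an explicit family size
   (0.05/9 = 5.6e-3, 0.05/853 = 5.9e-5).

A synthetic-data generator (`poppkgx.synth`) reproduces the statistical
structure of the study — 41 intensive subjects sampled pre-dose and at 1,
2, 4, 6, 8, 24 h, a sparse stratum with 1–2 samples, ~40% of subjects
without genotype, HWE genotypes with configurable LD, and a
genotype-driven bilirubin phenotype — so every stage is testable without
any restricted data.

## Worked example

`examples/04_genotype_mixture_model.py` simulates a 300-subject mixed
cohort (40 intensive, 260 sparse, 40% ungenotyped) and refits the
genotype model with the mixture enabled:

```
PKDataset(n_subjects=300, n_observations=677, n_blq=0) - 110 subjects without genotype record
mixing probabilities (observed frequencies): [0.332, 0.479, 0.189]

C/C clearance: 0.801 L/h (truth 0.78)
C/T decrease:  14.2% (truth 10.8%)
T/T decrease:  20.4% (truth 25.9%)
genotype effect LRT: dOFV -14.6, 2 df, P = 6.85e-04
```

The clearance decreases are recovered to within the sampling noise of a
cohort this size (a single ~300-subject dataset determines each category
contrast only to a few percentage points), and the likelihood-ratio test
detects the genotype effect decisively. The multipliers translate
directly into exposure: a T/T individual clears dolutegravir ~26% slower
and therefore keeps ~35% higher steady-state AUC and the highest troughs
relative to the 0.3 mg/L EC90 reference
(`examples/05_exposure_simulation_vpc.py`).

Each example script is a short, self-contained narrative of one
capability: structural predictions, population fitting, phenotype
derivation + association, the mixture model, and simulation/VPC.

There is also a thin CLI over the pipeline stages
(`poppkgx run-all --output-dir out --seed 1`, plus `simulate`, `fit`,
`ebe`, `assoc`, `locus`, `vpc` subcommands), which writes every stage
artifact and a JSON run manifest.

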