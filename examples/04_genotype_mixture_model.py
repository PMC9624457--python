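"""Fit the genotype-covariate model with a mixture over missing genotypes.

Simulates a 300-subject mixed intensive + sparse cohort in which 40% of subjects
lack a genotype record, fits clearance multipliers for C/T and T/T
relative to C/C with ungenotyped subjects marginalized over the observed
genotype frequencies, and compares the model with and without the
genotype effect by likelihood-ratio test.
"""

from poppkgx import MixtureSpec, fit, lrt, ofv
from poppkgx.synth import (
    SimulationDesign,
    default_genetic_truth,
    generate_study,
    genotype_truth_model,
)

truth = genotype_truth_model()
truth.re.bov = {}
design = SimulationDesign(
    n_intensive=40, n_sparse=260, sparse_samples_per_subject=(1, 2),
    fraction_ungenotyped=0.40,
)
study = generate_study(design, truth, default_genetic_truth(), seed=9)
data = study["pk"]
print(data, f"- {int(study['masked'].sum())} subjects without genotype record")

model = truth.copy()
model.covariates.genotype_cl = {"C/T": 1.0, "T/T": 1.0}
model.mixture = MixtureSpec.from_data(data)
print(f"mixing probabilities (observed frequencies): "
      f"{[round(p, 3) for p in model.mixture.probs]}")

geno_fit = fit(
    model, data, ["CL", "geno_CT", "geno_TT", "bsv_CL", "prop_sd"],
    init={"CL": 1.0, "bsv_CL": 0.1, "prop_sd": 0.15}, seed=0,
)

no_geno = geno_fit.model.copy()
no_geno.covariates.genotype_cl = None
base_fit = fit(no_geno, data, ["CL", "bsv_CL", "prop_sd"], seed=0)

est = geno_fit.estimates
p = lrt(base_fit.ofv, geno_fit.ofv, df=2)
print(f"\nC/C clearance: {est['CL']:.3f} L/h (truth 0.78)")
print(f"C/T decrease:  {100 * (1 - est['geno_CT']):.1f}% (truth 10.8%)")
print(f"T/T decrease:  {100 * (1 - est['geno_TT']):.1f}% (truth 25.9%)")
print(f"genotype effect LRT: dOFV {geno_fit.ofv - base_fit.ofv:+.1f}, 2 df, P = {p:.2e}")
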