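"""Post-hoc (empirical Bayes) individual estimates and association phenotypes.

From a converged population fit, each subject's random effects are set to
the mode of their penalized individual likelihood (MAP given the
population distribution — "post-hoc Bayes").  Three phenotypes follow:

* ``AUC_0_24``   — steady-state area under the curve over one dosing
  interval, by the clearance identity AUC = F_i * Dose_i / CL_i (mg*h/L).
* ``AUC_VAR``    — the covariate-unexplained component of AUC on the
  natural-log scale: log(AUC_i) - log(AUC_pop,i), where AUC_pop,i uses
  the subject's covariates with all random effects at zero.  This is the
  primary genetic-association phenotype.
* ``CL_BSV``     — the between-subject random effect (eta) on clearance,
  the secondary phenotype.

With between-subject variability on CL only, AUC_VAR = -eta_CL exactly;
the two phenotypes are strongly negatively correlated by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import PKDataset, Subject
from .nlme import PopPKModel, _dims, _laplace_component, _predict_subject
from .pk import ALLO_EXP_CL

__all__ = ["empirical_bayes", "compute_auc", "derive_phenotypes"]


def _subject_geno(model: PopPKModel, subj: Subject) -> str:
    if model.covariates.genotype_cl is not None and subj.geno:
        return subj.geno
    return "C/C"


def empirical_bayes(model: PopPKModel, data: PKDataset) -> pd.DataFrame:
    """MAP random effects per subject.

    Columns: ``eta_<param>`` for between-subject effects and
    ``kappa_<param>`` for the mean between-occasion effect per parameter.
    Subjects with no usable observations sit at the prior mode (all
    zeros, fully shrunk).
    """
    rows = []
    for subj in data.subjects:
        dims = _dims(model, subj)
        _, eta = _laplace_component(model, subj, _subject_geno(model, subj))
        rec: dict = {"ID": subj.id}
        for p in sorted(model.re.bsv):
            if model.re.bsv[p] > 0:
                i = dims.index(("bsv", p, -1))
                rec[f"eta_{p}"] = float(eta[i])
        for p in sorted(model.re.bov):
            if model.re.bov[p] > 0:
                ks = [eta[i] for i, d in enumerate(dims) if d[0] == "bov" and d[1] == p]
                rec[f"kappa_{p}"] = float(np.mean(ks)) if ks else 0.0
        rows.append(rec)
    return pd.DataFrame(rows).set_index("ID")


def compute_auc(F_i: float, dose: float, CL_i: float) -> float:
    """Steady-state AUC over one dosing interval: F_i * dose / CL_i (mg*h/L)."""
    if CL_i <= 0:
        raise ValueError("CL_i must be strictly positive")
    return F_i * dose / CL_i


def derive_phenotypes(
    model: PopPKModel,
    data: PKDataset,
    ebe: pd.DataFrame | None = None,
    daily_dose: float = 50.0,
) -> pd.DataFrame:
    """Per-subject phenotype table: AUC_0_24, AUC_VAR, CL_BSV.

    ``AUC_pop,i`` uses the subject's covariates (fat-free-mass allometry
    and, when the model carries one, the genotype effect) with all random
    effects at zero, so AUC_VAR isolates the random-effect component.
    Subjects whose dose history is empty are dropped with a note column.
    """
    if ebe is None:
        ebe = empirical_bayes(model, data)
    th = model.theta
    rows = []
    for subj in data.subjects:
        if subj.dose_amts.size:
            dose = float(np.max(subj.dose_amts))
        else:
            dose = daily_dose
        geno = _subject_geno(model, subj)
        allo = (subj.ffm / model.covariates.ref_ffm) ** ALLO_EXP_CL if model.covariates.allometry else 1.0
        cl_pop = th.CL * allo * model.covariates.cl_multiplier(geno)
        for e in model.covariates.effects:
            from .nlme import _covariate_value

            cl_mult = 1.0 + e.theta * (_covariate_value(subj, e.covariate) - e.center)
            if e.parameter == "CL":
                cl_pop *= max(cl_mult, 1e-6)
        eta_cl = float(ebe.loc[subj.id].get("eta_CL", 0.0)) if subj.id in ebe.index else 0.0
        kappa_f = float(ebe.loc[subj.id].get("kappa_F", 0.0)) if subj.id in ebe.index else 0.0
        cl_i = cl_pop * np.exp(eta_cl)
        f_i = th.F * np.exp(kappa_f)
        auc_i = compute_auc(f_i, dose, cl_i)
        auc_pop = compute_auc(th.F, dose, cl_pop)
        rows.append(
            {
                "sample_id": subj.id,
                "AUC_0_24": auc_i,
                "AUC_VAR": float(np.log(auc_i) - np.log(auc_pop)),
                "CL_BSV": eta_cl,
                "CL_i": cl_i,
                "F_i": f_i,
                "genotyped": subj.geno is not None,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
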