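"""Nonlinear mixed-effects estimation for the population PK model.

The hierarchical model: individual structural parameters are the typical
values (at 47 kg fat-free mass) scaled by allometry, optional covariate
and genotype effects, and log-normal random effects — between-subject
(eta, here on CL) and between-occasion (kappa, here on MTT, ka and F).
Residual error is combined additive + proportional, with the additive SD
constrained to at least 20% of the LLOQ.

The objective function value (OFV) is -2 log marginal likelihood
approximated by the Laplace method with eta-epsilon interaction: per
subject the joint -2 log-likelihood is minimized over the random effects
and a log-determinant curvature correction is added.  The 2*pi constants
are included, so absolute OFV differs from NONMEM's convention by a
data-dependent constant, but OFV *differences* between nested models on
the same data are directly comparable to chi-square quantiles.

Subjects without observed genotype enter a genotype-covariate model
through a mixture: their marginal likelihood is the mixing-probability-
weighted sum of the per-category likelihoods (log-sum-exp).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .data import PKDataset, Subject
from .pk import ALLO_EXP_CL, ALLO_EXP_V, REF_FFM, StructuralParams
from .pk import _laplace1, _profile  # closed-form kernels

__all__ = [
    "RandomEffectsSpec",
    "ErrorModel",
    "CovariateEffect",
    "CovariateModel",
    "MixtureSpec",
    "PopPKModel",
    "FitResult",
    "individual_neg2ll",
    "ofv",
    "fit",
    "lrt",
    "covariate_search",
    "mixture_marginal_neg2ll",
    "sir_ci",
    "GENOTYPES",
]

GENOTYPES = ("C/C", "C/T", "T/T")

_LOG2PI = math.log(2.0 * math.pi)
_STRUCT_NAMES = ("CL", "Vc", "Vp", "Q", "MTT", "ka", "F")


@dataclass
class RandomEffectsSpec:
    """Variances of log-normal random effects, keyed by parameter name."""

    bsv: dict[str, float] = field(default_factory=dict)  # between-subject
    bov: dict[str, float] = field(default_factory=dict)  # between-occasion

    def __post_init__(self) -> None:
        for d in (self.bsv, self.bov):
            for p, v in d.items():
                if p not in _STRUCT_NAMES:
                    raise ValueError(f"unknown parameter {p!r} in random effects")
                if v < 0:
                    raise ValueError("random-effect variances must be >= 0")


@dataclass
class ErrorModel:
    """Combined residual error: var = (prop_sd*pred)^2 + add_sd^2.

    The additive SD is constrained to at least 20% of the LLOQ
    (default LLOQ 0.030 mg/L).
    """

    prop_sd: float = 0.10
    add_sd: float = 0.006
    lloq: float = 0.030

    def __post_init__(self) -> None:
        if self.prop_sd < 0:
            raise ValueError("prop_sd must be >= 0")
        if self.add_sd < 0.2 * self.lloq - 1e-12:
            raise ValueError("add_sd must be at least 20% of the LLOQ")


@dataclass
class CovariateEffect:
    """Proportional covariate effect: parameter *= (1 + theta * (x - center))."""

    parameter: str
    covariate: str  # SEX, ARM or AGE
    theta: float = 0.0
    center: float = 0.0

    @property
    def label(self) -> str:
        return f"cov_{self.parameter}_{self.covariate}"


@dataclass
class CovariateModel:
    """Covariate parameterization: allometry, genotype CL multipliers, others.

    ``genotype_cl`` maps genotype category to a fractional CL multiplier
    with "C/C" the reference (1.0); e.g. {"C/T": 0.892, "T/T": 0.741}.
    """

    allometry: bool = True
    ref_ffm: float = REF_FFM
    genotype_cl: dict[str, float] | None = None
    effects: list[CovariateEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotype_cl is not None:
            for g, m in self.genotype_cl.items():
                if g not in GENOTYPES:
                    raise ValueError(f"unknown genotype category {g!r}")
                if not m > 0:
                    raise ValueError("genotype multipliers must be > 0")

    def cl_multiplier(self, geno: str) -> float:
        if self.genotype_cl is None or geno == "C/C":
            return 1.0
        return self.genotype_cl.get(geno, 1.0)


@dataclass
class MixtureSpec:
    """Mixing probabilities over genotype categories for ungenotyped subjects."""

    categories: tuple[str, ...] = GENOTYPES
    probs: tuple[float, ...] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("mixing probabilities must be a valid simplex")

    @classmethod
    def from_data(cls, data: PKDataset) -> "MixtureSpec":
        """Observed genotype frequencies among genotyped subjects."""
        counts = {g: 0 for g in GENOTYPES}
        for s in data.subjects:
            if s.geno in counts:
                counts[s.geno] += 1
        tot = sum(counts.values())
        if tot == 0:
            raise ValueError("no genotyped subjects to derive mixing probabilities")
        return cls(GENOTYPES, tuple(counts[g] / tot for g in GENOTYPES))

    @classmethod
    def from_hwe(cls, maf: float) -> "MixtureSpec":
        q = maf
        return cls(GENOTYPES, ((1 - q) ** 2, 2 * q * (1 - q), q * q))


@dataclass
class PopPKModel:
    """Full population model: typicals, random effects, error, covariates."""

    theta: StructuralParams
    re: RandomEffectsSpec = field(default_factory=RandomEffectsSpec)
    error: ErrorModel = field(default_factory=ErrorModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    mixture: MixtureSpec | None = None

    def copy(self) -> "PopPKModel":
        return copy.deepcopy(self)


@dataclass
class FitResult:
    """Outcome of a population fit."""

    model: PopPKModel
    ofv: float
    converged: bool
    estimate: list[str]
    x: np.ndarray  # transformed-scale estimates, aligned with `estimate`
    n_evals: int
    message: str = ""
    ci: dict[str, tuple[float, float]] | None = None

    @property
    def estimates(self) -> dict[str, float]:
        return {n: _get_param(self.model, n) for n in self.estimate}


# ----------------------------------------------------- parameter accessors --

def _get_param(model: PopPKModel, name: str) -> float:
    if name in _STRUCT_NAMES:
        return getattr(model.theta, name)
    if name in ("prop_sd", "add_sd"):
        return getattr(model.error, name)
    if name.startswith("bsv_"):
        return model.re.bsv[name[4:]]
    if name.startswith("bov_"):
        return model.re.bov[name[4:]]
    if name == "geno_CT":
        return model.covariates.genotype_cl["C/T"]
    if name == "geno_TT":
        return model.covariates.genotype_cl["T/T"]
    if name.startswith("cov_"):
        for e in model.covariates.effects:
            if e.label == name:
                return e.theta
    raise KeyError(name)


def _set_param(model: PopPKModel, name: str, value: float) -> None:
    if name in _STRUCT_NAMES:
        model.theta = replace(model.theta, **{name: value})
    elif name in ("prop_sd", "add_sd"):
        setattr(model.error, name, value)
    elif name.startswith("bsv_"):
        model.re.bsv[name[4:]] = value
    elif name.startswith("bov_"):
        model.re.bov[name[4:]] = value
    elif name == "geno_CT":
        model.covariates.genotype_cl["C/T"] = value
    elif name == "geno_TT":
        model.covariates.genotype_cl["T/T"] = value
    elif name.startswith("cov_"):
        for e in model.covariates.effects:
            if e.label == name:
                e.theta = value
                return
        raise KeyError(name)
    else:
        raise KeyError(name)


def _is_log_scale(name: str) -> bool:
    """All positive-constrained quantities are estimated on the log scale."""
    return not name.startswith("cov_")


def _to_x(model: PopPKModel, names: list[str]) -> np.ndarray:
    return np.array(
        [
            math.log(_get_param(model, n)) if _is_log_scale(n) else _get_param(model, n)
            for n in names
        ]
    )


def _from_x(template: PopPKModel, names: list[str], x: np.ndarray) -> PopPKModel:
    m = template.copy()
    for n, v in zip(names, x):
        _set_param(m, n, math.exp(v) if _is_log_scale(n) else float(v))
    return m


# -------------------------------------------------- individual likelihoods --

def _covariate_value(subj: Subject, cov: str) -> float:
    if cov == "SEX":
        return float(subj.sex)
    if cov == "ARM":
        return float(subj.arm)
    if cov == "AGE":
        return float(subj.age)
    raise ValueError(f"unknown covariate {cov!r}")


def _dims(model: PopPKModel, subj: Subject) -> list[tuple[str, str, int]]:
    """Random-effect dimensions for a subject: (kind, parameter, occasion)."""
    d = [("bsv", p, -1) for p in sorted(model.re.bsv) if model.re.bsv[p] > 0]
    for p in sorted(model.re.bov):
        if model.re.bov[p] > 0:
            d.extend(("bov", p, int(o)) for o in subj.occasions)
    return d


def _individual_pars(model: PopPKModel, subj: Subject, geno: str) -> dict[str, float]:
    """Covariate-scaled individual parameters before any random effects."""
    th = model.theta
    pars = {n: getattr(th, n) for n in _STRUCT_NAMES}
    cov = model.covariates
    if cov.allometry:
        f = subj.ffm / cov.ref_ffm
        pars["CL"] *= f**ALLO_EXP_CL
        pars["Q"] *= f**ALLO_EXP_CL
        pars["Vc"] *= f**ALLO_EXP_V
        pars["Vp"] *= f**ALLO_EXP_V
    pars["CL"] *= cov.cl_multiplier(geno)
    for e in cov.effects:
        mult = 1.0 + e.theta * (_covariate_value(subj, e.covariate) - e.center)
        pars[e.parameter] *= max(mult, 1e-6)
    return pars


def _predict_subject(
    model: PopPKModel,
    subj: Subject,
    geno: str,
    dims: list[tuple[str, str, int]],
    eta: np.ndarray,
) -> np.ndarray:
    th = model.theta
    pars = _individual_pars(model, subj, geno)
    occ_mult: dict[int, dict[str, float]] = {}
    for (kind, p, occ), v in zip(dims, eta):
        if kind == "bsv":
            pars[p] *= math.exp(v)
        else:
            occ_mult.setdefault(occ, {}).setdefault(p, 1.0)
            occ_mult[occ][p] *= math.exp(v)

    pred = np.zeros(subj.obs_times.shape[0])
    if subj.obs_times.size == 0:
        return pred
    for occ, d_times, d_amts in subj.dose_groups:
        om = occ_mult.get(occ, {})
        pred += _profile(
            subj.obs_times,
            d_times,
            d_amts,
            pars["CL"], pars["Vc"], pars["Vp"], pars["Q"],
            pars["MTT"] * om.get("MTT", 1.0),
            pars["ka"] * om.get("ka", 1.0),
            pars["F"] * om.get("F", 1.0),
            int(th.NN),
        )
    return pred


def _residual_neg2ll(dv: np.ndarray, pred: np.ndarray, error: ErrorModel) -> float:
    v = (error.prop_sd * pred) ** 2 + error.add_sd**2
    return float(np.sum(np.log(2.0 * np.pi * v) + (dv - pred) ** 2 / v))


def individual_neg2ll(
    model: PopPKModel,
    subj: Subject,
    geno: str = "C/C",
    etas: dict[str, float] | None = None,
    kappas: dict[tuple[str, int], float] | None = None,
) -> float:
    """-2 log residual likelihood of a subject at given random effects.

    Gaussian residuals with var = (prop_sd*pred)^2 + add_sd^2, including
    the 2*pi constants.  The random-effect prior is *not* included here.
    """
    dims = _dims(model, subj)
    eta = np.zeros(len(dims))
    for i, (kind, p, occ) in enumerate(dims):
        if kind == "bsv" and etas:
            eta[i] = etas.get(p, 0.0)
        elif kind == "bov" and kappas:
            eta[i] = kappas.get((p, occ), 0.0)
    pred = _predict_subject(model, subj, geno, dims, eta)
    if not np.all(np.isfinite(pred)):
        return math.inf
    return _residual_neg2ll(subj.obs_dv, pred, model.error)


def _joint_neg2ll(
    model: PopPKModel,
    subj: Subject,
    geno: str,
    dims: list[tuple[str, str, int]],
    eta: np.ndarray,
) -> float:
    """Conditional -2 log-likelihood plus -2 log random-effect prior."""
    pred = _predict_subject(model, subj, geno, dims, eta)
    if not np.all(np.isfinite(pred)):
        return math.inf
    g = _residual_neg2ll(subj.obs_dv, pred, model.error)
    for (kind, p, _), v in zip(dims, eta):
        var = model.re.bsv[p] if kind == "bsv" else model.re.bov[p]
        g += v * v / var + math.log(2.0 * math.pi * var)
    return g


def _laplace_component(
    model: PopPKModel,
    subj: Subject,
    geno: str,
    warm: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Laplace -2 log marginal likelihood for one subject/genotype component.

    Returns (neg2ll, eta_hat).  With no active random effects this is the
    conditional -2 log-likelihood at eta = 0 (degenerate hierarchy).
    """
    dims = _dims(model, subj)
    d = len(dims)
    if d == 0 or subj.obs_times.size == 0:
        eta0 = np.zeros(d)
        if subj.obs_times.size == 0:
            # no data: marginal likelihood integrates to 1
            return 0.0, eta0
        return _joint_neg2ll(model, subj, geno, dims, eta0), eta0

    g = lambda e: _joint_neg2ll(model, subj, geno, dims, e)

    if d == 1 and dims[0] == ("bsv", "CL", -1):
        # fused kernel: scalar CL effect, occasion-independent absorption
        pars = _individual_pars(model, subj, geno)
        n2, xh = _laplace1(
            subj.obs_times, subj.obs_dv, subj.dose_times, subj.dose_amts,
            pars["CL"], pars["Vc"], pars["Vp"], pars["Q"], pars["MTT"],
            pars["ka"], pars["F"], int(model.theta.NN),
            model.error.prop_sd, model.error.add_sd, model.re.bsv["CL"],
            float(warm[0]) if warm is not None and warm.size == 1 else 0.0,
        )
        return float(n2), np.array([xh])

    if d == 1:
        var = (
            model.re.bsv[dims[0][1]] if dims[0][0] == "bsv" else model.re.bov[dims[0][1]]
        )
        x = float(warm[0]) if warm is not None and warm.size == 1 else 0.0
        h = 1e-4
        g0 = g(np.array([x]))
        if not math.isfinite(g0):
            x, g0 = 0.0, g(np.array([0.0]))
        for _ in range(50):
            gp = g(np.array([x + h]))
            gm = g(np.array([x - h]))
            d1 = (gp - gm) / (2 * h)
            d2 = (gp - 2 * g0 + gm) / (h * h)
            if not (math.isfinite(d1) and math.isfinite(d2)) or d2 <= 0:
                break
            step = d1 / d2
            step = max(min(step, 2.0), -2.0)
            xn = x - step
            gn = g(np.array([xn]))
            if gn <= g0 + 1e-12:
                x, g0 = xn, gn
                if abs(step) < 1e-8:
                    break
            else:
                # damped retry
                xn = x - 0.25 * step
                gn = g(np.array([xn]))
                if gn <= g0:
                    x, g0 = xn, gn
                else:
                    break
        else:  # pragma: no cover
            pass
        # verify curvature at the mode; fall back to a bounded scalar search
        gp = g(np.array([x + h]))
        gm = g(np.array([x - h]))
        d2 = (gp - 2 * g0 + gm) / (h * h)
        if d2 <= 0 or min(gp, gm) < g0 - 1e-9:
            sd = math.sqrt(var)
            res = optimize.minimize_scalar(
                lambda e: g(np.array([e])), bounds=(-6 * sd, 6 * sd), method="bounded",
                options={"xatol": 1e-8},
            )
            x, g0 = float(res.x), float(res.fun)
            gp = g(np.array([x + h]))
            gm = g(np.array([x - h]))
            d2 = (gp - 2 * g0 + gm) / (h * h)
            if d2 <= 0:
                d2 = 2.0 / var  # prior curvature fallback
        return g0 + math.log(d2 / (4.0 * math.pi)), np.array([x])

    # multi-dimensional inner problem (BSV + BOV): quasi-Newton + numeric Hessian
    x0 = warm if warm is not None and warm.size == d else np.zeros(d)
    res = optimize.minimize(g, x0, method="BFGS", options={"gtol": 1e-5, "maxiter": 200})
    if np.any(x0 != 0) and not res.success:
        res2 = optimize.minimize(g, np.zeros(d), method="BFGS", options={"gtol": 1e-5, "maxiter": 200})
        if res2.fun < res.fun:
            res = res2
    xh, g0 = res.x, float(res.fun)
    h = 1e-3
    H = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                g(xh + ei + ej) - g(xh + ei - ej) - g(xh - ei + ej) + g(xh - ei - ej)
            ) / (4 * h * h)
    sign, logdet = np.linalg.slogdet(H / 2.0)
    if sign <= 0:
        H = np.diag([2.0 / (model.re.bsv.get(p, 0) or model.re.bov.get(p, 1)) for _, p, _ in dims])
        _, logdet = np.linalg.slogdet(H / 2.0)
    return g0 + logdet - d * _LOG2PI, xh


def mixture_marginal_neg2ll(
    model: PopPKModel,
    subj: Subject,
    mixture: MixtureSpec | None = None,
    warm: dict[str, np.ndarray] | None = None,
) -> tuple[float, dict[str, float]]:
    """Marginal -2 log-likelihood over unobserved genotype, with posteriors.

    L = sum_g p_g L_g, accumulated by log-sum-exp; returns the -2 log of
    the sum and the posterior probability of each genotype category.
    """
    mix = mixture or model.mixture
    if mix is None:
        raise ValueError("no mixture specification available")
    logl = np.empty(len(mix.categories))
    etas = {}
    for i, g in enumerate(mix.categories):
        n2, eh = _laplace_component(model, subj, g, warm.get(g) if warm else None)
        logl[i] = -0.5 * n2
        etas[g] = eh
    logp = np.log(np.maximum(np.asarray(mix.probs, float), 1e-300))
    tot = logsumexp(logp + logl)
    post = np.exp(logp + logl - tot)
    return -2.0 * tot, dict(zip(mix.categories, post))


def _subject_marginal(
    model: PopPKModel, subj: Subject, warm: dict | None, key: object
) -> float:
    has_geno_model = model.covariates.genotype_cl is not None
    if has_geno_model and subj.geno is None:
        if model.mixture is None:
            raise ValueError(
                f"subject {subj.id} has no genotype and the model has no mixture"
            )
        w = warm.get(key, {}) if warm is not None else None
        mix = model.mixture
        logl = np.empty(len(mix.categories))
        for i, g in enumerate(mix.categories):
            n2, eh = _laplace_component(model, subj, g, w.get(g) if w else None)
            logl[i] = -0.5 * n2
            if warm is not None:
                warm.setdefault(key, {})[g] = eh
        logp = np.log(np.maximum(np.asarray(mix.probs, float), 1e-300))
        return -2.0 * float(logsumexp(logp + logl))
    geno = subj.geno if (has_geno_model and subj.geno) else "C/C"
    w = warm.get(key) if warm is not None else None
    n2, eh = _laplace_component(model, subj, geno, w)
    if warm is not None:
        warm[key] = eh
    return n2


def ofv(model: PopPKModel, data: PKDataset, _warm: dict | None = None) -> float:
    """Objective function value: -2 log marginal likelihood (Laplace sum)."""
    total = 0.0
    for si, subj in enumerate(data.subjects):
        n2 = _subject_marginal(model, subj, _warm, si)
        if not math.isfinite(n2):
            return math.inf
        total += n2
    return total


# ---------------------------------------------------------------- fitting --

def fit(
    model: PopPKModel,
    data: PKDataset,
    estimate: list[str],
    init: dict[str, float] | None = None,
    seed: int = 0,
    maxiter: int | None = None,
    multi_start: int = 0,
    fatol: float = 1e-4,
    xatol: float = 1e-5,
) -> FitResult:
    """Maximum-likelihood population fit by Nelder-Mead over log parameters.

    ``estimate`` names the free parameters (e.g. ["CL", "Vc", "bsv_CL",
    "prop_sd"]); everything else is fixed at the template model's values.
    Deterministic given data, init and seed; ``multi_start`` adds seeded
    perturbed restarts for robustness.
    """
    if data.n_subjects < 2:
        raise ValueError("fitting requires at least 2 subjects")
    template = model.copy()
    if init:
        for n, v in init.items():
            _set_param(template, n, v)
    x0 = _to_x(template, estimate)
    warm: dict = {}
    n_evals = [0]

    def obj(x):
        n_evals[0] += 1
        if np.any(np.abs(x) > 12):
            return 1e12
        m = _from_x(template, estimate, x)
        try:
            v = ofv(m, data, _warm=warm)
        except (ValueError, FloatingPointError):
            return 1e12
        return v if math.isfinite(v) else 1e12

    rng = np.random.default_rng(seed)
    starts = [x0] + [
        x0 + rng.normal(0, 0.3, size=x0.size) for _ in range(multi_start)
    ]
    best = None
    for s in starts:
        res = optimize.minimize(
            obj,
            s,
            method="Nelder-Mead",
            options={
                "xatol": xatol,
                "fatol": fatol,
                "maxiter": maxiter or 400 * len(estimate),
                "adaptive": True,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    final = _from_x(template, estimate, best.x)
    return FitResult(
        model=final,
        ofv=float(best.fun),
        converged=bool(best.success),
        estimate=list(estimate),
        x=np.asarray(best.x),
        n_evals=n_evals[0],
        message=str(best.message),
    )


def lrt(ofv_reduced: float, ofv_full: float, df: int) -> float:
    """Likelihood-ratio test p-value: 1 - chi2_df CDF of the OFV decrease.

    A decrease of 3.84 at df=1 corresponds to P = 0.05.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if ofv_reduced < ofv_full - 0.1:
        raise ValueError("reduced model cannot beat the full model beyond tolerance")
    delta = max(ofv_reduced - ofv_full, 0.0)
    return float(stats.chi2.sf(delta, df))


def covariate_search(
    model: PopPKModel,
    data: PKDataset,
    candidates: list[tuple[str, str]],
    estimate: list[str],
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.01,
    **fit_kwargs,
) -> tuple[PopPKModel, list[dict]]:
    """Stepwise forward inclusion (P < 0.05) + backward elimination (P < 0.01).

    ``candidates`` are (parameter, covariate) pairs, each contributing one
    proportional-shift parameter (df = 1).  Returns the selected model and
    an audit trail recording every tested step with its delta-OFV.
    """
    audit: list[dict] = []

    def fit_with(effects: list[CovariateEffect]) -> FitResult:
        m = model.copy()
        m.covariates.effects = [copy.deepcopy(e) for e in effects]
        names = estimate + [e.label for e in m.covariates.effects]
        return fit(m, data, names, **fit_kwargs)

    current: list[CovariateEffect] = []
    base = fit_with(current)
    # forward
    remaining = list(candidates)
    while remaining:
        trials = []
        for par, cov in remaining:
            eff = CovariateEffect(par, cov)
            r = fit_with(current + [eff])
            p = lrt(base.ofv, min(r.ofv, base.ofv), 1)
            trials.append((r.ofv - base.ofv, p, (par, cov), r))
            audit.append(
                {"step": "forward", "candidate": (par, cov),
                 "dofv": r.ofv - base.ofv, "p": p, "included": False}
            )
        trials.sort(key=lambda t: t[0])
        dofv, p, cand, r = trials[0]
        if p < forward_alpha:
            current.append(
                CovariateEffect(*cand, theta=r.model.covariates.effects[-1].theta)
            )
            audit.append(
                {"step": "forward-select", "candidate": cand, "dofv": dofv, "p": p,
                 "included": True}
            )
            base = r
            remaining.remove(cand)
        else:
            break
    # backward
    crit = stats.chi2.ppf(1 - backward_alpha, 1)
    changed = True
    while changed and current:
        changed = False
        for eff in list(current):
            rest = [e for e in current if e is not eff]
            r = fit_with(rest)
            dofv = r.ofv - base.ofv  # worsening when removing
            keep = dofv > crit
            audit.append(
                {"step": "backward", "candidate": (eff.parameter, eff.covariate),
                 "dofv": dofv, "removed": not keep}
            )
            if not keep:
                current = rest
                base = r
                changed = True
                break
    selected = model.copy()
    selected.covariates.effects = current
    return base.model if current else selected, audit


# -------------------------------------------------------------------- SIR --

def _sir_core(
    neg2ll_fn,
    x_mode: np.ndarray,
    cov: np.ndarray,
    n_samples: int,
    n_resamples: int,
    seed: int,
) -> np.ndarray:
    """Sampling-importance resampling draws around a mode.

    Proposal: multivariate normal at the mode with the given covariance;
    importance weights proportional to likelihood / proposal density;
    resampling without replacement.  Returns the resampled draws
    (n_resamples x dim).
    """
    rng = np.random.default_rng(seed)
    d = x_mode.size
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-8)) * 2.0)
    xs = x_mode + rng.standard_normal((n_samples, d)) @ chol.T
    n2 = np.array([neg2ll_fn(x) for x in xs])
    n2 = np.where(np.isfinite(n2), n2, np.inf)
    cinv = np.linalg.inv(chol @ chol.T)
    dx = xs - x_mode
    log_q = -0.5 * np.einsum("ij,jk,ik->i", dx, cinv, dx)
    log_w = -0.5 * (n2 - n2.min()) - log_q
    log_w -= logsumexp(log_w)
    w = np.exp(log_w)
    k = min(n_resamples, n_samples)
    # weighted sampling without replacement (Efraimidis-Spirakis keys)
    keys = rng.random(n_samples) ** (1.0 / np.maximum(w, 1e-300))
    idx = np.argsort(-keys)[:k]
    return xs[idx]


def sir_ci(
    fit_result: FitResult,
    data: PKDataset,
    n_samples: int = 500,
    n_resamples: int = 100,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """95% confidence intervals by sampling-importance resampling.

    Draws transformed parameter vectors from a normal proposal at the
    mode (covariance from the numeric OFV Hessian, inflated diagonal
    fallback when degenerate), weights them by likelihood, resamples
    without replacement and reports per-parameter 2.5/97.5 percentiles
    on the natural scale.  Seeded and reproducible.
    """
    names = fit_result.estimate
    template = fit_result.model.copy()
    warm: dict = {}

    def n2(x):
        try:
            return ofv(_from_x(template, names, x), data, _warm=warm)
        except (ValueError, FloatingPointError):
            return math.inf

    x0 = fit_result.x
    d = x0.size
    h = 1e-3
    H = np.zeros((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                n2(x0 + ei + ej) - n2(x0 + ei - ej) - n2(x0 - ei + ej) + n2(x0 - ei - ej)
            ) / (4 * h * h)
    H /= 2.0  # curvature of -log L
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.diag(np.full(d, 0.05))  # inflated diagonal fallback
    draws = _sir_core(n2, x0, cov, n_samples, n_resamples, seed)
    out = {}
    for i, n in enumerate(names):
        col = draws[:, i]
        nat = np.exp(col) if _is_log_scale(n) else col
        lo, hi = np.percentile(nat, [2.5, 97.5])
        out[n] = (float(lo), float(hi))
    return out
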