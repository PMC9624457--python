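"""Synthetic study generator.

Emulates the statistical structure of a dolutegravir pharmacogenetic
study: a small intensively sampled group (7 samples at pre-dose, 1, 2,
4, 6, 8 and 24 h after an observed steady-state 50 mg dose), a larger
sparsely sampled group (1-2 samples), ~40% of subjects without genotype
data, genotypes in Hardy-Weinberg equilibrium at configurable minor
allele frequencies with configurable pairwise LD, log-normal
between-subject/between-occasion variability, combined residual error
with BLQ flagging, and a genotype-driven log10 bilirubin phenotype.

Every generator is bit-reproducible under a fixed seed and writes the
same formats the analysis pipeline reads, so it is the fixture factory
for all tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PKDataset
from .genetics import GenotypeMatrix
from .nlme import ErrorModel, GENOTYPES, PopPKModel, RandomEffectsSpec
from .pk import StructuralParams, compute_ffm

__all__ = [
    "SimulationDesign",
    "VariantTruth",
    "LDPair",
    "GeneticTruth",
    "default_truth_model",
    "genotype_truth_model",
    "default_genetic_truth",
    "simulate_subjects",
    "simulate_genotypes",
    "genotype_categories",
    "simulate_pk",
    "simulate_bilirubin",
    "generate_study",
]


@dataclass
class SimulationDesign:
    """Sampling design of the emulated study."""

    n_intensive: int = 41
    n_sparse: int = 431
    sparse_samples_per_subject: tuple[int, int] = (1, 2)  # inclusive range
    intensive_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0)
    dose: float = 50.0  # mg once daily
    interval: float = 24.0  # h
    n_run_in_doses: int = 15  # doses before sampling (steady state)
    fraction_ungenotyped: float = 0.40

    def __post_init__(self) -> None:
        if min(self.n_intensive, self.n_sparse) < 0:
            raise ValueError("subject counts must be >= 0")
        if any(t < 0 or t > self.interval for t in self.intensive_times):
            raise ValueError("intensive times must lie within one dosing interval")
        if not 0 <= self.fraction_ungenotyped <= 1:
            raise ValueError("fraction_ungenotyped must be in [0, 1]")


@dataclass
class VariantTruth:
    """One simulated variant: position, MAF and its bilirubin effect."""

    id: str
    chrom: str = "2"
    pos: int = 0
    maf: float = 0.2
    bili_beta: float = 0.0  # per-allele effect on log10 bilirubin
    imputation_r2: float = 0.99
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.maf <= 0.5:
            raise ValueError("MAF must be in [0, 0.5]")


@dataclass
class LDPair:
    """Target LD between an anchor variant and a dependent variant."""

    anchor: str
    partner: str
    r2: float

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1:
            raise ValueError("target r2 must be in [0, 1]")


@dataclass
class GeneticTruth:
    """Ground truth of the simulated genetics."""

    variants: list[VariantTruth]
    ld_pairs: list[LDPair] = field(default_factory=list)
    causal_variant: str = "rs887829_sim"
    cl_multipliers: dict[str, float] = field(
        default_factory=lambda: {"C/T": 0.892, "T/T": 0.741}
    )


def default_truth_model() -> PopPKModel:
    """Simulation truth for the no-genetics population model.

    Typical CL/Vc/Vp are the final-model estimates at 47 kg fat-free
    mass; Q, MTT, ka and NN are package defaults (declared configuration,
    not literature estimates); variances are plausible for an
    intensively sampled once-daily oral drug.
    """
    return PopPKModel(
        theta=StructuralParams(CL=0.732, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, F=1.0, NN=4),
        re=RandomEffectsSpec(
            bsv={"CL": 0.09},  # ~30% CV
            bov={"MTT": 0.09, "ka": 0.09, "F": 0.0225},  # ~30/30/15% CV
        ),
        error=ErrorModel(prop_sd=0.10, add_sd=0.006, lloq=0.030),
    )


def genotype_truth_model() -> PopPKModel:
    """Simulation truth with the genotype effect on clearance.

    C/C reference clearance 0.78 L/h with fractional multipliers 0.892
    (C/T, a 10.8% decrease) and 0.741 (T/T, a 25.9% decrease).
    """
    m = default_truth_model()
    m.theta = StructuralParams(CL=0.78, Vc=12.2, Vp=5.87, Q=1.5, MTT=1.8, ka=1.2, F=1.0, NN=4)
    m.covariates.genotype_cl = {"C/T": 0.892, "T/T": 0.741}
    return m


def default_genetic_truth(n_background: int = 150) -> GeneticTruth:
    """A compact UGT1A-like locus plus an unlinked background panel.

    The causal surrogate sits at MAF 0.41 with a +0.12 per-allele effect
    on log10 bilirubin; a second, rarer variant carries an independent
    -0.11 bilirubin effect; LD partners at r2 0.5/0.3/0.2 plus
    independent null variants complete the locus.  ``n_background``
    unlinked common variants on other chromosomes stand in for the
    genome-wide panel from which ancestry principal components are
    computed — without them, PCs derived from the locus alone would be
    dominated by the causal LD block and absorb the association signal.
    """
    variants = [
        VariantTruth("rs887829_sim", "2", 234_668_570, 0.41, bili_beta=0.12),
        VariantTruth("rs28899168_sim", "2", 234_602_202, 0.15, bili_beta=-0.11),
        VariantTruth("partner_r2_50", "2", 234_660_000, 0.41),
        VariantTruth("partner_r2_30", "2", 234_650_000, 0.35),
        VariantTruth("partner_r2_20", "2", 234_640_000, 0.30),
    ] + [
        VariantTruth(f"null_{i}", "2", 234_600_000 + 1000 * i, 0.10 + 0.02 * i)
        for i in range(15)
    ] + [
        VariantTruth(
            f"bg_{i}", str(1 + (i % 20) if (1 + i % 20) != 2 else 22),
            1_000_000 + 10_000 * i, 0.10 + 0.38 * ((i * 7) % 11) / 11,
        )
        for i in range(n_background)
    ]
    pairs = [
        LDPair("rs887829_sim", "partner_r2_50", 0.5),
        LDPair("rs887829_sim", "partner_r2_30", 0.3),
        LDPair("rs887829_sim", "partner_r2_20", 0.2),
    ]
    return GeneticTruth(variants=variants, ld_pairs=pairs)


# ------------------------------------------------------------- generators --

def simulate_subjects(n: int, seed: int = 0) -> pd.DataFrame:
    """Demographics: sex, weight, height, age, fat-free mass.

    Sex is Bernoulli(0.62 female); weight is log-normal calibrated to a
    73.1 kg median with an interquartile range near (67.2, 85.2); heights
    are plausible adult values by sex (scaffolding: only FFM enters the
    model); ages are log-normal with median 31 years.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sex = (rng.random(n) < 0.62).astype(int)  # 1 = female
    weight = np.exp(rng.normal(math.log(73.1), 0.176, n))
    height = np.where(
        sex == 1, rng.normal(1.59, 0.06, n), rng.normal(1.69, 0.07, n)
    ).clip(1.40, 2.05)
    age = np.exp(rng.normal(math.log(31.0), 0.16, n)).clip(18, 70)
    ffm = np.array(
        [
            compute_ffm(w, h, "female" if s == 1 else "male")
            for w, h, s in zip(weight, height, sex)
        ]
    )
    return pd.DataFrame(
        {
            "ID": np.arange(1, n + 1),
            "SEX": sex,
            "WT": np.round(weight, 2),
            "HT": np.round(height, 3),
            "AGE": np.round(age, 1),
            "FFM": np.round(ffm, 2),
            "ARM": (rng.random(n) < 0.5).astype(int),
        }
    ).set_index("ID")


def _max_r2(pa: float, pb: float) -> float:
    """Largest achievable r^2 for positively associated alleles."""
    qa, qb = 1 - pa, 1 - pb
    dmax = min(pa * qb, qa * pb)
    return dmax**2 / (pa * qa * pb * qb)


def simulate_genotypes(n: int, truth: GeneticTruth, seed: int = 0) -> GenotypeMatrix:
    """Genotypes in HWE at the stated MAFs with target pairwise LD.

    LD partners are generated from two-locus haplotypes: the partner's
    conditional allele probability given the anchor haplotype is set so
    that the haplotype disequilibrium D hits the target r^2 (positive
    D).  Infeasible targets (r^2 above the bound implied by the two
    MAFs) are rejected with the feasible bound reported.
    """
    rng = np.random.default_rng(seed)
    by_id = {v.id: v for v in truth.variants}
    partner_of = {p.partner: p for p in truth.ld_pairs}
    for p in truth.ld_pairs:
        pa, pb = by_id[p.anchor].maf, by_id[p.partner].maf
        if pa > 0 and pb > 0 and p.r2 > _max_r2(pa, pb) + 1e-12:
            raise ValueError(
                f"target r2={p.r2} infeasible for MAFs ({pa}, {pb}); "
                f"feasible bound is {_max_r2(pa, pb):.4f}"
            )

    haps: dict[str, np.ndarray] = {}
    # anchors and independent variants first, then partners conditionally
    for v in truth.variants:
        if v.id in partner_of:
            continue
        haps[v.id] = (rng.random((n, 2)) < v.maf).astype(float)
    for p in truth.ld_pairs:
        va, vb = by_id[p.anchor], by_id[p.partner]
        pa, pb = va.maf, vb.maf
        if p.r2 == 0 or pa == 0 or pb == 0:
            haps[vb.id] = (rng.random((n, 2)) < pb).astype(float)
            continue
        d = math.sqrt(p.r2 * pa * (1 - pa) * pb * (1 - pb))
        p1 = pb + d / pa  # P(partner allele | anchor allele)
        p0 = pb - d / (1 - pa)
        a = haps[va.id]
        cond = np.where(a > 0, p1, p0)
        haps[vb.id] = (rng.random((n, 2)) < cond).astype(float)

    cols = {}
    for v in truth.variants:
        dos = haps[v.id].sum(axis=1)
        if v.call_rate < 1.0:
            dos = dos.astype(float)
            dos[rng.random(n) >= v.call_rate] = np.nan
        cols[v.id] = dos
    dosage = pd.DataFrame(cols, index=pd.RangeIndex(1, n + 1, name="sample_id"))
    variants = pd.DataFrame(
        [(v.chrom, v.pos, "C", "T", v.imputation_r2) for v in truth.variants],
        index=[v.id for v in truth.variants],
        columns=["chrom", "pos", "ref", "alt", "imputation_r2"],
    )
    return GenotypeMatrix(dosage, variants)


def genotype_categories(g: GenotypeMatrix, variant: str) -> pd.Series:
    """Map a variant's rounded dosage to C/C, C/T, T/T categories."""
    d = g.dosage[variant].round()
    return d.map({0.0: "C/C", 1.0: "C/T", 2.0: "T/T"})


def simulate_pk(
    design: SimulationDesign,
    model: PopPKModel,
    subjects: pd.DataFrame,
    geno: pd.Series | None = None,
    seed: int = 0,
    geno_masked: pd.Series | None = None,
) -> PKDataset:
    """Forward-simulate concentrations under the population model.

    Subjects get log-normal eta/kappa draws, individual parameters
    through allometry and (when the model carries one) the genotype CL
    multiplier, a steady-state run-in of once-daily doses, and
    observations with combined residual error.  Values below the LLOQ
    are flagged BLQ.  ``geno`` maps subject id to the *true* genotype
    category driving the kinetics; subjects flagged in ``geno_masked``
    (or absent from ``geno``) get an empty GENO column — their kinetics
    still follow their true genotype, only its record is withheld.
    """
    rng = np.random.default_rng(seed)
    n = len(subjects)
    if design.n_intensive + design.n_sparse != n:
        raise ValueError("design subject counts must match the covariate table")
    from .nlme import _dims, _predict_subject  # shared parameterization
    from .data import Subject

    lo, hi = design.sparse_samples_per_subject
    rows = []
    last_dose = (design.n_run_in_doses - 1) * design.interval
    for i, (sid, cov) in enumerate(subjects.iterrows()):
        intensive = i < design.n_intensive
        g = geno.get(sid) if geno is not None else None
        g = g if isinstance(g, str) and g in GENOTYPES else None
        eta_cl = rng.normal(0, math.sqrt(model.re.bsv.get("CL", 0.0)))
        kap = {
            p: rng.normal(0, math.sqrt(v)) for p, v in model.re.bov.items() if v > 0
        }
        dose_times = np.arange(design.n_run_in_doses) * design.interval
        if intensive:
            rel = np.array(design.intensive_times, float)
        else:
            k = int(rng.integers(lo, hi + 1))
            rel = np.sort(rng.uniform(0.5, design.interval, k))
        obs_times = last_dose + rel
        subj = Subject(
            id=sid,
            ffm=float(cov["FFM"]),
            sex=int(cov["SEX"]),
            arm=int(cov["ARM"]),
            age=float(cov["AGE"]),
            geno=g,
            dose_times=dose_times,
            dose_amts=np.full(dose_times.size, design.dose),
            dose_occ=np.zeros(dose_times.size, dtype=int),
            obs_times=obs_times,
            obs_dv=np.zeros(obs_times.size),
            obs_occ=np.zeros(obs_times.size, dtype=int),
        )
        dims = _dims(model, subj)
        eta = np.array(
            [
                eta_cl if (kind == "bsv" and p == "CL") else kap.get(p, 0.0)
                for (kind, p, _) in dims
            ]
        )
        pred = _predict_subject(model, subj, g or "C/C", dims, eta)
        dv = pred * (1 + model.error.prop_sd * rng.standard_normal(pred.size))
        dv = dv + model.error.add_sd * rng.standard_normal(pred.size)
        dv = np.maximum(dv, 0.0)
        blq = (dv < model.error.lloq).astype(int)
        observed = g if not (geno_masked is not None and bool(geno_masked.get(sid, False))) else None
        common = dict(
            WT=cov["WT"], HT=cov["HT"], SEX=int(cov["SEX"]), ARM=int(cov["ARM"]),
            AGE=cov["AGE"], GENO=observed or "",
        )
        for t, a in zip(dose_times, subj.dose_amts):
            rows.append(dict(ID=sid, TIME=t, DV=np.nan, AMT=a, EVID=1, OCC=0, MDV=1, BLQ=0, **common))
        for t, y, b in zip(obs_times, dv, blq):
            rows.append(dict(ID=sid, TIME=t, DV=round(float(y), 5), AMT=0.0, EVID=0, OCC=0, MDV=0, BLQ=int(b), **common))
    return PKDataset(pd.DataFrame(rows))


def simulate_bilirubin(
    g: GenotypeMatrix,
    truth: GeneticTruth,
    seed: int = 0,
    intercept: float = 0.9,
    noise_sd: float = 0.20,
) -> pd.Series:
    """log10 bilirubin = intercept + sum(beta_v * dosage_v) + N(0, noise_sd).

    Default per-allele effects: +0.12 for the rs887829 surrogate and
    -0.11 for the rs28899168 surrogate; noise_sd 0.20 puts the primary
    association at study-scale significance for n ~ 284.
    """
    rng = np.random.default_rng(seed)
    y = np.full(len(g.samples), intercept)
    for v in truth.variants:
        if v.bili_beta != 0.0 and v.id in g.dosage.columns:
            y = y + v.bili_beta * np.nan_to_num(g.dosage[v.id].to_numpy(float))
    y = y + rng.normal(0, noise_sd, len(y))
    return pd.Series(y, index=g.samples, name="log10_bilirubin")


def generate_study(
    design: SimulationDesign,
    model: PopPKModel,
    gtruth: GeneticTruth,
    seed: int = 0,
) -> dict:
    """Full synthetic study: PK dataset, genotypes, bilirubin, subjects.

    Genotypes are simulated for every subject; the configured fraction is
    then masked — masked subjects have an empty GENO in the PK data and
    are absent from the exported genotype matrix, exactly like subjects
    who never consented to genotyping.
    """
    rng = np.random.default_rng(seed)
    n = design.n_intensive + design.n_sparse
    subjects = simulate_subjects(n, seed=int(rng.integers(2**31)))
    geno_all = simulate_genotypes(n, gtruth, seed=int(rng.integers(2**31)))
    categories = genotype_categories(geno_all, gtruth.causal_variant)
    if model.covariates.genotype_cl is not None:
        model = model.copy()
        model.covariates.genotype_cl = dict(gtruth.cl_multipliers)
    masked = pd.Series(rng.random(n) < design.fraction_ungenotyped, index=subjects.index)
    pkdata = simulate_pk(
        design, model, subjects, categories, seed=int(rng.integers(2**31)),
        geno_masked=masked,
    )
    keep = geno_all.samples[~masked.to_numpy()]
    geno_obs = GenotypeMatrix(
        geno_all.dosage.loc[keep],
        geno_all.variants[["chrom", "pos", "ref", "alt", "imputation_r2"]],
    )
    bili = simulate_bilirubin(geno_obs, gtruth, seed=int(rng.integers(2**31)))
    return {
        "pk": pkdata,
        "genotypes": geno_obs,
        "bilirubin": bili,
        "subjects": subjects,
        "true_categories": categories,
        "masked": masked.rename("masked"),
    }
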