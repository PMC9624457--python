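"""End-to-end orchestration of the two-stage analysis.

Stages, in study order: (optional) synthetic-data generation -> genotype
QC -> base population fit -> empirical-Bayes phenotypes -> ancestry PCA
and additive association (with optional conditional locus scan) ->
genotype-covariate mixture fit -> genotype-stratified simulation bands
and VPC.  Every stage records its inputs, outputs and seeds in a JSON
manifest; any stage failure halts downstream stages with a structured
error while preserving partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetics, nlme, phenotypes, simvpc, synth
from .data import PKDataset

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the manifest records the stage and traceback."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Configuration of a pipeline run (a YAML/JSON-serializable record)."""

    output_dir: str = "poppkgx_run"
    seed: int = 1
    # inputs; left None when `simulate` is true
    pk_csv: str | None = None
    vcf: str | None = None
    bilirubin_csv: str | None = None
    simulate: bool = True
    design: synth.SimulationDesign = field(default_factory=synth.SimulationDesign)
    # model settings
    nn: int = 4
    estimate: tuple[str, ...] = ("CL", "Vc", "Vp", "bsv_CL", "prop_sd")
    genotype_fit: bool = True
    mixture: bool = True
    fit_maxiter: int | None = None
    # association settings
    family_m: int = 9
    pca_components: int = 2
    reference_snp: str = "rs887829_sim"
    conditioning_snp: str | None = "rs887829_sim"
    locus_chrom: str = "2"
    locus_center: int = 234_640_000
    locus_flank: int = 50_000
    # simulation / VPC settings
    vpc_n_sim: int = 100
    bands_n: int = 1200

    stages: tuple[str, ...] = (
        "simulate", "qc", "fit", "phenotypes", "association", "locus",
        "genotype_fit", "bands", "vpc",
    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        design = raw.pop("design", None)
        cfg = cls(**raw)
        if design:
            cfg.design = synth.SimulationDesign(**design)
        return cfg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "config": _jsonable(config),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }

    def record(stage: str, t0: float, **info):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 3), **_jsonable(info)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    def artifact(name: str, path: Path):
        manifest["artifacts"][name] = str(path)

    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.time()
            if stage == "simulate" and config.simulate:
                truth = synth.genotype_truth_model()
                study = synth.generate_study(
                    config.design, truth, synth.default_genetic_truth(), seed=config.seed
                )
                pk_path = out / "pk_data.csv"
                vcf_path = out / "genotypes.vcf"
                bili_path = out / "bilirubin.csv"
                study["pk"].to_csv(pk_path)
                study["genotypes"].to_vcf(vcf_path)
                study["bilirubin"].to_frame().to_csv(bili_path)
                config.pk_csv = str(pk_path)
                config.vcf = str(vcf_path)
                config.bilirubin_csv = str(bili_path)
                state["truth_causal"] = synth.default_genetic_truth().causal_variant
                artifact("pk_csv", pk_path)
                artifact("vcf", vcf_path)
                artifact("bilirubin_csv", bili_path)
                record(stage, t0, n_subjects=study["pk"].n_subjects)
            elif stage == "simulate":
                record(stage, t0, skipped=True)
            elif stage == "qc":
                g = genetics.GenotypeMatrix.from_vcf(config.vcf)
                g, report = genetics.qc_filter(g)
                state["genotypes"] = g
                report.to_csv(out / "qc_report.csv")
                artifact("qc_report", out / "qc_report.csv")
                record(stage, t0, n_variants=g.n_variants, excluded=int(report.loc["total_excluded", "any_failing"]))
            elif stage == "fit":
                data = PKDataset.from_csv(config.pk_csv)
                state["data"] = data
                base = synth.default_truth_model()
                base.re.bov = {}
                base.theta = dataclasses.replace(base.theta, NN=config.nn)
                res = nlme.fit(
                    base, data, list(config.estimate),
                    init={"CL": 1.0, "Vc": 15.0, "Vp": 4.0},
                    seed=config.seed, maxiter=config.fit_maxiter,
                )
                state["fit"] = res
                (out / "fit_base.json").write_text(
                    json.dumps({"ofv": res.ofv, "estimates": res.estimates,
                                "converged": res.converged}, indent=2)
                )
                artifact("fit_base", out / "fit_base.json")
                record(stage, t0, ofv=res.ofv, estimates=res.estimates)
            elif stage == "phenotypes":
                pheno = phenotypes.derive_phenotypes(state["fit"].model, state["data"])
                # genotype-side sample ids are VCF strings; align on str
                pheno.index = pheno.index.astype(str)
                if config.bilirubin_csv:
                    bili = pd.read_csv(config.bilirubin_csv, index_col=0)
                    bili.index = bili.index.astype(str)
                    pheno = pheno.join(bili, how="left")
                state["phenotypes"] = pheno
                pheno.to_csv(out / "phenotypes.csv")
                artifact("phenotypes", out / "phenotypes.csv")
                record(stage, t0, n=len(pheno))
            elif stage == "association":
                g = state["genotypes"]
                # ancestry PCs from the panel *excluding* the target locus:
                # in an LD block the top eigenvector is the block itself and
                # would absorb the association signal
                v = g.variants
                off_locus = v.index[
                    ~(
                        (v["chrom"].astype(str) == str(config.locus_chrom))
                        & (v["pos"] >= config.locus_center - config.locus_flank)
                        & (v["pos"] <= config.locus_center + config.locus_flank)
                    )
                ]
                g_pca = (
                    genetics.GenotypeMatrix(
                        g.dosage[off_locus],
                        g.variants.loc[off_locus, ["chrom", "pos", "ref", "alt", "imputation_r2"]],
                    )
                    if len(off_locus)
                    else g
                )
                pcs = genetics.pca_ancestry(g_pca, k=config.pca_components)
                state["pcs"] = pcs
                pheno = state["phenotypes"]
                results = []
                for pname in ("AUC_VAR", "CL_BSV", "log10_bilirubin"):
                    if pname not in pheno.columns:
                        continue
                    y = pheno[pname]
                    for vid in g.dosage.columns:
                        try:
                            r = genetics.assoc_linear(y, g.dosage[vid], pcs, variant=vid)
                        except ValueError:
                            continue
                        results.append({"phenotype": pname, **dataclasses.asdict(r)})
                assoc = pd.DataFrame(results).sort_values(["phenotype", "p_value"])
                assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
                state["assoc"] = assoc
                artifact("associations", out / "associations.tsv")
                thr = genetics.bonferroni_threshold(config.family_m)
                top = assoc[assoc.phenotype == "AUC_VAR"].iloc[0] if len(assoc) else None
                record(
                    stage, t0, bonferroni=thr,
                    top_aucvar=None if top is None else
                    {"variant": top["variant"], "p": top["p_value"], "beta": top["beta"]},
                )
            elif stage == "locus":
                g = state["genotypes"]
                pheno = state["phenotypes"]
                scan = genetics.locus_scan(
                    g, pheno["AUC_VAR"], config.locus_chrom, config.locus_center,
                    config.locus_flank, config.reference_snp, state.get("pcs"),
                )
                scan.to_csv(out / "locus_scan.tsv", sep="\t", index=False)
                cond = genetics.locus_scan(
                    g, pheno["AUC_VAR"], config.locus_chrom, config.locus_center,
                    config.locus_flank, config.reference_snp, state.get("pcs"),
                    condition_on=config.conditioning_snp,
                )
                cond.to_csv(out / "locus_scan_conditional.tsv", sep="\t", index=False)
                artifact("locus_scan", out / "locus_scan.tsv")
                artifact("locus_scan_conditional", out / "locus_scan_conditional.tsv")
                record(stage, t0, n_variants=len(scan))
            elif stage == "genotype_fit" and config.genotype_fit:
                data = state["data"]
                m = state["fit"].model.copy()
                m.covariates.genotype_cl = {"C/T": 0.9, "T/T": 0.8}
                m.mixture = nlme.MixtureSpec.from_data(data) if config.mixture else None
                res = nlme.fit(
                    m, data, ["CL", "geno_CT", "geno_TT", "bsv_CL", "prop_sd"],
                    seed=config.seed, maxiter=config.fit_maxiter,
                )
                state["geno_fit"] = res
                dofv = res.ofv - state["fit"].ofv
                est = res.estimates
                (out / "fit_genotype.json").write_text(
                    json.dumps({"ofv": res.ofv, "dofv_vs_base": dofv,
                                "estimates": est,
                                "pct_decrease_CT": 100 * (1 - est["geno_CT"]),
                                "pct_decrease_TT": 100 * (1 - est["geno_TT"])}, indent=2)
                )
                artifact("fit_genotype", out / "fit_genotype.json")
                record(stage, t0, ofv=res.ofv, estimates=est)
            elif stage == "genotype_fit":
                record(stage, t0, skipped=True)
            elif stage == "bands":
                model = state.get("geno_fit", state["fit"]).model
                strata = ("C/C", "C/T", "T/T") if model.covariates.genotype_cl else ("C/C",)
                frames = []
                troughs = {}
                for s in strata:
                    b = simvpc.simulate_profiles(
                        model, s, n=config.bands_n,
                        seed=int(rng.integers(2**31)),
                    )
                    frames.append(b.as_frame())
                    troughs[s] = b.trough_above_ec90
                pd.concat(frames).to_csv(out / "simulated_bands.tsv", sep="\t", index=False)
                artifact("simulated_bands", out / "simulated_bands.tsv")
                record(stage, t0, trough_above_ec90=troughs)
            elif stage == "vpc":
                table = simvpc.vpc(
                    state["fit"].model, state["data"], n_sim=config.vpc_n_sim,
                    seed=int(rng.integers(2**31)),
                )
                table.to_csv(out / "vpc.tsv", sep="\t", index=False)
                artifact("vpc", out / "vpc.tsv")
                record(stage, t0, n_bins=len(table))
    except Exception as exc:  # halt downstream, keep partial outputs
        manifest["error"] = {
            "stage": stage,
            "message": str(exc),
            "traceback": traceback.format_exc(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
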