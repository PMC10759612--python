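"""End-to-end orchestration: simulate (or load) -> genotype QC -> relationship
matrices -> the seven model fits -> information-criterion comparison ->
variance proportions and heritabilities -> cross-validated predictive
ability, with every artifact written as CSV/JSON under one output directory
and recorded in a run manifest carrying the config hash and seeds."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .data import GenotypeMatrix, Pedigree
from .evaluation import compare_pa, make_folds, run_cv, select_optimal_terms
from .kinship import (
    epistatic_matrix,
    filter_snps,
    genomic_matrix,
    impute_random,
    marker_matrix_additive,
    marker_matrix_dominance,
    marker_matrix_imprinting,
    pedigree_additive,
    pedigree_dominance,
    resolve_phase,
)
from .mixed_model import build_model, compare_models, fit_reml, heritability
from .rkhs import GibbsConfig, build_component_kernels
from .simulate import SimulationConfig, simulate_dataset
from .traits import describe_table

__all__ = ["RunConfig", "run_pipeline", "MODEL_FORMS"]

# model name -> (matrix source, included random terms)
MODEL_FORMS = {
    "ABLUP-OP": ("ped_op", {"plot", "a"}),
    "ABLUP-FS-A": ("ped_fs", {"plot", "a"}),
    "ABLUP-FS-AD": ("ped_fs", {"plot", "a", "d"}),
    "GBLUP-A": ("genomic", {"plot", "a"}),
    "GBLUP-AD": ("genomic", {"plot", "a", "d"}),
    "GBLUP-ADI": ("genomic", {"plot", "a", "d", "i"}),
    "GBLUP-ADIE": ("genomic", {"plot", "a", "d", "i", "e"}),
}


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    simulation: dict | None = None      # SimulationConfig kwargs; None -> load files
    genotype_file: str | None = None
    pedigree_file: str | None = None
    phenotype_file: str | None = None
    traits: list[str] = field(default_factory=list)
    models: list[str] = field(default_factory=lambda: list(MODEL_FORMS))
    maf_min: float = 0.05
    call_rate_min: float = 0.40
    reml: dict = field(default_factory=dict)
    negligible_threshold: float = 0.05
    cv: dict | None = None              # {"k":10, "replicates":10, "models":[...]}
    gibbs: dict = field(default_factory=dict)
    rkhs_bandwidth: float | list = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_FORMS)
        if unknown:
            raise ValueError(f"unknown model names {sorted(unknown)}")
        if self.simulation is None:
            for path in (self.genotype_file, self.pedigree_file, self.phenotype_file):
                if path is None or not Path(path).exists():
                    raise ValueError(
                        "without a simulation block, genotype/pedigree/phenotype "
                        f"files must all exist (missing: {path})"
                    )

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim = simulate_dataset(SimulationConfig(**sim_kwargs))
        traits = config.traits or [sim.config.trait_name]
        return sim.genotypes_observed, sim.pedigree_fs, sim.phenotypes, traits, sim
    geno = lio.read_genotypes(config.genotype_file)
    ped = lio.read_pedigree(config.pedigree_file)
    pheno = pd.read_csv(config.phenotype_file)
    traits = config.traits
    if not traits:
        raise ValueError("trait list required when loading phenotypes from file")
    return geno, ped, pheno, traits, None


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": {},
        "stages": {},
        "status": "running",
    }

    def stage(name):
        t0 = time.time()

        def done():
            manifest["stages"][name] = round(time.time() - t0, 3)

        return done

    try:
        done = stage("load")
        geno, ped_fs, pheno, traits, sim = _load_inputs(config)
        ped_op = ped_fs.op_view()
        done()

        done = stage("descriptives")
        desc = describe_table(pheno, traits)
        desc.to_csv(out / "descriptives.csv")
        manifest["artifacts"]["descriptives"] = "descriptives.csv"
        done()

        done = stage("genotype_qc")
        filtered, report = filter_snps(geno, config.maf_min, config.call_rate_min)
        imputed = impute_random(filtered, seed=config.seed + 101)
        phased = resolve_phase(imputed, ped_fs)
        manifest["snp_filter"] = report.__dict__
        done()

        done = stage("matrices")
        prog_ids = [i for i in phased.ids]
        a_ped_op = pedigree_additive(ped_op).subset(prog_ids)
        a_ped_fs_full = pedigree_additive(ped_fs)
        a_ped_fs = a_ped_fs_full.subset(prog_ids)
        d_ped_fs = pedigree_dominance(ped_fs, a_ped_fs_full).subset(prog_ids)
        g_a = genomic_matrix(phased, "A")
        g_d = genomic_matrix(phased, "D")
        g_i = genomic_matrix(phased, "I")
        g_aa = epistatic_matrix(g_a)
        matrix_sets = {
            "ped_op": {"a": a_ped_op},
            "ped_fs": {"a": a_ped_fs, "d": d_ped_fs},
            "genomic": {"a": g_a, "d": g_d, "i": g_i, "e": g_aa},
        }
        done()

        done = stage("model_fits")
        fits = {}
        grid_rows, prop_rows, h2_rows = [], [], []
        for trait in traits:
            trait_fits = []
            for model in config.models:
                source, include = MODEL_FORMS[model]
                mats = matrix_sets[source]
                spec = build_model(pheno, trait, mats, include, name=model)
                fit = fit_reml(spec, **config.reml)
                fits[(trait, model)] = fit
                trait_fits.append(fit)
                est = heritability(fit)
                grid_rows.append(
                    {"trait": trait, "model": model, "AIC": fit.aic, "BIC": fit.bic,
                     "logL": fit.logL, "converged": fit.converged}
                )
                prop_rows.append(
                    {"trait": trait, "model": model, **est.proportions}
                )
                h2_rows.append(
                    {"trait": trait, "model": model, "h2": est.h2, "se_h2": est.se_h2,
                     "H2": est.H2, "se_H2": est.se_H2}
                )
            compare_models(trait_fits).to_csv(
                out / f"model_ranking_{trait}.csv", index=False
            )
        pd.DataFrame(grid_rows).to_csv(out / "model_comparison.csv", index=False)
        pd.DataFrame(prop_rows).to_csv(out / "variance_proportions.csv", index=False)
        pd.DataFrame(h2_rows).to_csv(out / "heritability.csv", index=False)
        manifest["artifacts"].update(
            model_comparison="model_comparison.csv",
            variance_proportions="variance_proportions.csv",
            heritability="heritability.csv",
        )
        done()

        if config.cv is not None:
            done = stage("cross_validation")
            cv_cfg = dict(config.cv)
            k = cv_cfg.get("k", 10)
            reps = cv_cfg.get("replicates", 10)
            cv_models = cv_cfg.get("models", ["GBLUP-A", "GS-GBLUP", "GS-RKHS"])
            rows = []
            for trait in traits:
                full = fits.get((trait, "GBLUP-ADIE"))
                optimal = (
                    select_optimal_terms(full, config.negligible_threshold)
                    if full is not None
                    else {"a"}
                )
                ids = pheno.loc[~pheno[trait].isna(), "id"].tolist()
                folds = make_folds(ids, k=k, replicates=reps, seed=config.seed + 7)
                genomic = matrix_sets["genomic"]
                kernels = build_component_kernels(
                    {
                        c: m
                        for c, m in {
                            "a": marker_matrix_additive(phased.orient_minor()),
                            "d": marker_matrix_dominance(phased.orient_minor()),
                            "i": marker_matrix_imprinting(phased.orient_minor()),
                        }.items()
                        if c in optimal or c == "a"
                    },
                    phased.ids,
                    bandwidths=config.rkhs_bandwidth,
                )
                kernels = {
                    lab: K
                    for lab, K in kernels.items()
                    if K.meta["component"] in optimal
                }
                results = {}
                for model in cv_models:
                    if model == "GBLUP-A":
                        mats, include = {"a": genomic["a"]}, {"plot", "a"}
                    elif model == "GS-GBLUP":
                        mats = {c: genomic[c] for c in optimal}
                        include = {"plot", *optimal}
                    elif model == "GS-RKHS":
                        mats = kernels
                        include = {"plot", *kernels}
                    else:
                        raise ValueError(f"unknown CV model {model!r}")
                    res = run_cv(
                        model,
                        trait,
                        pheno,
                        mats,
                        folds,
                        include=include,
                        gibbs_config=GibbsConfig(
                            seed=config.seed + 13, **config.gibbs
                        ),
                        reml_kwargs=config.reml,
                    )
                    results[model] = res
                    res.scores.assign(trait=trait, model=model).to_csv(
                        out / f"cv_scores_{trait}_{model}.csv", index=False
                    )
                for model in cv_models:
                    if model == "GBLUP-A":
                        continue
                    rows.append(compare_pa(results[model], results["GBLUP-A"]))
            pd.DataFrame(rows).to_csv(out / "pa_comparison.csv", index=False)
            manifest["artifacts"]["pa_comparison"] = "pa_comparison.csv"
            done()

        if sim is not None:
            lio.write_truth(sim.truth, out / "truth.json")
            manifest["artifacts"]["truth"] = "truth.json"
        manifest["status"] = "complete"
    except Exception as exc:  # record the failing stage, then re-raise
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
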