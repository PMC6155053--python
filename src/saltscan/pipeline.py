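"""End-to-end orchestration: prep -> QC -> two-stage scans -> post-hoc."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qcmod
from . import scan as scanmod
from . import strata as stratamod
from .phenotype import prepare_cohort, exclude_incomplete
from .vcfio import read_genotypes, read_phenotypes


class PipelineError(RuntimeError):
    """Stage failure; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (round-trips through YAML)."""

    genotype_path: str = ""
    phenotype_path: str = ""
    out_dir: str = "saltscan_out"
    trait: str = "sbp"
    models: tuple = ("dosage", "additive", "dominant", "recessive")
    n_pcs: int = 20
    effect_allele: str = "alt"
    use_imputed_bp: bool = True
    suggestive_p: float = 1e-5
    replication_p: float = 0.05
    genome_wide_p: float = 5e-8
    qc_thresholds: dict = field(default_factory=dict)
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write outputs under ``config.out_dir``.

    Stages: phenotype preparation and exclusions; variant QC on the discovery
    cohort; per-coding-model discovery scan with genomic control; replication
    scan of suggestive loci; site-adjusted combined scan; two-stage decisions;
    stratified post-hoc analyses for replicated loci. Returns the JSON run
    report (also written to ``run_report.json``). The run is deterministic:
    no stage draws random numbers.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "stages": {}}

    @_stage("prep")
    def prep():
        raw = read_phenotypes(config.phenotype_path)
        n_input = len(raw)
        prepared = prepare_cohort(raw, use_imputed=config.use_imputed_bp)
        cohort, log = exclude_incomplete(prepared)
        report["stages"]["prep"] = {
            "n_input": n_input, "n_retained": len(cohort), "exclusions": log}
        return cohort

    cohort = prep()

    @_stage("read_genotypes")
    def load():
        geno = read_genotypes(config.genotype_path)
        report["stages"]["read_genotypes"] = {
            "n_variants": geno.n_variants, "n_samples": geno.n_subjects,
            "multiallelic_skipped": getattr(geno, "n_multiallelic_skipped", 0)}
        return geno

    genotypes = load()

    disc = cohort[cohort["site"] == "discovery"].reset_index(drop=True)
    repl = cohort[cohort["site"] == "replication"].reset_index(drop=True)
    if len(disc) == 0 or len(repl) == 0:
        raise PipelineError("prep", "both discovery and replication subjects "
                            "are required (site column)")

    @_stage("qc")
    def run_qc():
        geno_disc = genotypes.subset_subjects(list(disc["subject_id"]))
        table = qcmod.qc_table(geno_disc, thresholds=config.qc_thresholds or None,
                               effect_allele=config.effect_allele)
        table.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
        return table

    qc_report = run_qc()

    geno_disc = genotypes.subset_subjects(list(disc["subject_id"]))
    geno_repl = genotypes.subset_subjects(list(repl["subject_id"]))
    combined = pd.concat([disc, repl], ignore_index=True)
    geno_comb = genotypes.subset_subjects(list(combined["subject_id"]))

    decisions = []
    report["stages"]["scan"] = {}
    for model in config.models:
        @_stage(f"scan[{model}]")
        def scan_model(model=model):
            disc_recs = scanmod.genome_scan(
                disc, geno_disc, model, trait=config.trait, n_pcs=config.n_pcs,
                effect_allele=config.effect_allele,
                qc_thresholds=config.qc_thresholds or None)
            if not disc_recs:
                raise PipelineError("qc", f"no variants passed QC for the "
                                    f"{model} model")
            lam, disc_recs = scanmod.genomic_control(disc_recs)
            table = scanmod.scan_table(disc_recs)
            table.to_csv(out_dir / f"scan_{model}_discovery.tsv",
                         sep="\t", index=False)
            testable = table.loc[~table["untestable"], "p_raw"]
            scanmod.qq_data(testable).to_csv(
                out_dir / f"qq_{model}.tsv", sep="\t", index=False)

            suggestive = [r for r in disc_recs
                          if not r.untestable and r.p_gc < config.suggestive_p]
            report["stages"]["scan"][model] = {
                "n_variants": len(disc_recs), "lambda_gc": lam,
                "n_suggestive": len(suggestive)}
            if not suggestive:
                return []

            ids = [r.variant_id for r in suggestive]
            repl_recs = scanmod.genome_scan(
                repl, geno_repl, model, trait=config.trait, n_pcs=config.n_pcs,
                effect_allele=config.effect_allele, variant_subset=ids)
            comb_recs = scanmod.genome_scan(
                combined, geno_comb, model, trait=config.trait,
                n_pcs=config.n_pcs, effect_allele=config.effect_allele,
                site_adjust=True, variant_subset=ids)
            repl_by = {r.variant_id: r for r in repl_recs}
            comb_by = {r.variant_id: r for r in comb_recs}
            out = []
            for r in suggestive:
                dec = scanmod.two_stage_evaluate(
                    r, repl_by[r.variant_id], comb_by[r.variant_id],
                    suggestive_p=config.suggestive_p,
                    replication_p=config.replication_p,
                    genome_wide_p=config.genome_wide_p)
                out.append((model, dec, r))
            return out

        decisions.extend(scan_model())

    dec_table = pd.DataFrame([{
        "variant_id": d.variant_id, "coding_model": model,
        "p_discovery": d.p_discovery, "p_replication": d.p_replication,
        "p_combined": d.p_combined,
        "direction_consistent": d.direction_consistent, "status": d.status,
    } for model, d, _ in decisions])
    dec_table.to_csv(out_dir / "decisions.tsv", sep="\t", index=False)
    report["stages"]["two_stage"] = {
        "n_evaluated": len(decisions),
        "n_replicated": int((dec_table["status"].isin(
            ["replicated", "genome_wide"])).sum()) if len(dec_table) else 0,
        "n_genome_wide": int((dec_table["status"] == "genome_wide").sum())
        if len(dec_table) else 0,
    }

    @_stage("posthoc")
    def posthoc():
        done = []
        for model, dec, rec in decisions:
            if dec.status not in ("replicated", "genome_wide"):
                continue
            i = geno_disc.variant_ids.index(dec.variant_id)
            coded, _ = scanmod.code_genotype(
                posteriors=geno_disc.gp[i],
                model=model if model in ("dominant", "recessive") else "dominant",
                effect_allele=config.effect_allele)
            carrier = coded >= 1.0
            slopes = stratamod.subgroup_slopes(disc, carrier, config.trait)
            slopes.to_csv(out_dir / f"slopes_{model}_{dec.variant_id}.tsv",
                          sep="\t", index=False)
            table, bounds = stratamod.tertile_table(disc, carrier, config.trait)
            table.to_csv(out_dir / f"tertiles_{model}_{dec.variant_id}.tsv",
                         sep="\t", index=False)
            done.append({"variant_id": dec.variant_id, "model": model,
                         "tertile_boundaries": bounds})
        return done

    report["stages"]["posthoc"] = posthoc()
    report["qc_pass_counts"] = {
        m: int(qc_report[f"pass_{k}"].sum())
        for m, k in (("call_rate", "call_rate"), ("hwe", "hwe_p"),
                     ("maf", "maf"), ("r2", "r2"))
    }
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
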