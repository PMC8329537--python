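"""End-to-end pipeline: simulate/load -> families -> call -> covariates -> model.

Each stage writes its artifacts under the run directory and records its
counts in a manifest (seed, package version, input digests, records kept and
dropped per stage), so a run is reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import process_families
from .config import RunConfig
from .covariates import build_analysis_table
from .families import extract_three_gen_families, filter_by_panel
from .grm import compute_grm
from .io import read_pedigree, read_temperature, read_vcf
from .markers import read_bed_mask
from .model import (RecombinationMixedModel, fit_age_spline, group_summary,
                    temp_group_summary)
from .covariates import age_group

log = logging.getLogger("pedrec")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns artifacts dict including the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {},
        "counts": {},
    }
    artifacts: dict = {"manifest": manifest, "outdir": str(out)}

    # -- stage: simulate / load ------------------------------------------------
    if config.simulate:
        from .simulate import generate_dataset

        sim = dataclasses.replace(config.sim, seed=config.seed)
        bundle = generate_dataset(sim)
        paths = bundle.write(out / "inputs")
        pedigree, genotypes, temperature = bundle.pedigree, bundle.genotypes, bundle.temperature
        manifest["counts"]["simulated_animals"] = len(pedigree)
        manifest["counts"]["simulated_meioses"] = len(bundle.truth_meioses)
        artifacts["bundle"] = bundle
        ped_path, vcf_path = Path(paths["pedigree"]), Path(paths["genotypes"])
        temp_path = Path(paths["temperature"])
    else:
        for name, p in (("pedigree_csv", config.pedigree_csv),
                        ("genotypes_vcf", config.genotypes_vcf)):
            if p is None or not Path(p).exists():
                raise PipelineError("load", f"required input {name} missing: {p}")
        ped_path, vcf_path = Path(config.pedigree_csv), Path(config.genotypes_vcf)
        pedigree = read_pedigree(ped_path)
        genotypes = read_vcf(vcf_path)
        temperature = None
        temp_path = None
        if config.run_temperature_stage:
            if config.temperature_csv is None or not Path(config.temperature_csv).exists():
                raise PipelineError(
                    "covariates", f"temperature stage enabled but temperature "
                    f"file missing: {config.temperature_csv}")
            temp_path = Path(config.temperature_csv)
            temperature = read_temperature(temp_path)
    if config.simulate and not config.run_temperature_stage:
        temperature = None
    for p in (ped_path, vcf_path, temp_path):
        if p is not None:
            manifest["inputs"][p.name] = _sha256(p)

    region_mask = None
    if config.region_mask_bed is not None:
        region_mask = read_bed_mask(config.region_mask_bed)
        manifest["inputs"][Path(config.region_mask_bed).name] = _sha256(Path(config.region_mask_bed))

    # -- stage: families ---------------------------------------------------------
    genotyped = set(genotypes.ids)
    families = extract_three_gen_families(pedigree, genotyped)
    n_extracted = len(families)
    families = filter_by_panel(families, pedigree, genotyped, config.min_panel_markers)
    families.to_csv(out / "families.csv", index=False)
    manifest["counts"]["families_extracted"] = n_extracted
    manifest["counts"]["families_after_panel_filter"] = len(families)
    log.info("families: %d extracted, %d after panel filter", n_extracted, len(families))
    if families.empty:
        raise PipelineError("families", "no eligible three-generation families")

    # -- stage: call -------------------------------------------------------------
    records, events, call_stats = process_families(
        families, genotypes, region_mask=region_mask,
        max_inconsistency_rate=config.max_inconsistency_rate,
        max_count=config.max_crossovers)
    # chip class of the focal parent enters the residual adjustment
    chips = pedigree.set_index("animal_id")["chip_class"]
    records["chip_class"] = records["parent_id"].map(chips).to_numpy()
    records.to_csv(out / "counts.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    manifest["counts"].update({f"call_{k}": v for k, v in call_stats.items()})
    if records.empty:
        raise PipelineError("call", "no meioses survived crossover calling/QC")

    # -- stage: covariates ---------------------------------------------------------
    table = build_analysis_table(
        records, pedigree, temperature,
        temperature_reference=config.temperature_reference,
        hot=config.hot_threshold_c, cold=config.cold_threshold_c)
    table.to_csv(out / "analysis_table.csv", index=False)
    manifest["counts"]["meioses_with_temperature"] = int(table["has_temperature"].sum())
    artifacts["table"] = table

    # -- stage: model ----------------------------------------------------------------
    if config.run_model_stage:
        model_table = table[table["has_temperature"]] if temperature is not None else table
        if len(model_table) < 30:
            raise PipelineError("model", f"only {len(model_table)} usable rows (< 30)")
        parents = sorted(set(model_table["parent_id"]))
        grm = compute_grm(genotypes.rows(parents), parents)
        model = RecombinationMixedModel.from_dataframe(
            model_table, grm, include_temperature=temperature is not None)
        fit = model.fit()
        artifacts["fit"] = fit
        manifest["counts"]["meioses_in_model"] = len(model_table)
        manifest["counts"]["parents_in_model"] = len(parents)
        make_report(fit, table, out, config)
    else:
        artifacts["fit"] = None

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    artifacts["manifest_path"] = str(manifest_path)
    return artifacts


def make_report(fit, table: pd.DataFrame, outdir, config: RunConfig) -> dict:
    """Write the coefficient table, spline grid, and group summaries.

    Produces the full-model report (eight fixed-effect rows when both
    temperature stages are present), the fitted age-spline grid, per-age-group
    means with standard errors, and temperature-category boxplot statistics.
    """
    if fit is None:
        raise PipelineError("report", "model stage did not produce a fit")
    out = Path(outdir)
    coef = fit.fixed_effects().drop(index="Intercept")
    has_temp = any(name.startswith("T") for name in coef.index)
    report = {
        "heritability": {"h2": fit.h2, "se": fit.h2_se},
        "variance_components": {"sigma_g2": fit.sigma_g2, "sigma_e2": fit.sigma_e2},
        "converged": fit.converged,
        "fixed_effects": [
            {"factor": name, "beta": float(r["beta"]), "se": float(r["se"]),
             "p_value": float(r["p_value"])}
            for name, r in coef.iterrows()
        ],
    }
    if not has_temp:
        report["note"] = "temperature stage disabled; T1/T2 rows omitted"
    (out / "model_report.json").write_text(json.dumps(report, indent=2))
    with open(out / "model_report.txt", "w") as fh:
        fh.write(fit.summary() + "\n")

    spline = fit_age_spline(table["A"], table["Y"])
    pd.DataFrame({"age_months": spline.grid, "fitted_Y": spline.fitted}).to_csv(
        out / "spline_grid.csv", index=False)
    report["spline_argmin_age"] = spline.argmin_age

    groups = age_group(table["A"], start=config.age_group_start,
                       width=config.age_group_width, n_groups=config.n_age_groups)
    group_summary(table["Y"], groups).to_csv(out / "age_group_summary.csv", index=False)

    tsub = table[table["has_temperature"]]
    if len(tsub):
        temp_group_summary(tsub["Y"], tsub["T1"]).to_csv(
            out / "temp_group_summary.csv", index=False)
    return report
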