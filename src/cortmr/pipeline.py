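"""End-to-end pipeline driver: YAML configuration, stage wiring, and the
run manifest.

A single YAML file describes which stages to run (simulate ->
instruments -> mr -> sensitivity -> study -> enrich) and their
parameters; every run writes a JSON manifest recording the configuration
snapshot, seeds, per-stage row counts and package version, so a study is
reproducible from its manifest alone.  Empty-result conditions inside a
stage are recorded in the manifest, never raised as process failures.
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .gwas_io import (read_summary_stats, write_summary_stats, read_ld_table,
                      write_ld_table, read_bed, read_gmt, read_annotation)
from .synthetic_gwas import (SimulationConfig, simulate_pair,
                             simulate_outcome_grid, confounder_annotation)
from .instruments import SelectionConfig, build_instruments
from .estimators import run_all
from .sensitivity import run_sensitivity
from .study_runner import (StudyConfig, build_grid, run_study, RegionSpec)
from .enrichment import map_variants_to_genes, overrepresentation, results_frame


def _dataclass_from(cls, mapping: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ConfigError(
            f"{where}: unknown field(s) {', '.join(sorted(unknown))}")
    kw = dict(mapping)
    for f in dataclasses.fields(cls):
        if f.name in kw and isinstance(kw[f.name], list):
            kw[f.name] = tuple(kw[f.name])
    return cls(**kw)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def run_pipeline(config_path, out_dir=None) -> dict:
    """Execute the configured stages and write artifacts plus a manifest.

    Returns the manifest dictionary.  Raises :class:`ConfigError` (hard
    error) on a malformed configuration; unestimable cells and empty
    instrument sets are recorded as data.
    """
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    stages = cfg.get("stages", ["simulate", "study"])
    sim_cfg = None
    exposure = outcome = ld = truth = None
    annotation = None

    if "simulate" in stages:
        sim_cfg = _dataclass_from(SimulationConfig,
                                  {**cfg.get("simulate", {}), "seed": seed},
                                  "simulate")
        exposure, outcome, ld, truth = simulate_pair(sim_cfg)
        write_summary_stats(exposure, out / "exposure.tsv")
        write_summary_stats(outcome, out / "outcome.tsv")
        write_ld_table(ld, out / "ld.tsv")
        (out / "truth.json").write_text(truth.to_json())
        annotation = confounder_annotation(truth, sim_cfg)
        manifest["stages"]["simulate"] = {
            "n_variants": len(exposure), "n_instruments": sim_cfg.n_instruments,
            "theta": sim_cfg.theta,
        }
    else:
        paths = cfg.get("inputs", {})
        if "exposure" not in paths:
            raise ConfigError("config missing required field: inputs.exposure")
        exposure = read_summary_stats(paths["exposure"])
        if "outcome" in paths:
            outcome = read_summary_stats(paths["outcome"])
        if "ld" in paths:
            ld = read_ld_table(paths["ld"])
        if "annotation" in paths:
            annotation = read_annotation(paths["annotation"])

    sel = _dataclass_from(SelectionConfig, cfg.get("selection", {}), "selection")
    study_cfg = _dataclass_from(StudyConfig, cfg.get("study", {}), "study")

    needs_instruments = any(s in stages for s in
                            ("instruments", "mr", "sensitivity"))
    if needs_instruments:
        if ld is None:
            raise ConfigError("config missing required field: inputs.ld "
                              "(clumping needs an LD table)")
        if outcome is None:
            raise ConfigError("config missing required field: inputs.outcome")
        selres = build_instruments(exposure, outcome, ld, sel)
        selres.table.to_csv(out / "instruments.tsv", sep="\t", index=False)
        (out / "attrition.json").write_text(json.dumps(selres.attrition, indent=1))
        manifest["stages"]["instruments"] = selres.attrition
        if "mr" in stages and not selres.empty and len(selres.table) >= 2:
            methods = run_all(selres.table, n_boot=study_cfg.n_boot, seed=seed,
                              methods=study_cfg.methods)
            mr_rows = [m.to_dict() for m in methods.values()]
            pd.DataFrame(mr_rows).to_csv(out / "mr.tsv", sep="\t", index=False)
            manifest["stages"]["mr"] = {"n_methods": len(mr_rows),
                                        "n_snp": len(selres.table)}
            if "sensitivity" in stages:
                rep = run_sensitivity(
                    selres.table, int(exposure["n"].iloc[0]),
                    int(outcome["n"].iloc[0]),
                    mr_result=methods.get("ivw_re"),
                    annotation=annotation,
                    confounder_traits=study_cfg.confounder_traits,
                    alpha=study_cfg.alpha, n_sim=study_cfg.n_sim, seed=seed)
                (out / "sensitivity.json").write_text(
                    json.dumps(_report_dict(rep), indent=1, default=str))
                manifest["stages"]["sensitivity"] = {
                    "verdict": rep.verdict, "reason": rep.verdict_reason}
        elif "mr" in stages:
            manifest["stages"]["mr"] = {"empty_result": True}

    if "study" in stages:
        if sim_cfg is None:
            raise ConfigError("the study stage of this driver runs on "
                              "simulated grids; include the simulate stage")
        grid_cfg = cfg.get("grid", {})
        regions = grid_cfg.get("regions")
        grid = build_grid(regions) if regions else build_grid()
        thetas = {RegionSpec.from_label(k): float(v)
                  for k, v in grid_cfg.get("thetas", {}).items()}
        expo, ld2, outcomes, truths = simulate_outcome_grid(
            sim_cfg, grid, thetas=thetas or None)
        res = run_study(expo, outcomes, ld2, sel, study_cfg, grid=grid,
                        n_outcome=sim_cfg.n_outcome,
                        annotation=annotation, seed=seed)
        frame = res.results_frame()
        frame.to_csv(out / "study_results.tsv", sep="\t", index=False)
        surv = frame.loc[frame["cell"].isin(
            [s.label for s in res.survivors])]
        surv.to_csv(out / "study_survivors.tsv", sep="\t", index=False)
        manifest["stages"]["study"] = {
            "n_cells": len(grid.cells),
            "bonferroni": res.bonferroni,
            "bonferroni_display": res.bonferroni_display,
            "n_nominal": len(res.nominal),
            "n_meaningful": len(res.meaningful),
            "n_survivors": len(res.survivors),
            "attrition": res.attrition,
        }

    if "enrich" in stages:
        paths = cfg.get("inputs", {})
        for key in ("snps", "genes", "sets"):
            if key not in paths:
                raise ConfigError(f"config missing required field: inputs.{key}")
        snps = pd.read_csv(paths["snps"], sep="\t")
        genes = read_bed(paths["genes"])
        sets = read_gmt(paths["sets"])
        query = map_variants_to_genes(snps, genes)
        res = overrepresentation(query, sets, set(genes["gene_id"]))
        results_frame(res).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "n_query_genes": len(query), "n_sets": len(sets)}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


def _report_dict(rep) -> dict:
    d: dict = {"verdict": rep.verdict, "reason": rep.verdict_reason}
    if rep.cochran:
        d["cochran_q"] = {"q": rep.cochran.q, "df": rep.cochran.df,
                          "p": rep.cochran.pval}
    if rep.egger_intercept is not None:
        d["egger_intercept"] = {"value": rep.egger_intercept,
                                "se": rep.egger_intercept_se,
                                "p": rep.egger_intercept_pval}
    if rep.presso:
        d["presso"] = {"global_rss": rep.presso.global_rss,
                       "global_p": rep.presso.global_pval,
                       "outliers": rep.presso.outliers,
                       "outliers_identified": rep.presso.outliers_identified,
                       "distortion_p": rep.presso.distortion_pval}
    if rep.steiger:
        d["steiger"] = {"r2_exposure": rep.steiger.r2_exposure,
                        "r2_outcome": rep.steiger.r2_outcome,
                        "correct_direction": rep.steiger.correct_direction,
                        "p": rep.steiger.pval}
    if rep.loo:
        d["leave_one_out"] = {
            "driven_by_single_snp": rep.loo.driven_by_single_snp}
    if rep.removed_confounder_variants:
        d["confounder_screen"] = {
            "removed": rep.removed_confounder_variants,
            "post_screen_p": rep.post_screen_ivw.pval
            if rep.post_screen_ivw else None}
    return d
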