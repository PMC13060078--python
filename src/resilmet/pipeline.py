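"""End-to-end orchestration of the two analysis branches.

``run_pipeline`` executes, on a synthetic cohort (or user-supplied
files): simulate → resilience-branch preprocessing → trajectory model →
sparse PLS (tune, fit, cross-validate, permute) → external-visit
validation → hurdle and fold-change analyses → aging-branch mixed models
→ spectral queries, writing tidy CSV/JSON outputs plus a
:class:`RunManifest` with per-file SHA-256 hashes so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig, PipelineConfig
from .io import (FeatureTable, write_feature_table, write_metadata, write_mgf,
                 write_truth_json)
from .preprocess import (lmm_branch, select_external_visit, spls_branch)
from .resilience import fit_trajectory, resilience_scores
from .spectra import (GLUCURONIDE_LOSSES, ParentDrug, drug_metabolite_pipeline,
                      neutral_loss_query)
from .spls import (cross_validate, external_validate, fit_spls1,
                   permutation_test, prepare_matrix, tune_keep)
from .stats import fold_change, hurdle, lmm_age, split_resilience_groups
from .synth import generate_all

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    seed: int
    version: str
    generator_config: dict
    pipeline_config: dict
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, index=True) -> None:
    df.to_csv(path, float_format="%.10g", index=index)
    manifest.outputs[path.name] = _sha256(path)


def run_pipeline(gen_config: GeneratorConfig | None = None,
                 pipe_config: PipelineConfig | None = None,
                 out_dir: str | Path = "pipeline_out",
                 seed: int | None = None) -> RunManifest:
    """Run the full synthetic-cohort analysis and write all stage outputs."""
    gen = gen_config or GeneratorConfig()
    if seed is not None:
        gen = gen.replace(seed=seed)
    cfg = pipe_config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=gen.seed, version=__version__,
                           generator_config=dataclasses.asdict(gen),
                           pipeline_config=dataclasses.asdict(cfg))

    # --- simulate ----------------------------------------------------------
    records, table, meta, spectra, truth = generate_all(gen)
    manifest.stages.append("simulate")
    write_feature_table(table, out / "feature_table.csv")
    manifest.outputs["feature_table.csv"] = _sha256(out / "feature_table.csv")
    write_mgf(spectra, out / "spectra.mgf")
    manifest.outputs["spectra.mgf"] = _sha256(out / "spectra.mgf")
    write_truth_json(truth, out / "ground_truth.json")

    # --- resilience scores -------------------------------------------------
    fit = fit_trajectory(records)
    scores = resilience_scores(fit)
    manifest.stages.append("resilience")
    manifest.summary["trajectory"] = {
        "age_slope_per_decade": fit.age_slope,
        "random_slope_sd": fit.random_slope_sd,
        "converged": fit.converged,
    }
    _write(scores.rename("resilience").to_frame(), out / "resilience_scores.csv",
           manifest)
    meta = meta.copy()
    meta["resilience"] = meta["participant_id"].map(scores)
    write_metadata(meta, out / "sample_metadata.csv")
    manifest.outputs["sample_metadata.csv"] = _sha256(out / "sample_metadata.csv")

    # --- resilience branch: preprocess + sPLS ------------------------------
    x_sel, meta_sel, report = spls_branch(
        table, meta, rt_min=cfg.rt_min_minutes, blank_factor=cfg.blank_factor,
        blank_aggregate=cfg.blank_aggregate, min_presence=cfg.min_presence_spls,
        nzv_var_eps=cfg.nzv_var_eps, nzv_dominance=cfg.nzv_dominance)
    manifest.stages.append("preprocess_spls")
    manifest.summary["preprocess"] = {
        "steps": report.steps, "achieved_age_sd": report.achieved_age_sd}

    X = prepare_matrix(x_sel)
    y = meta_sel.set_index("sample_id")["resilience"].loc[X.index].to_numpy(float)
    if cfg.keep is None:
        tuned = tune_keep(X, y, folds=cfg.folds, seed=gen.seed,
                          scale=cfg.scale_features)
        keep = tuned.keep
    else:
        keep = cfg.keep
    sfit = fit_spls1(X, y, keep, scale=cfg.scale_features)
    cv = cross_validate(X, y, keep, k=cfg.folds, seed=gen.seed,
                        scale=cfg.scale_features)
    perm = permutation_test(X, y, keep, n_perm=cfg.n_permutations, seed=gen.seed,
                            scale=cfg.scale_features)
    manifest.stages.append("spls")
    manifest.summary["spls"] = {
        "keep": keep, "r2": sfit.r2, "p_value": sfit.p_value,
        "cv_observed_r": cv.observed_r, "cv_r2": cv.cv_r2, "cv_rmse": cv.rmse,
        "permutation_p": perm.p_value,
        "median_stability_selected": float(
            cv.stability[list(sfit.selected_set)].median()) if sfit.selected_set else np.nan,
    }
    feat_out = pd.DataFrame({
        "weight": sfit.weights,
        "stability": cv.stability,
        "selected": sfit.weights != 0,
    })
    _write(feat_out, out / "spls_features.csv", manifest)

    # --- external validation ------------------------------------------------
    ext_map = select_external_visit(meta, report.selected_visits)
    x_ext, meta_ext, _ = spls_branch(
        table, meta, rt_min=cfg.rt_min_minutes, blank_factor=cfg.blank_factor,
        blank_aggregate=cfg.blank_aggregate, min_presence=cfg.min_presence_spls,
        nzv_var_eps=cfg.nzv_var_eps, nzv_dominance=cfg.nzv_dominance,
        visit_map=ext_map)
    shared = x_sel.index.intersection(x_ext.index)
    X_ext = prepare_matrix(x_ext.loc[shared])
    y_ext = meta_ext.set_index("sample_id")["resilience"].loc[X_ext.index].to_numpy(float)
    sfit_shared = fit_spls1(X[shared], y, min(keep, len(shared)),
                            scale=cfg.scale_features)
    ext = external_validate(sfit_shared, X_ext, y_ext, folds=cfg.folds,
                            seed=gen.seed)
    manifest.stages.append("external_validation")
    manifest.summary["external_validation"] = dataclasses.asdict(ext)

    # --- hurdle + fold change on the selected visit -------------------------
    sel_samples = list(x_sel.columns)
    res_by_sample = meta_sel.set_index("sample_id")["resilience"]
    sel_table = table.subset_samples(sel_samples)
    hd = hurdle(sel_table, res_by_sample, min_group=cfg.hurdle_min_group)
    manifest.stages.append("hurdle")
    _write(hd, out / "hurdle_results.csv", manifest)
    groups = split_resilience_groups(res_by_sample)
    fc = fold_change(sel_table, groups)
    _write(fc, out / "fold_change.csv", manifest)
    manifest.summary["hurdle"] = {
        "n_step1_significant": int((hd["q1"] < 0.05).sum()),
        "n_step2_significant": int((hd["q2"] < 0.05).sum()),
    }

    # --- aging branch --------------------------------------------------------
    x_lmm, meta_lmm, _ = lmm_branch(
        table, meta, rt_min=cfg.rt_min_minutes, blank_factor=cfg.blank_factor,
        blank_aggregate=cfg.blank_aggregate, min_presence=cfg.min_presence_lmm)
    lmm_df, lmm_summary = lmm_age(x_lmm, meta, selection_rule=cfg.selection_rule)
    manifest.stages.append("lmm_age")
    manifest.summary["lmm_age"] = lmm_summary
    _write(lmm_df, out / "lmm_age_results.csv", manifest)

    # --- spectral queries ----------------------------------------------------
    gluc = neutral_loss_query(spectra, GLUCURONIDE_LOSSES, tol=cfg.query_tol_da)
    parents = [ParentDrug(pid, info["precursor_mz"], info["rt"],
                          frozenset(info["occurrences"]))
               for pid, info in truth.parent_drugs.items()]
    metab = drug_metabolite_pipeline(spectra, parents, tol=cfg.query_tol_da,
                                     min_matched=cfg.min_matched_fragments)
    manifest.stages.append("spectra")
    manifest.summary["spectra"] = {
        "n_glucuronide_matches": len(gluc),
        "n_metabolite_candidates": len(metab),
        "metabolite_annotations": sorted(m.annotation for m in metab),
    }
    metab_df = pd.DataFrame([{
        "spectrum_id": m.spectrum_id, "parent_id": m.parent_id,
        "delta_mass": m.delta_mass, "annotation": m.annotation,
        "rt": m.rt, "co_occurrence_ok": m.co_occurrence_ok,
        "rt_precedence_ok": m.rt_precedence_ok,
    } for m in metab])
    _write(metab_df, out / "drug_metabolites.csv", manifest, index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=1, sort_keys=True,
                  default=str)
    return manifest
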