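"""Config-driven orchestration of the full genic distribution workflow.

``run_pipeline`` reproduces the end-to-end analysis on any conforming
inputs: thin occurrences, select variables (one set trained on each
allele), tune by AICc, fit subsampling replicates, evaluate (AUC, partial
ROC), project to scenario members and average per scenario, classify by
training-presence thresholds, map relative favourability, and run the
overlap statistics and randomization tests. Every stage logs its seeds and
writes plain-text outputs; a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, overlap, projection, synthetic
from .geo import (ClimateStack, OccurrenceSet, extract_values, read_occurrences,
                  read_raster_stack, sample_background, thin_occurrences)
from .maxent import ModelSettings, MaxentNicheModel, tune_model

log = logging.getLogger("alleleniche")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the published study design."""

    # inputs: either a synthetic world ...
    synthetic: dict | None = None  # kwargs for synthetic.make_world, or {} for default
    # ... or paths
    stack_paths: list = field(default_factory=list)
    occurrence_path: str | None = None
    scenario_paths: dict = field(default_factory=dict)  # label -> [member dir, ...]

    thinning_km: float = 10.0
    r_threshold: float = 0.8
    target_k: int = 4
    n_background: int = 2000
    candidate_feature_sets: list = field(default_factory=lambda: ["L", "LQ", "LQH"])
    candidate_multipliers: list = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0])
    n_replicates: int = 50
    test_fraction: float = 0.25
    n_randomizations: int = 100
    pauc_omission: float = 0.05
    pauc_bootstraps: int = 100
    variable_sets: str = "both"  # "both" | "first" (skip the Set-2 duplicate run)
    seed: int = 0

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self):
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    """Returns (present stack, occurrences, {scenario label: [member stacks]})."""
    if config.synthetic is not None:
        kwargs = dict(config.synthetic)
        seed = kwargs.pop("seed", config.seed)
        if kwargs:
            world = synthetic.make_world(seed, **kwargs)
        else:
            world = synthetic.make_default_world(seed)
        scenarios = {}
        if world.future is not None:
            scenarios["future"] = [world.future]
        return world.present, world.occurrences, scenarios
    if not config.stack_paths or config.occurrence_path is None:
        raise ValueError("config needs either 'synthetic' or stack_paths + occurrence_path")
    stack = read_raster_stack(config.stack_paths)
    occ = read_occurrences(config.occurrence_path)
    scenarios = {}
    for label, member_dirs in config.scenario_paths.items():
        members = []
        for d in member_dirs:
            paths = [Path(d) / f"{name}.asc" for name in stack.names]
            members.append(read_raster_stack(paths, stack.names))
        scenarios[label] = members
    return stack, occ, scenarios


def _replicate_fit(pres_values, bg_values, stack, settings, n_replicates,
                   test_fraction, pauc_kw, seed):
    """Subsampling replicates: mean cloglog surface + per-replicate AUC/pAUC."""
    reps = evaluation.subsample_replicates(len(pres_values), n_replicates,
                                           test_fraction, seed)
    surfaces, rows = [], []
    bg_for_scores = bg_values
    for i, (train, test) in enumerate(reps):
        model = MaxentNicheModel(pres_values.iloc[train], bg_values,
                                 feature_classes=settings.feature_classes,
                                 reg_multiplier=settings.reg_multiplier,
                                 n_hinge_knots=settings.n_hinge_knots)
        res = model.fit(tol=settings.tol, max_iter=settings.max_iter)
        surf = res.predict_surface(stack, output_scale="cloglog")
        surfaces.append(surf)
        test_scores = res.predict(pres_values.iloc[test], output_scale="cloglog")
        bg_scores = res.predict(bg_for_scores, output_scale="cloglog")
        auc = evaluation.auc(test_scores, bg_scores)
        try:
            pauc, pauc_p = evaluation.partial_auc_ratio(
                test_scores, bg_scores, seed=seed + 7919 * i, **pauc_kw)
        except ValueError:
            pauc, pauc_p = float("nan"), float("nan")
        rows.append({"replicate": i, "auc": auc, "pauc_ratio": pauc,
                     "pauc_p": pauc_p})
        if i == 0:
            full_results = res
    mean_surface = projection.average_surfaces(surfaces)
    return mean_surface, pd.DataFrame(rows), full_results


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the whole workflow; returns a results dict and writes the run
    directory (tables as CSV, grids as ASCII, overlap results as YAML)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    provenance = {"config_sha256": config.digest(), "seed": config.seed}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(16)]
    results: dict = {"provenance": provenance}

    log.info("loading inputs")
    stack, occ_raw, scenarios = _load_inputs(config)

    # --- thinning ----------------------------------------------------------
    occ = thin_occurrences(occ_raw, config.thinning_km)
    counts = occ.counts()
    results["occurrence_counts"] = counts
    results["n_sites"] = occ.n_sites
    occ.write(outdir / "occurrences_thinned.csv")
    log.info("thinned occurrences: %s at %d sites", counts, occ.n_sites)
    alleles = occ.alleles
    if len(alleles) != 2:
        raise ValueError(f"pipeline models exactly two alleles, found {alleles}")

    # --- variable selection (Set 1 trained on allele A, Set 2 on allele B) -
    sets = {}
    set_labels = [("set1", alleles[0]), ("set2", alleles[1])]
    if config.variable_sets == "first" or len(stack.names) <= config.target_k:
        set_labels = set_labels[:1]
    for k, (label, train_allele) in enumerate(set_labels):
        if len(stack.names) > config.target_k:
            report = evaluation.select_variables(
                stack, occ.for_allele(train_allele),
                r_threshold=config.r_threshold, target_k=config.target_k,
                n_background=config.n_background, seed=seeds[0] + k)
            variables = report.final_variables
            report.removal_table().to_csv(outdir / f"variable_removals_{label}.csv",
                                          index=False)
        else:
            variables = list(stack.names)
        sets[label] = variables
        log.info("%s (trained on %s): %s", label, train_allele, variables)
    results["variable_sets"] = sets

    # --- per-set modelling -------------------------------------------------
    pauc_kw = {"omission_E": config.pauc_omission, "n_boot": config.pauc_bootstraps}
    results["sets"] = {}
    for si, (label, variables) in enumerate(sets.items()):
        sub = stack.subset(variables)
        bg_values, _ = sample_background(sub, min(config.n_background, sub.n_unmasked),
                                         seeds[1] + si)
        per_allele = {}
        for ai, allele in enumerate(alleles):
            occ_a = occ.for_allele(allele)
            pres = extract_values(sub, occ_a)
            tuning = tune_model(pres, bg_values,
                                candidate_feature_sets=config.candidate_feature_sets,
                                candidate_multipliers=config.candidate_multipliers)
            tuning.table.to_csv(outdir / f"tuning_{label}_{allele}.csv", index=False)
            settings = ModelSettings(feature_classes=tuning.best_classes,
                                     reg_multiplier=tuning.best_multiplier)
            mean_surface, eval_table, first_fit = _replicate_fit(
                pres, bg_values, sub, settings, config.n_replicates,
                config.test_fraction, pauc_kw, seeds[2] + 31 * si + ai)
            eval_table.to_csv(outdir / f"evaluation_{label}_{allele}.csv", index=False)
            mean_surface.write(outdir / f"suitability_present_{label}_{allele}.asc")
            thresholds = projection.training_thresholds(mean_surface, occ_a)
            classified = projection.classify_suitability(mean_surface, thresholds)
            classified.write(outdir / f"classified_present_{label}_{allele}.asc")
            per_allele[allele] = {
                "settings": settings, "occurrences": occ_a,
                "mean_surface": mean_surface, "thresholds": thresholds,
                "auc_mean": float(eval_table["auc"].mean()),
                "pauc_mean": float(eval_table["pauc_ratio"].mean()),
                "tuning": tuning, "presence_values": pres,
            }
            log.info("%s/%s: classes=%s mult=%s AUC=%.3f pAUC=%.3f",
                     label, allele, tuning.best_classes, tuning.best_multiplier,
                     per_allele[allele]["auc_mean"], per_allele[allele]["pauc_mean"])

        # favourability, present
        a, b = alleles
        fav_now = projection.relative_favourability(
            per_allele[a]["mean_surface"], per_allele[b]["mean_surface"], a, b)
        fav_now.write(outdir / f"favourability_present_{label}.asc")
        set_out = {"per_allele": per_allele,
                   "favourability_present": fav_now.percent,
                   "favourability": {"present": fav_now}}

        # projections per scenario
        for scen, members in scenarios.items():
            scen_surfs = {}
            for allele in alleles:
                settings = per_allele[allele]["settings"]
                pres = per_allele[allele]["presence_values"]
                member_means = []
                for member in members:
                    msub = member.subset(variables)
                    reps = evaluation.subsample_replicates(
                        len(pres), config.n_replicates, config.test_fraction,
                        seeds[2] + 31 * si + alleles.index(allele))
                    surfs = []
                    for train, _test in reps:
                        model = MaxentNicheModel(
                            pres.iloc[train], bg_values,
                            feature_classes=settings.feature_classes,
                            reg_multiplier=settings.reg_multiplier)
                        res = model.fit(tol=settings.tol, max_iter=settings.max_iter)
                        surfs.append(res.predict_surface(msub, output_scale="cloglog"))
                    member_means.append(projection.average_surfaces(surfs))
                scen_mean = projection.average_surfaces(member_means)
                scen_mean.write(outdir / f"suitability_{scen}_{label}_{allele}.asc")
                classified = projection.classify_suitability(
                    scen_mean, per_allele[allele]["thresholds"])
                classified.write(outdir / f"classified_{scen}_{label}_{allele}.asc")
                scen_surfs[allele] = scen_mean
            fav = projection.relative_favourability(scen_surfs[a], scen_surfs[b], a, b)
            fav.write(outdir / f"favourability_{scen}_{label}.asc")
            set_out[f"favourability_{scen}"] = fav.percent
            set_out["favourability"][scen] = fav
            log.info("%s/%s favourability: %s", label, scen, fav.percent)
        results["sets"][label] = set_out

    # --- overlap and randomization tests (on Set 1 variables) --------------
    label, variables = next(iter(sets.items()))
    sub = stack.subset(variables)
    a, b = alleles
    set1 = results["sets"][label]["per_allele"]
    d_geo = overlap.schoener_d_geographic(
        set1[a]["mean_surface"], set1[b]["mean_surface"])
    # both alleles and every permutation replicate share one tuned setting
    settings = set1[a]["settings"]
    fit_a = settings.fit(set1[a]["presence_values"],
                         sample_background(sub, min(config.n_background,
                                                    sub.n_unmasked), seeds[3])[0])
    fit_b = settings.fit(set1[b]["presence_values"],
                         sample_background(sub, min(config.n_background,
                                                    sub.n_unmasked), seeds[3])[0])
    d_env = overlap.schoener_d_environment(fit_a, fit_b, n_points=10_000,
                                           seed=seeds[4])
    ident = overlap.identity_test(occ.for_allele(a), occ.for_allele(b), sub,
                                  model_settings=settings,
                                  n_reps=config.n_randomizations, seed=seeds[5],
                                  n_background=config.n_background)
    ident.save(outdir / "identity_test.yaml")
    bg_tests = {}
    for direction, (oa, ob) in {"randomize_" + b: (a, b),
                                "randomize_" + a: (b, a)}.items():
        t = overlap.background_test(occ.for_allele(oa), occ.for_allele(ob), sub,
                                    model_settings=settings,
                                    n_reps=config.n_randomizations,
                                    seed=seeds[6], n_background=config.n_background)
        t.save(outdir / f"background_test_{direction}.yaml")
        bg_tests[direction] = {"observed_d": t.observed, "p_value": t.p_value}
    results["overlap"] = {
        "d_geographic": d_geo, "d_environmental": d_env,
        "identity_p": ident.p_value, "identity_observed_d": ident.observed,
        "background_tests": bg_tests,
    }
    log.info("overlap: D_geo=%.3f D_env=%.3f identity p=%.4f",
             d_geo, d_env, ident.p_value)

    # --- summary -----------------------------------------------------------
    summary = {
        "provenance": provenance,
        "occurrence_counts": {k: int(v) for k, v in counts.items()},
        "n_sites": int(occ.n_sites),
        "variable_sets": sets,
        "auc": {lab: {al: results["sets"][lab]["per_allele"][al]["auc_mean"]
                      for al in alleles} for lab in sets},
        "favourability_percent": {
            lab: {k: v for k, v in results["sets"][lab].items()
                  if k.startswith("favourability_")} for lab in sets},
        "overlap": {k: v for k, v in results["overlap"].items()},
    }
    with open(outdir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False, default_flow_style=False)
    return results
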