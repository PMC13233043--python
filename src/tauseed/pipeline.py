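"""End-to-end orchestration: cohort -> model -> inference -> statistics.

A run loads (or synthesizes) a connectome and PET cohort, stratifies
subjects by biomarker status, fits group-average and subject-level
stationary solutions, runs the seeding permutation test, compares predicted
entorhinal seeding between groups, and regresses empirical tau on the
model predictions (simple, covariate-adjusted and diagnosis-stratified).
The JSON report embeds the fully resolved configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .atlas import braak_regions, default_atlas, load_atlas
from .connectome import load_connectome
from .inference import SeedingPermutationTest
from .pet import (correct_unstable_regions, load_demographics, load_suvr_table,
                  pair_scans, stratify_cohort)
from .stats import (fit_adjusted_regression, fit_simple_regression,
                    pairwise_group_tests, predict_subject_seeding,
                    stratified_fits)
from .synthetic import get_preset, make_scenario_bundle
from .transport import AnomalyField, TauTransportModel, TransportParams

log = logging.getLogger("tauseed")

__all__ = ["RunConfig", "run_full_analysis", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of a full analysis run.

    Either ``preset`` names a synthetic scenario, or the file paths
    (atlas, connectome, SUVR tables, demographics) point at on-disk inputs.
    """

    preset: Optional[str] = None
    atlas_path: Optional[str] = None
    connectome_path: Optional[str] = None
    primary_suvr_path: Optional[str] = None
    tau_suvr_path: Optional[str] = None
    amyloid_suvr_path: Optional[str] = None
    demographics_path: Optional[str] = None
    modality: str = "FDG"
    params: TransportParams = field(default_factory=TransportParams)
    n_perm: int = 10_000
    rng_seed: int = 0
    pairing_policy: str = "earliest"
    window_days: int = 365
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %-18s %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("load_inputs")
def _load_inputs(config: RunConfig):
    if config.preset is not None:
        scenario = get_preset(config.preset, rng_seed=config.rng_seed)
        bundle = make_scenario_bundle(scenario, config.params)
        bundle["modality"] = scenario.modality
        return bundle
    if not (config.atlas_path and config.connectome_path
            and config.primary_suvr_path and config.tau_suvr_path):
        raise ValueError("either a preset or the full set of input paths is required")
    atlas = load_atlas(config.atlas_path) if config.atlas_path != "default" else default_atlas()
    conn = load_connectome(config.connectome_path, atlas)
    primary = load_suvr_table(config.primary_suvr_path, atlas, config.modality)
    tau = load_suvr_table(config.tau_suvr_path, atlas, "tau")
    amyloid = (load_suvr_table(config.amyloid_suvr_path, atlas, "amyloid")
               if config.amyloid_suvr_path else
               (primary if config.modality == "amyloid" else []))
    subjects = (load_demographics(config.demographics_path)
                if config.demographics_path else [])
    return {
        "atlas": atlas, "connectome": conn,
        "scans": {config.modality: primary, "amyloid": amyloid, "tau": tau},
        "tau_outcomes": tau, "subjects": subjects, "groups": None,
        "modality": config.modality, "manifest": None,
    }


@_stage("stratify")
def _stratify(bundle, config: RunConfig) -> pd.DataFrame:
    amyloid = bundle["scans"].get("amyloid") or []
    tau = bundle["scans"]["tau"]
    atlas = bundle["atlas"]
    if not amyloid:
        raise ValueError("no amyloid scans available for biomarker stratification")
    return stratify_cohort(amyloid, tau, atlas,
                           window_days=config.window_days,
                           policy=config.pairing_policy)


@_stage("seeding_inference")
def _seeding_inference(bundle, config: RunConfig):
    atlas = bundle["atlas"]
    modality = bundle["modality"]
    scans = bundle["scans"][modality]
    corrected = [correct_unstable_regions(s, atlas) for s in scans]
    mean_suvr = np.mean([s.suvr for s in corrected], axis=0)
    group_field = AnomalyField(atlas=atlas, values=mean_suvr,
                               modality=modality, provenance="group_average")
    test = SeedingPermutationTest(bundle["connectome"], group_field, config.params)
    results = test.fit(n_perm=config.n_perm, rng_seed=config.rng_seed)
    state = TauTransportModel(bundle["connectome"], group_field, config.params).fit()
    return results, state, corrected


@_stage("group_comparisons")
def _group_comparisons(bundle, corrected, strata: pd.DataFrame, config: RunConfig):
    atlas = bundle["atlas"]
    conn = bundle["connectome"]
    target = sorted(braak_regions(atlas, {1}))
    preds = {
        s.subject_id: predict_subject_seeding(s, conn, config.params, target)
        for s in corrected
    }
    pred_df = pd.DataFrame({"subject_id": list(preds), "seeding": list(preds.values())})

    results = {}
    if bundle["groups"] is not None:
        labels = pd.Series(bundle["groups"], name="group")
    elif len(strata):
        labels = strata.set_index("subject_id")["group"]
    else:
        labels = None
    if labels is not None:
        merged = pred_df.set_index("subject_id").join(labels, how="inner")
        merged = merged[merged["group"] != "EXCLUDED"]
        samples = {g: grp["seeding"].to_numpy()
                   for g, grp in merged.groupby("group")}
        results["by_biomarker"] = pairwise_group_tests(samples)
    subjects = bundle["subjects"]
    if subjects:
        diag = pd.Series({s.subject_id: s.diagnosis for s in subjects},
                         name="diagnosis").dropna()
        merged = pred_df.set_index("subject_id").join(diag, how="inner")
        samples = {g: grp["seeding"].to_numpy()
                   for g, grp in merged.groupby("diagnosis") if len(grp) >= 2}
        if len(samples) >= 2:
            results["by_diagnosis"] = pairwise_group_tests(samples)
    return results, pred_df


@_stage("regression")
def _regressions(bundle, pred_df: pd.DataFrame, config: RunConfig):
    atlas = bundle["atlas"]
    tau_scans = bundle.get("tau_outcomes") or bundle["scans"]["tau"]
    if not tau_scans:
        raise ValueError("tau table required for regression analyses")
    primary = bundle["scans"][bundle["modality"]]
    pairs = pair_scans(primary, tau_scans, window_days=config.window_days,
                       policy=config.pairing_policy)
    target = sorted(braak_regions(atlas, {1}))
    tgt_idx = [atlas.index_of(r) for r in target]
    rows = []
    for pr in pairs:
        rows.append({"subject_id": pr.subject_id,
                     "tau": float(pr.tau_scan.suvr[tgt_idx].mean())})
    df = pd.DataFrame(rows).merge(pred_df, on="subject_id")
    subjects = bundle["subjects"]
    demo = pd.DataFrame([{
        "subject_id": s.subject_id, "age": s.age,
        "sex": 1.0 if s.sex == "female" else 0.0,
        "apoe4": 1.0 if s.apoe4_carrier else 0.0,
        "diagnosis": s.diagnosis,
    } for s in subjects]) if subjects else pd.DataFrame()

    out = {"n_pairs": len(df)}
    out["simple"] = fit_simple_regression(df["seeding"], df["tau"])
    if len(demo):
        full = df.merge(demo, on="subject_id", how="inner")
        out["adjusted"] = fit_adjusted_regression(
            full["seeding"], full[["age", "sex", "apoe4"]], full["tau"])
        out["stratified"] = stratified_fits(full)
        out["cohort_frame"] = full
    return out


def _regression_to_dict(res) -> dict:
    if isinstance(res, str):
        return {"skipped": res}
    return {
        "n": res.n, "r": res.r, "model_kind": res.model_kind,
        "terms": [asdict(t) for t in res.terms],
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    bundle = _load_inputs(config)
    strata = _stratify(bundle, config)
    seed_results, state, corrected = _seeding_inference(bundle, config)
    comparisons, pred_df = _group_comparisons(bundle, corrected, strata, config)
    regressions = _regressions(bundle, pred_df, config)

    report = {
        "tauseed_version": __version__,
        "config": config.to_dict(),
        "manifest": bundle.get("manifest"),
        "n_subjects": len(pred_df),
        "group_sizes": (strata["group"].value_counts().to_dict()
                        if len(strata) else {}),
        "seeding_test": seed_results.to_dict(),
        "steady_state_top_regions": (
            state.to_series().sort_values(ascending=False).head(8).to_dict()),
        "group_comparisons": {
            key: [asdict(c) for c in comps]
            for key, comps in comparisons.items()
        },
        "regressions": {
            "n_pairs": regressions["n_pairs"],
            "simple": _regression_to_dict(regressions["simple"]),
            **({"adjusted": _regression_to_dict(regressions["adjusted"])}
               if "adjusted" in regressions else {}),
            **({"stratified": {k: _regression_to_dict(v)
                               for k, v in regressions["stratified"].items()}}
               if "stratified" in regressions else {}),
        },
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        pred_df.to_csv(out / "subject_predictions.csv", index=False)
        if len(strata):
            strata.to_csv(out / "biomarker_groups.csv", index=False)
        if "cohort_frame" in regressions:
            regressions["cohort_frame"].to_csv(out / "regression_frame.csv",
                                               index=False)
    return report
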