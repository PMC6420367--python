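"""The umbrella analysis: simulate → (asymmetry screen, hemisphere
combination) → AUC ranking → composite selection → scoring → ROC
discrimination, with optional phantom-based voxel-wise maps.

``run_full_analysis`` drives everything from one resolved configuration
mapping and is deterministic given (config, seed): report files are
byte-identical across reruns.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import discrimination, image_quant, region_select, synthetic, tableio
from .atlas import default_atlas
from .synthetic import AV1451_COMPOSITE, PIB_GLOBAL

DEFAULT_CONFIG: dict = {
    "cohort": {"preset": "table1", "correlation": 0.5,
               "n_per_group": {"CN": 100, "DLB": 33, "PCA": 18},
               "printed_extremes": False},
    "selection": {"positive": "PCA", "negative": "DLB",
                  "auc_threshold": 0.97, "alpha": 0.001},
    "asymmetry_alpha": 0.001,
    "voxelwise": {"enabled": False, "p_thresh": 0.001, "extent": 25,
                  "connectivity": 18, "n_per_group": 4, "noise_sd": 0.05,
                  "effect_region": "target_8", "effect_size": 0.5},
    "pvc": True,
    "min_tissue": image_quant.DEFAULT_MIN_TISSUE,
    "seed": 0,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merged(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merged(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def resolve_config(config: dict | None = None, seed: int | None = None) -> dict:
    cfg = _merged(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage name must surface
            raise PipelineError(name, exc) from exc
    return wrap


def cohort_spec_from_config(cfg: dict) -> synthetic.CohortSpec:
    c = cfg["cohort"]
    preset = synthetic.COHORT_PRESETS[c.get("preset", "table1")]
    return preset(correlation=c.get("correlation", 0.5), seed=cfg["seed"],
                  printed_extremes=c.get("printed_extremes", False),
                  n_per_group={k: int(v) for k, v in c["n_per_group"].items()})


def _voxelwise_stage(cfg: dict, seed: int) -> dict:
    vw = cfg["voxelwise"]
    spec = synthetic.default_phantom_spec(noise_sd=vw["noise_sd"])
    boosted = dict(spec.true_uptake)
    boosted[vw["effect_region"]] = boosted[vw["effect_region"]] + vw["effect_size"]
    from dataclasses import replace
    spec_b = replace(spec, true_uptake=boosted)
    n = int(vw["n_per_group"])

    def suvr_volume(phantom_spec, s):
        pet, gm, wm, _csf, labels = synthetic.generate_phantom(phantom_spec, seed=s)
        vol = pet
        if cfg["pvc"]:
            vol = image_quant.pvc_two_compartment(pet, gm, wm, cfg["min_tissue"])
        ref = tuple(lab for lab, name in phantom_spec.label_map.items()
                    if name in phantom_spec.reference_regions)
        from .atlas import AtlasDefinition
        atlas = AtlasDefinition(phantom_spec.label_map, (), ref)
        return image_quant.normalize_suvr(vol, labels, atlas)

    group_a = [suvr_volume(spec, seed * 1000 + i) for i in range(n)]
    group_b = [suvr_volume(spec_b, seed * 1000 + 500 + i) for i in range(n)]
    t_map, p_map = image_quant.voxelwise_ttest(group_b, group_a)
    result = image_quant.cluster_threshold(p_map, t_map, vw["p_thresh"],
                                           vw["extent"], vw["connectivity"])
    return {"n_clusters": int(len(result.clusters)),
            "clusters": result.clusters,
            "effect_region": vw["effect_region"]}


def run_full_analysis(config: dict | None = None, seed: int | None = None,
                      outdir: str | Path | None = None) -> dict:
    """Execute the full synthetic analysis and return the report bundle.

    When ``outdir`` is given, writes cohort.csv, regional.csv, ranking.csv,
    composite.json, scores.csv, roc.csv, report.json and config.json, each
    tagged with the resolved config hash.
    """
    cfg = resolve_config(config, seed)
    seed = cfg["seed"]
    cfg_hash = tableio.config_hash(cfg)
    atlas = default_atlas()

    spec = _stage("cohort_spec")(cohort_spec_from_config, cfg)
    cohort = _stage("simulate_cohort")(synthetic.generate_cohort, spec, seed)
    regional = _stage("simulate_regional")(
        synthetic.generate_regional_profile, spec, atlas.gray_matter_names,
        composite_latent=cohort, seed=seed)

    asym_report, verdict = _stage("asymmetry_screen")(
        region_select.asymmetry_screen, regional, cfg["asymmetry_alpha"])
    combined = _stage("combine_left_right")(region_select.combine_left_right, regional)

    sel = cfg["selection"]
    ranking = _stage("rank_regions")(
        region_select.rank_regions, combined, sel["positive"], sel["negative"])
    composite = _stage("select_composite")(
        region_select.select_composite, ranking, sel["auc_threshold"], sel["alpha"])
    scores = _stage("composite_score")(region_select.composite_score, combined, composite)

    scored = combined[["subject_id", "group"]].copy()
    scored["occipital_composite"] = scores.to_numpy()
    scored[PIB_GLOBAL] = cohort[PIB_GLOBAL].to_numpy()

    comparison = _stage("discriminate")(
        discrimination.compare_markers, scored, "occipital_composite", PIB_GLOBAL,
        sel["positive"], sel["negative"], seed=seed)

    summary = (scored.groupby("group")[["occipital_composite", PIB_GLOBAL]]
               .agg(["mean", "std"]).round(4))
    summary.columns = ["_".join(c) for c in summary.columns]
    summary_direct = (cohort.groupby("group")[[AV1451_COMPOSITE, PIB_GLOBAL]]
                      .agg(["mean", "std"]).round(4))
    summary_direct.columns = ["_".join(c) for c in summary_direct.columns]

    report = {
        "seed": seed,
        "asymmetry_verdict": verdict,
        "n_asymmetric_flags": int(asym_report["asymmetric"].sum()),
        "composite_regions": list(composite.regions),
        "auc_threshold": composite.auc_threshold,
        "alpha": composite.alpha,
        "ranking_top5": ranking.head(5),
        "group_summary": summary.reset_index(),
        "group_summary_direct": summary_direct.reset_index(),
        "discrimination": {
            k: v for k, v in comparison.items() if k != "roc"
        },
    }
    if cfg["voxelwise"]["enabled"]:
        report["voxelwise"] = _stage("voxelwise")(_voxelwise_stage, cfg, seed)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tableio.write_table_csv(cohort, outdir / "cohort.csv", cfg_hash)
        tableio.write_table_csv(regional, outdir / "regional.csv", cfg_hash)
        tableio.write_table_csv(ranking, outdir / "ranking.csv", cfg_hash)
        tableio.write_table_csv(scored, outdir / "scores.csv", cfg_hash)
        composite.to_json(outdir / "composite.json")
        roc_rows = []
        for marker, roc in comparison["roc"].items():
            for t, sens, spc in zip(roc.thresholds, roc.sensitivity, roc.specificity):
                roc_rows.append({"marker": marker,
                                 "threshold": "inf" if np.isinf(t) else round(float(t), 10),
                                 "sensitivity": sens, "specificity": spc})
        tableio.write_table_csv(pd.DataFrame(roc_rows), outdir / "roc.csv", cfg_hash)
        tableio.write_report_json(report, outdir / "report.json", cfg_hash)
        tableio.write_report_json({"resolved_config": cfg}, outdir / "config.json", cfg_hash)
    return report
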