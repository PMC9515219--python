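"""Configuration-driven end-to-end runs.

A single YAML config describes either a simulation block (synthetic
inputs with planted structure) or paths to user-supplied tables, plus
stage toggles and stage parameters.  Stages exchange data through TSV
artifacts on disk — downstream stages re-read what upstream stages wrote,
so any stage can be rerun in isolation — and the run ends with a
consolidated JSON report and a log line per stage recording parameters,
seeds and input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as tgio
from .containers import ParcelMap
from .gradients import build_mpc, connectivity_gradients
from .predict import MultiscaleLasso
from .profiles import profile_feature_panel
from .shared import SharedDimension, leave_one_condition_out, mean_effect_map
from .spatial import generate_spins, stratify_map, test_feature_panel
from .synthetic import (
    SimulationConfig,
    make_parcellation,
    simulate_connectivity,
    simulate_effect_matrix,
    simulate_feature_panel,
    simulate_profiles,
    simulate_smooth_map,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_inputs"]

logger = logging.getLogger(__name__)

_DEFAULT_PARAMS = {
    "scaling": "center",
    "n_components": 5,
    "density": 0.1,
    "alpha": 0.5,
    "t": 0.0,
    "n_spins": 1000,
    "k_outer": 5,
    "k_inner": 5,
    "n_repeats": 100,
    "n_perm": 0,  # 0 disables the permutation test
}

_DEFAULT_STAGES = {
    "shared_dimension": True,
    "profiles": True,
    "gradients": True,
    "correlations": True,
    "stratification": True,
    "prediction": True,
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stages = {**_DEFAULT_STAGES, **self.stages}
        self.params = {**_DEFAULT_PARAMS, **self.params}
        unknown = set(self.params) - set(_DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        if self.simulate is None:
            required = {"meta", "effects"}
            if self.stages.get("profiles") or self.stages.get("gradients"):
                required.add("profiles")
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(
                    f"no simulation block and missing input paths: {sorted(missing)}"
                )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"seed", "simulate", "inputs", "stages", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:12]


def simulate_inputs(cfg: SimulationConfig, outdir: str) -> dict:
    """Generate all synthetic inputs, write them as TSVs, return their paths.

    The planted ground truth (shared map, peak depths, axis, feature
    support) is written to a JSON sidecar for recovery checks.
    """
    os.makedirs(outdir, exist_ok=True)
    meta = make_parcellation(cfg)
    shared = simulate_smooth_map(meta, cfg.lengthscale, cfg.seed, name="planted_shared")
    effects = simulate_effect_matrix(meta, shared, cfg)
    # peak depth follows the planted axis so laminar features track it
    peak = ParcelMap(
        0.5 + 0.35 * np.tanh(shared.values), meta, name="planted_peak_depth"
    )
    amp = ParcelMap(np.full(meta.n_regions, 1.0), meta, name="amplitude")
    prof = simulate_profiles(
        meta, peak, amp, cfg.profile_depths, cfg.seed + 11, noise_sd=0.02
    )
    conn = simulate_connectivity(meta, shared, noise=0.05, seed=cfg.seed + 13)
    panel = simulate_feature_panel(meta, shared, cfg)

    paths = {
        "meta": os.path.join(outdir, "parcellation.tsv"),
        "effects": os.path.join(outdir, "effects.tsv"),
        "profiles": os.path.join(outdir, "profiles.tsv"),
        "functional_matrix": os.path.join(outdir, "functional_matrix.tsv"),
        "feature_panel": os.path.join(outdir, "feature_panel.tsv"),
    }
    tgio.write_meta(meta, paths["meta"])
    tgio.write_parcel_table(effects, paths["effects"])
    tgio.write_parcel_table(prof, paths["profiles"])
    tgio.write_matrix(conn, paths["functional_matrix"])
    tgio.write_parcel_table(panel, paths["feature_panel"])
    truth = {
        "planted_shared_map": {r: float(v) for r, v in zip(meta.region_id, shared.values)},
        "planted_peak_depth": {r: float(v) for r, v in zip(meta.region_id, peak.values)},
        "informative_features": [panel.feature_names[j] for j in cfg.informative_features],
        "shared_loadings": list(cfg.shared_loadings),
        "seed": cfg.seed,
    }
    truth_path = os.path.join(outdir, "ground_truth.json")
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    paths["ground_truth"] = truth_path
    return paths


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute all enabled stages; returns the consolidated report dict.

    Artifacts (TSV per stage, ``report.json``, ``pipeline.log``) land in
    ``outdir``.  Deterministic for a fixed config.
    """
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "pipeline.log")
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"seed": config.seed, "params": dict(sorted(config.params.items()))}
    try:
        return _run(config, outdir, report)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: str, report: dict) -> dict:
    p = config.params
    if config.simulate is not None:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
        inputs = simulate_inputs(sim_cfg, outdir)
        logger.info("stage=simulate seed=%d params=%s", config.seed, config.simulate)
        report["simulation"] = {k: _hash_file(v) for k, v in inputs.items()}
    else:
        inputs = dict(config.inputs)

    meta = tgio.read_meta(inputs["meta"])
    logger.info("stage=load meta=%s hash=%s", inputs["meta"], _hash_file(inputs["meta"]))

    scores_map = None
    if config.stages["shared_dimension"]:
        effects = tgio.read_parcel_table(inputs["effects"], meta, kind="effects")
        results = SharedDimension(effects, scaling=p["scaling"]).fit(p["n_components"])
        scores_map = results.score_map(0)
        tgio.write_parcel_table(scores_map, os.path.join(outdir, "shared_scores.tsv"))
        loco = leave_one_condition_out(effects, results)
        report["shared_dimension"] = {
            "variance_explained": [float(v) for v in results.variance_explained],
            "loadings": {
                c: [float(v) for v in results.loadings[i]]
                for i, c in enumerate(effects.conditions)
            },
            "leave_one_condition_out": {
                row.held_out: float(row.abs_r) for row in loco.itertuples()
            },
            "mean_effect_corr": float(
                np.corrcoef(scores_map.values, mean_effect_map(effects).values)[0, 1]
            ),
        }
        logger.info(
            "stage=shared_dimension scaling=%s var1=%.4f",
            p["scaling"],
            results.variance_explained[0],
        )

    feature_blocks = []
    if config.stages["profiles"]:
        prof = tgio.read_parcel_table(inputs["profiles"], meta, kind="features")
        profset = _profiles_from_panel(prof)
        laminar = profile_feature_panel(profset)
        tgio.write_parcel_table(laminar, os.path.join(outdir, "laminar_features.tsv"))
        feature_blocks.append(laminar)
        logger.info("stage=profiles n_depths=%d", profset.n_depths)

    if config.stages["gradients"]:
        prof = tgio.read_parcel_table(inputs["profiles"], meta, kind="features")
        mpc = build_mpc(_profiles_from_panel(prof))
        mpc_grad = connectivity_gradients(
            mpc, density=p["density"], alpha=p["alpha"], diffusion_time=p["t"],
            n_components=min(p["n_components"], meta.n_regions - 2),
        )
        grads = {"mpc_gradient1": mpc_grad.gradient_map(0)}
        if "functional_matrix" in inputs:
            fc = tgio.read_matrix(inputs["functional_matrix"], meta, kind="functional")
            fc_grad = connectivity_gradients(
                fc, density=p["density"], alpha=p["alpha"], diffusion_time=p["t"],
                n_components=min(p["n_components"], meta.n_regions - 2),
            )
            grads["fc_gradient1"] = fc_grad.gradient_map(0)
        from .containers import FeaturePanel

        gpanel = FeaturePanel(
            np.column_stack([g.values for g in grads.values()]),
            tuple(grads),
            meta,
            provenance=("gradient",) * len(grads),
        )
        tgio.write_parcel_table(gpanel, os.path.join(outdir, "gradients.tsv"))
        feature_blocks.append(gpanel)
        report["gradients"] = {
            "mpc_eigenvalues": [float(v) for v in mpc_grad.eigenvalues[:3]],
        }
        logger.info("stage=gradients density=%.2f alpha=%.2f t=%.1f",
                    p["density"], p["alpha"], p["t"])

    if "feature_panel" in inputs:
        extra = tgio.read_parcel_table(inputs["feature_panel"], meta, kind="features")
        feature_blocks.append(extra)
    if "transmitters" in inputs:
        tm = tgio.read_parcel_table(inputs["transmitters"], meta, kind="features")
        feature_blocks.append(tm)

    panel = _merge_panels(feature_blocks, meta) if feature_blocks else None

    if config.stages["correlations"] and scores_map is not None and panel is not None:
        spins = generate_spins(meta, n_rotations=p["n_spins"], seed=config.seed + 101)
        table = test_feature_panel(scores_map, panel, spins)
        table.to_csv(
            os.path.join(outdir, "correlations.tsv"), sep="\t", index=False,
            float_format="%.12g",
        )
        report["correlations"] = {
            row.feature: {"r": float(row.r), "p_spin": float(row.p_spin),
                          "q_fdr": float(row.q_fdr)}
            for row in table.itertuples()
        }
        logger.info("stage=correlations n_spins=%d n_features=%d",
                    p["n_spins"], panel.n_features)

    if config.stages["stratification"] and scores_map is not None:
        strat = {}
        for label in ("community", "hierarchy"):
            df = stratify_map(scores_map, label)
            df.to_csv(
                os.path.join(outdir, f"stratification_{label}.tsv"),
                sep="\t", index=False, float_format="%.12g",
            )
            strat[label] = {
                str(r["class"]): {
                    "count": int(r["count"]),
                    "mean": None if np.isnan(r["mean"]) else float(r["mean"]),
                    "sd": None if np.isnan(r["sd"]) else float(r["sd"]),
                }
                for _, r in df.iterrows()
            }
        report["stratification"] = strat
        logger.info("stage=stratification")

    if config.stages["prediction"] and scores_map is not None and panel is not None:
        model = MultiscaleLasso(
            panel, scores_map, k_outer=p["k_outer"], k_inner=p["k_inner"],
            n_repeats=p["n_repeats"],
        )
        pred = model.fit(seed=config.seed + 202)
        if p["n_perm"] > 0:
            model.permutation_test(pred, n_perm=p["n_perm"], seed=config.seed + 203)
        pred.selection_frame().to_csv(
            os.path.join(outdir, "selection_frequency.tsv"), sep="\t", index=False,
            float_format="%.12g",
        )
        report["prediction"] = {
            "mean_r": float(pred.r_per_repeat.mean()),
            "sd_r": float(pred.r_per_repeat.std(ddof=1)) if p["n_repeats"] > 1 else 0.0,
            "mean_mae": float(pred.mae_per_repeat.mean()),
            "p_perm": pred.p_perm,
            "selection_frequency": {
                f: float(v)
                for f, v in zip(panel.feature_names, pred.selection_frequency)
            },
        }
        logger.info("stage=prediction repeats=%d mean_r=%.3f",
                    p["n_repeats"], report["prediction"]["mean_r"])

    report_path = os.path.join(outdir, "report.json")
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("stage=report path=%s", report_path)
    return report


def _profiles_from_panel(panel) -> "object":
    """Reinterpret a region x depth-column table as a ProfileSet."""
    from .containers import ProfileSet

    try:
        depths = np.array([float(c) for c in panel.feature_names])
    except ValueError:
        depths = np.linspace(0.0, 1.0, panel.n_features)
    return ProfileSet(panel.values, depths, panel.meta, source="table")


def _merge_panels(blocks, meta):
    from .containers import FeaturePanel

    names: list[str] = []
    prov: list[str] = []
    cols = []
    for blk in blocks:
        for j, name in enumerate(blk.feature_names):
            if name in names:  # later blocks defer to earlier computed features
                continue
            names.append(name)
            prov.append(blk.provenance[j])
            cols.append(blk.values[:, j])
    return FeaturePanel(np.column_stack(cols), names, meta, provenance=tuple(prov))
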