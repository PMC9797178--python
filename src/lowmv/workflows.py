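"""End-to-end study orchestration.

``run_study`` executes the pipeline stages in dependency order —

    synth -> commission -> validate -> plan -> evaluate -> mc

— from a single YAML-style configuration, writing a consolidated JSON report
(beam-quality table, gamma pass table, paired-plan dose indices, MC bone
table) plus a run manifest with config hash, seeds and a file inventory.
Stages can be switched off; a failed stage halts everything downstream and
the manifest records the partial completion.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dose as dose_mod
from . import evaluate as ev
from .commissioning import build_beam_model, extract_dd10, extract_dmax
from .optimize import ObjectiveSpec, optimize_fluence, segment_width_range
from .phantoms import planning_phantom
from .scans import (BeamQualitySpec, beam_quality_2p5mv, beam_quality_6mv,
                    generate_beam_scan_set)
from .spectra import generate_spectrum

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "beams": {
        "2.5MV": {"preset": "2.5MV"},
        "6MV": {"preset": "6MV"},
    },
    "stages": {"synth": True, "commission": True, "validate": True,
               "plan": True, "evaluate": True, "mc": False},
    "plan": {
        "target_depth_cm": 4.0,
        "voxel_cm": 0.5,
        "gantry_angles_deg": [0.0, 72.0, 144.0, 216.0, 288.0],
        "bixel_width_cm": 0.5,
        "prescription_gy": 60.0,
    },
    "mc": {"histories": 2_000_000, "tuning_budget": 12_000_000,
           "presets": ["cranium", "femur"]},
}


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    stages_completed: list[str] = field(default_factory=list)
    stages_skipped: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    outputs: dict[str, str] = field(default_factory=dict)
    log_path: str | None = None
    started: float = 0.0
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _quality_from_config(cfg: dict) -> BeamQualitySpec:
    preset = cfg.get("preset")
    if preset in ("2.5MV", "2p5mv", "2.5mv"):
        return beam_quality_2p5mv()
    if preset in ("6MV", "6mv"):
        return beam_quality_6mv()
    return BeamQualitySpec(**{k: v for k, v in cfg.items() if k != "preset"})


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def execution_dag(config: dict | None = None) -> list[str]:
    """Stage names in dependency order, honoring the stage switches."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    order = ["synth", "commission", "validate", "plan", "evaluate", "mc"]
    return [s for s in order if cfg["stages"].get(s, False)]


def run_study(config: dict | str | Path | None = None,
              out_dir: str | Path = "study_out",
              dry_run: bool = False) -> RunManifest:
    """Run the requested stages and write report + manifest under ``out_dir``."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge(DEFAULT_CONFIG, config or {})
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    seed = int(cfg["seed"])
    manifest = RunManifest(config_hash=cfg_hash,
                           seeds={"synth": seed, "mc": seed + 1},
                           started=time.time())
    dag = execution_dag(cfg)
    if dry_run:
        print(" -> ".join(dag))
        manifest.stages_skipped = dag
        manifest.finished = time.time()
        return manifest

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg_hash}
    scans: dict = {}
    models: dict = {}
    try:
        if "synth" in dag:
            for label, bcfg in cfg["beams"].items():
                scan = generate_beam_scan_set(_quality_from_config(bcfg),
                                              seed=seed, beam_label=label)
                scans[label] = scan
                scan.save(out_dir / f"scan_{label.replace('.', 'p')}")
                manifest.outputs[f"scan/{label}"] = f"scan_{label.replace('.', 'p')}"
            manifest.stages_completed.append("synth")

        if "commission" in dag:
            for label, scan in scans.items():
                model = build_beam_model(scan)
                path = out_dir / f"model_{label.replace('.', 'p')}.h5"
                model.save(path)
                models[label] = model
                manifest.outputs[f"model/{label}"] = path.name
            manifest.stages_completed.append("commission")

        if "validate" in dag:
            table = {}
            zg = np.arange(0.0, 30.001, 0.2)
            for label, model in models.items():
                scan = scans[label]
                pdd10 = dose_mod.openfield_pdd(model, 10.0, zg)
                entry = {"d_max_cm": extract_dmax(zg, pdd10),
                         "dd10_percent": extract_dd10(zg, pdd10),
                         "gamma": {}}
                for w, (d, p) in scan.pdd_curves.items():
                    rec = dose_mod.openfield_pdd(model, w, zg)
                    crit = (3.0, 0.3) if w >= 40.0 else (2.0, 0.2)
                    g = ev.gamma_index((d, p), (zg, rec), dose_percent=crit[0],
                                       dta=crit[1])
                    entry["gamma"][f"{w:g}"] = {
                        "criteria": f"{crit[0]:g}%/{10*crit[1]:g}mm",
                        "pass_fraction": g.pass_fraction,
                    }
                table[label] = entry
            report["beam_quality"] = table
            manifest.stages_completed.append("validate")

        if "plan" in dag:
            pc = cfg["plan"]
            phantom, structures = planning_phantom(
                target_depth=pc["target_depth_cm"], voxel=pc["voxel_cm"])
            setups = _plan_setups(phantom, structures, pc)
            rx = pc["prescription_gy"]
            objectives = [
                ObjectiveSpec("ptv", "squared_deviation", rx, 100.0),
                ObjectiveSpec("oar_distal", "squared_overdose", 0.3 * rx, 30.0),
                ObjectiveSpec("oar_lateral", "squared_overdose", 0.3 * rx, 30.0),
                ObjectiveSpec("body", "squared_overdose", 1.05 * rx, 10.0),
            ]
            plan_report = {}
            plans = {}
            for label, model in models.items():
                infl = dose_mod.influence_matrix(model, phantom, setups,
                                                 mask=structures["body"])
                res = optimize_fluence(infl, objectives, structures)
                res.segment_widths = segment_width_range(setups, res.weights)
                plans[label] = (res, phantom, structures, setups)
                plan_report[label] = {"objective": res.objective_trace[-1],
                                      "converged": res.converged}
            report["plan"] = plan_report
            manifest.stages_completed.append("plan")

        if "evaluate" in dag and "plan" in manifest.stages_completed:
            table = {}
            for label, (res, phantom, structures, setups) in plans.items():
                idx = ev.dose_indices(res.dose, structures,
                                      voxel_volume=phantom.voxel_volume)
                table[label] = {
                    "indices": idx.per_structure,
                    "integral_dose_gy": ev.integral_dose(res.dose, structures["body"]),
                    "avg_radiological_depth_cm": ev.average_radiological_depth(
                        phantom, setups, structures["ptv"]),
                    "segment_width_range_cm": res.segment_widths,
                }
            report["evaluation"] = table
            manifest.stages_completed.append("evaluate")

        if "mc" in dag:
            report["mc"] = _mc_stage(cfg, models, out_dir, seed)
            manifest.stages_completed.append("mc")
        else:
            report["mc"] = "skipped"
            manifest.stages_skipped.append("mc")
    except Exception as exc:  # halt downstream stages, record partial run
        manifest.failed_stage = next((s for s in dag
                                      if s not in manifest.stages_completed), None)
        report["error"] = f"{type(exc).__name__}: {exc}"
        log.exception("stage %s failed", manifest.failed_stage)

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=_jsonify))
    manifest.outputs["report"] = report_path.name
    manifest.finished = time.time()
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _plan_setups(phantom, structures, pc):
    xx, yy, zz = phantom.center_grids()
    ids = np.flatnonzero(structures["ptv"].ravel())
    iso = (float(xx.ravel()[ids].mean()), float(yy.ravel()[ids].mean()),
           float(zz.ravel()[ids].mean()))
    # aperture: PTV bounding square + 1 cm margin
    r_ptv = 0.5 * (xx.ravel()[ids].max() - xx.ravel()[ids].min()) + 1.0
    n = max(int(np.ceil(2 * r_ptv / pc["bixel_width_cm"])), 1)
    return [dose_mod.BeamSetup(gantry_deg=g, isocenter=iso,
                               bixel_width=pc["bixel_width_cm"], n_bixels=(n, n))
            for g in pc["gantry_angles_deg"]]


def _mc_stage(cfg, models, out_dir, seed):
    from .mc import bone_experiment, transport, tune_spectrum
    from .phantoms import water_cube

    mcc = cfg["mc"]
    label = next((l for l in models if "2.5" in l), next(iter(models)))
    model = models[label]
    z = (np.arange(150) + 0.5) * 0.2
    ref = dose_mod.openfield_pdd(model, 10.0, z)
    spectrum = generate_spectrum()
    tuned, tune_report = tune_spectrum(spectrum, (z, ref),
                                       budget=mcc["tuning_budget"], seed=seed + 1)
    kern = tune_report["buildup_kernel"]
    tuned.to_csv(out_dir / "tuned_spectrum.csv")
    tg = transport(tuned, water_cube(voxel=0.5), n_histories=mcc["histories"],
                   seed=seed + 1, buildup_kernel=kern)
    diff = tg.pdd - ref
    beyond = z > z[np.argmax(ref)] + 0.2
    out = {
        "tuning": {k: v for k, v in tune_report.items()
                   if k not in ("group_scales", "group_bounds", "buildup_kernel")},
        "water_agreement": {
            "max_diff_falloff_percent": float(np.max(np.abs(diff[beyond]))),
            "max_diff_buildup_percent": float(np.max(np.abs(diff[~beyond]))),
        },
        "bone": {},
    }
    for preset in mcc["presets"]:
        r = bone_experiment(preset, tuned, n_histories=mcc["histories"],
                            seed=seed + 1, buildup_kernel=kern)
        out["bone"][preset] = {k: v for k, v in r.items()
                               if not k.startswith("tally")}
    return out


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
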