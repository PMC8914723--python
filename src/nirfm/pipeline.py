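"""End-to-end pipeline: simulate → preprocess/fit → select → refit → imaging.

A run is driven by a JSON configuration validated against the schema shipped
in ``nirfm/schema/pipeline.schema.json`` (a small built-in checker enforces
it: unknown keys, wrong types and out-of-range values are errors).  Every
stage seeds its randomness from the single configured seed, so re-running an
identical configuration reproduces all numeric outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from . import __version__
from .core import stratified_split
from .imaging import evaluate_band_combinations
from .plsda import choose_n_lv, evaluate_model, fit_plsda
from .preprocess import apply_preprocessing
from .select import (
    ipls_select,
    refit_with_bands,
    sfs_select,
    spa_select,
    table4_style_rows,
    vip_select,
    wrc_select,
)
from .synthesize import (
    default_grid,
    demo_scene_specs,
    simulate_demo_spectra,
    simulate_hypercube,
)

__all__ = ["PipelineConfigError", "load_schema", "validate_config", "run_pipeline"]

DEFAULT_COMBINATIONS = [
    [1150, 1400, 1731, 1880, 1920],
    [1150, 1400, 1450, 1731, 1880, 1920],
    [1150, 1400, 1450, 1731, 1880, 1920, 2114],
]

_DEFAULTS = {
    "spectra": {"n_veg": 140, "n_fm": 160, "grid_points": 389,
                "include_water_mimic": False},
    "preprocess": {"methods": ["mean", "max", "range", "msc", "snv",
                               "sg1", "sg2", "raw"],
                   "window": 11, "polyorder": 2},
    "split": {"calibration_fraction": 0.7},
    "pls": {"max_lv": 10, "folds": 5, "autoscale": False},
    "selection": {
        "wrc": {"k": 5, "min_separation_nm": 30.0},
        "vip": {"n_lv": 5, "folds": 5},
        "sfs": {"max_features": 10, "folds": 20},
        "spa": {"min_vars": 2, "max_vars": 10, "folds": 5},
        "ipls": {"interval_width": 1, "max_lv": 5,
                 "max_intervals_selected": 10, "folds": 5},
    },
    "imaging": {"n_scenes": 7, "lines": 96, "pixels": 128,
                "include_water_mimic": True, "noise_scale": 1.0,
                "min_blob": 5, "median_filter": True,
                "combinations": DEFAULT_COMBINATIONS},
}


class PipelineConfigError(ValueError):
    """Raised when a pipeline configuration violates the schema."""


def load_schema() -> dict:
    text = (
        resources.files("nirfm") / "schema" / "pipeline.schema.json"
    ).read_text(encoding="utf-8")
    return json.loads(text)


def _check(node, schema, path: str) -> None:
    kind = schema.get("type")
    if kind == "object":
        if not isinstance(node, dict):
            raise PipelineConfigError(f"{path}: expected an object")
        props = schema.get("properties", {})
        if not schema.get("additionalProperties", True):
            for key in node:
                if key not in props:
                    raise PipelineConfigError(f"{path}: unknown key {key!r}")
        for key in schema.get("required", []):
            if key not in node:
                raise PipelineConfigError(f"{path}: missing required key {key!r}")
        for key, sub in props.items():
            if key in node:
                _check(node[key], sub, f"{path}.{key}")
    elif kind == "array":
        if not isinstance(node, list):
            raise PipelineConfigError(f"{path}: expected an array")
        for i, item in enumerate(node):
            _check(item, schema.get("items", {}), f"{path}[{i}]")
    elif kind == "integer":
        if not isinstance(node, int) or isinstance(node, bool):
            raise PipelineConfigError(f"{path}: expected an integer")
    elif kind == "number":
        if not isinstance(node, (int, float)) or isinstance(node, bool):
            raise PipelineConfigError(f"{path}: expected a number")
    elif kind == "boolean":
        if not isinstance(node, bool):
            raise PipelineConfigError(f"{path}: expected a boolean")
    elif kind == "string":
        if not isinstance(node, str):
            raise PipelineConfigError(f"{path}: expected a string")
    if kind in ("integer", "number") and not isinstance(node, bool):
        if "minimum" in schema and node < schema["minimum"]:
            raise PipelineConfigError(f"{path}: below minimum {schema['minimum']}")
        if "exclusiveMinimum" in schema and node <= schema["exclusiveMinimum"]:
            raise PipelineConfigError(f"{path}: must exceed {schema['exclusiveMinimum']}")
        if "exclusiveMaximum" in schema and node >= schema["exclusiveMaximum"]:
            raise PipelineConfigError(f"{path}: must be below {schema['exclusiveMaximum']}")


def _merge_defaults(raw: dict) -> dict:
    merged = {"seed": raw["seed"], "output_dir": raw["output_dir"]}
    for section, defaults in _DEFAULTS.items():
        got = dict(raw.get(section, {}))
        block = {}
        for key, value in defaults.items():
            if isinstance(value, dict):
                inner = dict(value)
                inner.update(got.get(key, {}))
                block[key] = inner
            else:
                block[key] = got.get(key, value)
        merged[section] = block
    return merged


def validate_config(raw: dict) -> dict:
    """Validate a raw config dict and fill in defaults."""
    _check(raw, load_schema(), "config")
    return _merge_defaults(raw)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __init__(self, stage_name):
            self.stage_name = stage_name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineConfigError):
                raise RuntimeError(f"pipeline stage '{self.stage_name}' failed: {exc}") from exc
            return False
    return _Ctx(name)


def run_pipeline(raw_config: dict) -> Path:
    """Execute the full study pipeline; returns the run directory.

    Writes: ``preprocessing_models.csv`` (one PLS-DA per treatment, the
    calibration/validation summary), ``selection_<method>.json`` traces,
    ``selected_wavelengths.csv``, ``reduced_models.csv`` (refits on the
    selected bands), ``band_combinations.csv`` (image detection per band
    subset) and a ``manifest.json`` with the config hash and versions.
    """
    cfg = validate_config(raw_config)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    with _stage("simulate"):
        sp = cfg["spectra"]
        grid = default_grid(sp["grid_points"])
        spectra = simulate_demo_spectra(
            n_veg=sp["n_veg"], n_fm=sp["n_fm"], grid=grid, seed=seed,
            include_water_mimic=sp["include_water_mimic"],
        )

    with _stage("preprocess+fit"):
        pls = cfg["pls"]
        pre = cfg["preprocess"]
        frac = cfg["split"]["calibration_fraction"]
        rows = []
        for method in pre["methods"]:
            treated = apply_preprocessing(
                spectra, method, window=pre["window"], polyorder=pre["polyorder"]
            )
            cal, val = stratified_split(treated, frac, seed + 1)
            max_lv = min(pls["max_lv"], cal.n_samples - 1, cal.n_wavelengths)
            n_lv = choose_n_lv(cal, max_lv=max_lv, folds=pls["folds"], seed=seed + 2)
            model = fit_plsda(cal, n_lv=n_lv, autoscale=pls["autoscale"])
            for tag, part in (("calibration", cal), ("validation", val)):
                row = evaluate_model(model, part, partition_tag=tag).row()
                row["preprocessing"] = method
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "preprocessing_models.csv", index=False)

    with _stage("select"):
        cal_raw, val_raw = stratified_split(spectra, frac, seed + 1)
        sel_cfg = cfg["selection"]
        wrc_model = fit_plsda(
            cal_raw,
            n_lv=choose_n_lv(cal_raw, max_lv=min(pls["max_lv"], cal_raw.n_samples - 1),
                             folds=pls["folds"], seed=seed + 2),
            autoscale=True,
        )
        selections = {
            "wrc": wrc_select(
                wrc_model, k=sel_cfg["wrc"]["k"],
                min_separation=sel_cfg["wrc"]["min_separation_nm"],
            ),
            "vip": vip_select(cal_raw, n_lv=sel_cfg["vip"]["n_lv"],
                              folds=sel_cfg["vip"]["folds"], seed=seed + 3),
            "sfs": sfs_select(cal_raw, max_features=sel_cfg["sfs"]["max_features"],
                              folds=sel_cfg["sfs"]["folds"], seed=seed + 4),
            "spa": spa_select(cal_raw, min_vars=sel_cfg["spa"]["min_vars"],
                              max_vars=sel_cfg["spa"]["max_vars"],
                              folds=sel_cfg["spa"]["folds"], seed=seed + 5),
            "ipls": ipls_select(
                cal_raw, interval_width=sel_cfg["ipls"]["interval_width"],
                max_lv=sel_cfg["ipls"]["max_lv"],
                max_intervals_selected=sel_cfg["ipls"]["max_intervals_selected"],
                folds=sel_cfg["ipls"]["folds"], seed=seed + 6,
            ),
        }
        summary = []
        for method, sel in selections.items():
            (out / f"selection_{method}.json").write_text(sel.to_json())
            summary.append({
                "method": method,
                "n_selected": sel.n_selected,
                "wavelengths_nm": ", ".join(
                    f"{w:.0f}" for w in sel.selected_wavelengths
                ),
            })
        pd.DataFrame(summary).to_csv(out / "selected_wavelengths.csv", index=False)

    with _stage("refit"):
        reports = {
            method: refit_with_bands(cal_raw, sel, test=val_raw, seed=seed + 7)
            for method, sel in selections.items()
        }
        pd.DataFrame(table4_style_rows(reports)).to_csv(
            out / "reduced_models.csv", index=False
        )

    with _stage("evaluate-image"):
        img = cfg["imaging"]
        scenes = demo_scene_specs(
            n_scenes=img["n_scenes"], lines=img["lines"], pixels=img["pixels"],
            include_water_mimic=img["include_water_mimic"],
            noise_scale=img["noise_scale"], seed=seed + 8,
        )
        cubes = [
            (f"scene_{i}", simulate_hypercube(scene, seed=seed + 9 + i))
            for i, scene in enumerate(scenes)
        ]
        training = simulate_demo_spectra(
            n_veg=sp["n_veg"], n_fm=sp["n_fm"], grid=default_grid(sp["grid_points"]),
            seed=seed + 20, include_water_mimic=img["include_water_mimic"],
        )
        ranked = evaluate_band_combinations(
            cubes, training, img["combinations"],
            min_blob=img["min_blob"], median_filter=img["median_filter"],
            folds=pls["folds"], seed=seed + 21,
        )
        combo_rows = [
            {"bands_nm": ", ".join(f"{w:.0f}" for w in combo),
             "n_bands": len(combo),
             "total_fms": rep.total_fms,
             "detected_fms": rep.detected_fms,
             "false_positives": rep.false_positives,
             "overall_accuracy_pct": round(rep.overall_accuracy, 2)}
            for combo, rep in ranked
        ]
        pd.DataFrame(combo_rows).to_csv(out / "band_combinations.csv", index=False)

    with _stage("manifest"):
        manifest = {
            "nirfm_version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "seed": seed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
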