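"""Run orchestration: one config drives synth -> demand -> allocation -> quality.

A run is described by a single YAML-able mapping (see ``default_config``).
``run_pipeline`` executes the stages in dependency order, writes every
intermediate artifact (ESRI ASCII rasters, CSV tables) under the output
directory, and returns a manifest recording inputs, parameters, seeds and
SHA-256 checksums of all outputs — identical config and seeds give identical
checksums.  The transition matrix and the fitted suitability network are
shared across scenarios, so scenario maps differ only through demand,
probability edits, cost matrices and the allocation draws.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import ca, changes, habitat, suitability
from .grids import CLASS_LABELS, CategoricalRaster, write_raster
from .markov import (BUILTIN_SCENARIOS, apply_scenario, constrain_to_cost,
                     estimate_transition, project_demand, round_demand)
from .synthetic import SyntheticConfig, generate_fixture

__all__ = ["default_config", "validate_config", "run_pipeline"]


def default_config() -> dict[str, Any]:
    """A complete runnable configuration on synthetic inputs."""
    return {
        "output_dir": "flusim_run",
        "seed": 42,
        "synth": {"shape": [200, 200], "cell_size": 100.0, "smoothness": 4.0},
        "scenarios": ["natural", "cultivated_protection", "ecological_protection"],
        "steps": 3,
        "suitability": {"n_samples": 5000, "hidden_units": 12},
        "ca": {"tol": 0.002, "max_iter": 300},
        "habitat": {"half_saturation": 0.5},
    }


def validate_config(config: dict[str, Any]) -> list[str]:
    """Check cross-references and parameter ranges; returns all errors found."""
    errors: list[str] = []
    if not isinstance(config.get("seed", 0), int):
        errors.append("seed must be an integer")
    for name in config.get("scenarios", []):
        if name not in BUILTIN_SCENARIOS:
            errors.append(f"unknown scenario name {name!r}")
    if config.get("steps", 1) < 1:
        errors.append("steps must be >= 1")
    synth = config.get("synth")
    if synth is not None:
        shape = synth.get("shape", [200, 200])
        if min(shape) < 3:
            errors.append("synth shape must be at least 3x3")
        if synth.get("cell_size", 100.0) <= 0:
            errors.append("synth cell_size must be positive")
        if synth.get("smoothness", 4.0) <= 0:
            errors.append("synth smoothness must be positive")
    suit = config.get("suitability", {})
    if suit.get("hidden_units", 12) < 1:
        errors.append("suitability hidden_units must be >= 1")
    if suit.get("n_samples", 5000) < 60:
        errors.append("suitability n_samples too small (< 60)")
    ca_cfg = config.get("ca", {})
    if not 0 < ca_cfg.get("tol", 0.002) < 1:
        errors.append("ca tol must lie in (0, 1)")
    if ca_cfg.get("max_iter", 300) < 1:
        errors.append("ca max_iter must be >= 1")
    if config.get("habitat", {}).get("half_saturation", 0.5) <= 0:
        errors.append("habitat half_saturation must be positive")
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, Any], stages: tuple[str, ...] = ("synth", "simulate", "habitat")) -> dict[str, Any]:
    """Execute the configured stages and return the run manifest."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(config.get("output_dir", "flusim_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 42))
    manifest: dict[str, Any] = {"config": config, "seed": seed, "outputs": {}, "stages": []}

    def _save_raster(raster, name: str) -> Path:
        path = out_dir / f"{name}.asc"
        write_raster(raster, path)
        manifest["outputs"][path.name] = _sha256(path)
        return path

    def _save_frame(frame: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=index)
        manifest["outputs"][path.name] = _sha256(path)
        return path

    # --- synthetic fixtures -------------------------------------------------
    stage = "synth"
    try:
        synth_cfg = config.get("synth", {})
        scfg = SyntheticConfig(
            shape=tuple(synth_cfg.get("shape", (200, 200))),
            cell_size=float(synth_cfg.get("cell_size", 100.0)),
            smoothness=float(synth_cfg.get("smoothness", 4.0)),
            seed=seed,
        )
        fixture = generate_fixture(scfg)
        _save_raster(fixture.lu_t0, "landuse_t0")
        _save_raster(fixture.lu_t1, "landuse_t1")
        for name in fixture.drivers.names:
            _save_raster(fixture.drivers[name], f"driver_{name}")
        manifest["stages"].append(stage)
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    if "simulate" not in stages:
        _save_frame(pd.DataFrame(), "manifest_placeholder")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # --- demand + suitability (shared across scenarios) ---------------------
    stage = "simulate"
    scenario_maps: dict[str, CategoricalRaster] = {}
    try:
        transition = estimate_transition(fixture.lu_t0, fixture.lu_t1)
        _save_frame(transition.to_frame(), "transition_probs")
        suit_cfg = config.get("suitability", {})
        ss = np.random.SeedSequence([seed, 7])
        s_train, s_fit, s_alloc = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3))
        valid = fixture.lu_t1.valid_mask & fixture.drivers.valid_mask
        n_samples = min(int(suit_cfg.get("n_samples", 5000)), int(valid.sum()))
        table = suitability.sample_training(fixture.lu_t1, fixture.drivers, n_samples, seed=s_train)
        model = suitability.fit_suitability(
            table, hidden_units=int(suit_cfg.get("hidden_units", 12)), seed=s_fit)
        surfaces = suitability.predict_suitability(model, fixture.drivers)
        counts = fixture.lu_t1.class_counts().astype(float)
        ca_cfg = config.get("ca", {})
        demands = {}
        for name in config.get("scenarios", ["natural"]):
            spec = BUILTIN_SCENARIOS[name]
            edited = constrain_to_cost(apply_scenario(transition, spec), spec)
            demand = round_demand(
                project_demand(counts, edited, steps=int(config.get("steps", 3))),
                int(valid.sum()))
            demands[name] = demand
            result = ca.roulette_allocate(
                fixture.lu_t1, surfaces, demand, spec,
                seed=s_alloc, max_iter=int(ca_cfg.get("max_iter", 300)),
                tol=float(ca_cfg.get("tol", 0.002)))
            scenario_maps[name] = result.raster
            _save_raster(result.raster, f"landuse_{name}")
            _save_frame(result.history, f"convergence_{name}")
        _save_frame(
            pd.DataFrame(demands, index=list(CLASS_LABELS)).T, "projected_demand")
        _save_frame(
            changes.compare_scenarios(fixture.lu_t1, scenario_maps),
            "scenario_comparison", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    if "habitat" not in stages:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # --- habitat quality -----------------------------------------------------
    stage = "habitat"
    try:
        k = float(config.get("habitat", {}).get("half_saturation", 0.5))
        summaries = []
        for name, lu in {"base": fixture.lu_t1, **scenario_maps}.items():
            result = habitat.assess(lu, roads=fixture.roads, k=k)
            _save_raster(result.quality, f"quality_{name}")
            row = result.summary.copy()
            row.insert(0, "map", name)
            summaries.append(row)
        _save_frame(pd.concat(summaries, ignore_index=True), "quality_summary", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
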