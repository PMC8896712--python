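"""Orchestration: run configurations, the scenario registry, and tabular
outputs for lateral fixation-offset sweep analyses.

A :class:`RunConfig` bundles a scenario specification (generator kind plus
parameters, with an optional perturbation list), the retinal grid spec and
analysis options, and a seed.  Every run writes a manifest (config echo +
seed) sufficient to reproduce it byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calib as calib_mod
from . import foe as foe_mod
from . import synth
from .retflow import RetinalGridSpec, analyze_scenario

log = logging.getLogger("gazeflow")

SCENARIO_GENERATORS = {
    "straight_approach": synth.straight_approach,
    "sinusoid": synth.sinusoid_trajectory,
    "corkscrew": synth.corkscrew_trajectory,
    "gait_head": synth.gait_head_trajectory,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration for a scenario run."""

    scenario: dict
    retinal: dict = dataclass_field(default_factory=dict)
    ground_spacing: float = 0.25
    max_ground_distance: float = 15.0
    foveal_window_deg: float = 2.0
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "retinal": self.retinal,
            "ground_spacing": self.ground_spacing,
            "max_ground_distance": self.max_ground_distance,
            "foveal_window_deg": self.foveal_window_deg,
            "seed": self.seed,
        }

    def retinal_spec(self) -> RetinalGridSpec:
        return RetinalGridSpec(**self.retinal)


def build_scenario(spec: dict, seed: int | None = None) -> synth.Scenario:
    """Instantiate a scenario from a generator spec:
    ``{"kind": ..., "params": {...}, "perturbations": [...]}``."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in SCENARIO_GENERATORS:
        raise ConfigError(
            f"unknown scenario kind {kind!r}; expected one of "
            f"{sorted(SCENARIO_GENERATORS)}"
        )
    params = dict(spec.pop("params", {}))
    perts = spec.pop("perturbations", [])
    if spec:
        raise ConfigError(f"unknown scenario keys: {sorted(spec)}")
    if seed is not None:
        params.setdefault("seed", seed)
    scenario = SCENARIO_GENERATORS[kind](**params)
    for p in perts:
        scenario = synth.apply_perturbation(scenario, synth.Perturbation(**p))
    return scenario


def _write_manifest(outdir: Path, config: RunConfig, stage: str) -> None:
    manifest = {"stage": stage, "seed": config.seed, "config": config.to_dict()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_scenario(config: RunConfig, keep_frames: bool = False):
    """Execute synth -> eyemodel -> retflow per frame; returns the
    per-frame feature table (and frames when requested), writing
    features.csv and a manifest when an output directory is configured."""
    scenario = build_scenario(config.scenario, config.seed)
    log.info("scenario %s: %d frames at %g fps", scenario.kind, scenario.n_frames, scenario.fps)
    try:
        df, frames = analyze_scenario(
            scenario,
            spec=config.retinal_spec(),
            ground_spacing=config.ground_spacing,
            max_ground_distance=config.max_ground_distance,
            foveal_window_deg=config.foveal_window_deg,
            keep_frames=keep_frames,
        )
    except Exception as exc:
        raise RuntimeError(f"retflow stage failed: {exc}") from exc
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "features.csv", index=False, float_format="%.10g")
        _write_manifest(outdir, config, "analyze")
    return (df, frames) if keep_frames else df


def sweep_offsets(config: RunConfig, offsets) -> pd.DataFrame:
    """Re-run a straight-approach scenario across lateral fixation offsets.

    Returns per (offset, frame) rows of the feature columns (the
    heading-angle scatter:
    velocity->fixation angle on x, foveal curl or max-divergence angle on
    y, one dot per frame)."""
    offsets = list(offsets)
    if len(offsets) < 2:
        raise ConfigError("need at least 2 offsets to sweep")
    tables = []
    for off in offsets:
        sub = RunConfig(**{**config.to_dict(), "outdir": None})
        sub.scenario = json.loads(json.dumps(config.scenario))
        sub.scenario.setdefault("params", {})["fixation_offset_angle"] = float(off)
        df = run_scenario(sub)
        df.insert(0, "offset_deg", float(off))
        tables.append(df)
    out = pd.concat(tables, ignore_index=True)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "sweep.csv", index=False, float_format="%.10g")
        _write_manifest(outdir, config, "sweep")
    return out


def run_foe(config: RunConfig, camera: foe_mod.CameraSpec | None = None) -> pd.DataFrame:
    """Head-centered FoE track for the configured scenario."""
    scenario = build_scenario(config.scenario, config.seed)
    df = foe_mod.track_scenario(scenario, camera=camera)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "foe.csv", index=False, float_format="%.10g")
        _write_manifest(outdir, config, "foe")
    return df


def run_calibration(session: calib_mod.CalibrationSession, outdir: str | None = None):
    """Fit the gaze-alignment rotation for a session and optionally write
    the structured report."""
    result = calib_mod.fit_alignment(session)
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        report = {
            "euler_deg": [float(v) for v in result.euler_deg],
            "residual_error_m": result.residual_error,
            "scatter_rms_m": result.scatter_rms,
            "n_frames": result.n_frames,
            "converged": result.converged,
        }
        (out / "alignment.json").write_text(json.dumps(report, indent=2))
    return result
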