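"""Configuration files, voxel-grid persistence and run manifests.

A single YAML file configures the whole pipeline; every default equals the
design constants of the reference problem (1 mm cells, 100-400 um pores,
1000-2700 N/mm axial stiffness with E = 1.8 GPa and D = L = 30 mm, dt =
1e-4, 21-day horizon).  Unknown keys are rejected so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from .geometry import ScaffoldSpec, VoxelGrid
from .growth import GrowthParams
from .optimize import ConstraintConfig
from .pore_metrics import PoreLimits
from .stiffness import StiffnessEnvelope

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "write_grid",
    "read_grid",
    "save_spec",
    "load_spec",
]


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


_SECTIONS = {
    "pores": {"d_lo_um", "d_hi_um", "resolution"},
    "stiffness": {"E_Pa", "D_mm", "L_mm", "k_lo_N_mm", "k_hi_N_mm"},
    "growth": {"dt", "lambda_mm2_day", "max_days", "fill_threshold",
               "resolution", "fill_fraction"},
    "optimise": {"vf_sweep", "stiffness_mode", "manual_windows",
                 "growth_sweep_points", "cache_dir", "use_published_windows"},
    "geometry": {"cell_size_mm"},
}


def _check_keys(section: str, data: Dict[str, Any]):
    unknown = set(data) - _SECTIONS[section]
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)}; "
            f"allowed: {sorted(_SECTIONS[section])}")


def load_config(path) -> ConstraintConfig:
    """Read a YAML config; missing fields fall back to the design defaults.

    An empty file yields the full default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}; "
                          f"allowed: {sorted(_SECTIONS)}")
    for sec, data in raw.items():
        if data is None:
            raw[sec] = {}
        elif not isinstance(data, dict):
            raise ConfigError(f"section '{sec}' must be a mapping")
        else:
            _check_keys(sec, data)

    p = raw.get("pores", {})
    try:
        limits = PoreLimits(d_lo=float(p.get("d_lo_um", 100.0)),
                            d_hi=float(p.get("d_hi_um", 400.0)))
    except ValueError as exc:
        raise ConfigError(f"pores: {exc}") from exc

    s = raw.get("stiffness", {})
    try:
        env = StiffnessEnvelope(E=float(s.get("E_Pa", 1.8e9)),
                                D=float(s.get("D_mm", 30.0)),
                                L=float(s.get("L_mm", 30.0)),
                                k_lo=float(s.get("k_lo_N_mm", 1000.0)),
                                k_hi=float(s.get("k_hi_N_mm", 2700.0)))
    except ValueError as exc:
        raise ConfigError(f"stiffness: {exc}") from exc

    g = raw.get("growth", {})
    try:
        gp = GrowthParams(dt=float(g.get("dt", 1e-4)),
                          lambda_coef=float(g.get("lambda_mm2_day", 1.0)),
                          max_days=float(g.get("max_days", 21.0)),
                          fill_threshold=float(g.get("fill_threshold", 0.005)))
    except ValueError as exc:
        raise ConfigError(f"growth: {exc}") from exc

    o = raw.get("optimise", {})
    geo = raw.get("geometry", {})
    manual = o.get("manual_windows")
    if o.get("use_published_windows"):
        from .optimize import PUBLISHED_WINDOWS
        manual = dict(PUBLISHED_WINDOWS)
    try:
        cfg = ConstraintConfig(
            pore_limits=limits,
            envelope=env,
            growth_params=gp,
            pore_resolution=int(p.get("resolution", 60)),
            growth_resolution=int(g.get("resolution", 64)),
            cell_size=float(geo.get("cell_size_mm", 1.0)),
            stiffness_mode=str(o.get("stiffness_mode", "report")),
            manual_windows=manual,
            growth_sweep_points=int(o.get("growth_sweep_points", 3)),
            cache_dir=o.get("cache_dir"),
            **({"vf_sweep": tuple(float(v) for v in o["vf_sweep"])}
               if "vf_sweep" in o else {}),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def save_config(cfg: ConstraintConfig, path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    data = {
        "geometry": {"cell_size_mm": cfg.cell_size},
        "pores": {"d_lo_um": cfg.pore_limits.d_lo,
                  "d_hi_um": cfg.pore_limits.d_hi,
                  "resolution": cfg.pore_resolution},
        "stiffness": {"E_Pa": cfg.envelope.E, "D_mm": cfg.envelope.D,
                      "L_mm": cfg.envelope.L,
                      "k_lo_N_mm": cfg.envelope.k_lo,
                      "k_hi_N_mm": cfg.envelope.k_hi},
        "growth": {"dt": cfg.growth_params.dt,
                   "lambda_mm2_day": cfg.growth_params.lambda_coef,
                   "max_days": cfg.growth_params.max_days,
                   "fill_threshold": cfg.growth_params.fill_threshold,
                   "resolution": cfg.growth_resolution},
        "optimise": {"vf_sweep": list(cfg.vf_sweep),
                     "stiffness_mode": cfg.stiffness_mode,
                     "manual_windows": ({k: list(v) for k, v in cfg.manual_windows.items()}
                                        if cfg.manual_windows else None),
                     "growth_sweep_points": cfg.growth_sweep_points,
                     "cache_dir": cfg.cache_dir},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_grid(grid: VoxelGrid, path) -> None:
    """Persist a voxel grid as .npy occupancy plus a JSON sidecar.

    The sidecar (<path>.json) carries spacing and origin at full precision,
    so read_grid round-trips losslessly.
    """
    path = Path(path)
    np.save(path, grid.occupancy)
    meta = {"spacing": grid.spacing, "origin": list(grid.origin),
            "format": "tpmsopt-voxelgrid-v1"}
    path.with_suffix(path.suffix + ".json" if path.suffix != ".npy"
                     else ".npy.json").write_text(json.dumps(meta))


def read_grid(path) -> VoxelGrid:
    """Load a voxel grid written by :func:`write_grid`."""
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(path.suffix + ".npy")
    occ = np.load(path)
    if occ.ndim != 3:
        raise ValueError(f"expected a 3-D occupancy array, got ndim={occ.ndim}")
    meta_path = path.with_suffix(".npy.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing grid metadata sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
        spacing = float(meta["spacing"])
        origin = tuple(meta.get("origin", (0.0, 0.0, 0.0)))
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt grid metadata in {meta_path}: {exc}") from exc
    return VoxelGrid(occupancy=occ.astype(bool), spacing=spacing, origin=origin)


def save_spec(spec: ScaffoldSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_spec(path) -> ScaffoldSpec:
    return ScaffoldSpec.from_dict(yaml.safe_load(Path(path).read_text()))
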