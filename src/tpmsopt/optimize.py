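"""Constrained selection of scaffold type and volume fraction.

The design space is (TPMS type, volume fraction).  Pore-size limits and the
axial-stiffness window each map to an admissible volume-fraction interval
per type; their intersection is the final window, inside which the
volume fraction maximising the average cell growth rate is selected.
Because growth rate decreases monotonically with volume fraction for every
type, the optimum sits at the window minimum whenever the window is
non-empty.

A long-standing quirk of this design problem is that the Gibson-Ashby
stiffness window computed from the published scaling constants and the
printed material/geometry defaults lies *below* the pore-size window for
every type, so a strict intersection would be empty.  The published
admissible windows coincide with pore-size crossings instead.  The default
pipeline therefore treats the pore window as binding and reports the
stiffness window alongside with its provenance; ``stiffness_mode`` can
force the strict intersection, and ``manual_windows`` lets reproduction
runs supply the published per-type limits directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import TPMS_TYPES, _canonical_type
from .growth import GrowthParams, simulate_type
from .pore_metrics import PoreLimits, PoreWindow, pore_window
from .stiffness import TABLE_LAWS, StiffnessEnvelope, stiffness_window

__all__ = [
    "ConstraintConfig",
    "TypeResult",
    "OptimisationResult",
    "PUBLISHED_WINDOWS",
    "constraint_windows",
    "growth_sweep",
    "select_optimum",
    "run_optimisation",
    "report",
]

log = logging.getLogger(__name__)

#: Published admissible volume-fraction windows (pore + stiffness applied),
#: usable as manual window input for reproduction runs.
PUBLISHED_WINDOWS: Dict[str, Tuple[float, float]] = {
    "gyroid": (0.47, 0.66),
    "split_p": (0.44, 0.54),
    "diamond": (0.44, 0.66),
    "lidinoid": (0.49, 0.59),
}


@dataclasses.dataclass
class ConstraintConfig:
    """All knobs of the optimisation pipeline (defaults: design values)."""

    pore_limits: PoreLimits = dataclasses.field(default_factory=PoreLimits)
    envelope: StiffnessEnvelope = dataclasses.field(default_factory=StiffnessEnvelope)
    vf_sweep: Tuple[float, ...] = tuple(np.round(np.arange(0.2, 0.901, 0.05), 3))
    pore_resolution: int = 60
    growth_resolution: int = 64
    growth_params: GrowthParams = dataclasses.field(default_factory=GrowthParams)
    cell_size: float = 1.0
    stiffness_mode: str = "report"       # "report" | "strict"
    manual_windows: Optional[Dict[str, Tuple[float, float]]] = None
    growth_sweep_points: int = 3         # window edges + interior points
    cache_dir: Optional[str] = None

    def __post_init__(self):
        sweep = tuple(float(v) for v in self.vf_sweep)
        if list(sweep) != sorted(sweep):
            raise ValueError("vf_sweep must be sorted ascending")
        if sweep and not (0.2 <= sweep[0] and sweep[-1] <= 0.9):
            raise ValueError("vf_sweep must lie within [0.2, 0.9]")
        if self.stiffness_mode not in ("report", "strict"):
            raise ValueError("stiffness_mode must be 'report' or 'strict'")
        self.vf_sweep = sweep
        if self.manual_windows:
            self.manual_windows = {_canonical_type(k): (float(a), float(b))
                                   for k, (a, b) in self.manual_windows.items()}


@dataclasses.dataclass
class TypeResult:
    """Windows, growth curve and optimum for one TPMS type."""

    tpms_type: str
    pore_window: Optional[Tuple[float, float]]
    stiffness_window: Optional[Tuple[float, float]]
    final_window: Optional[Tuple[float, float]]
    window_provenance: str = ""
    exclusion_reason: Optional[str] = None
    sweep_vfs: List[float] = dataclasses.field(default_factory=list)
    sweep_rates: List[Optional[float]] = dataclasses.field(default_factory=list)
    optimal_vf: Optional[float] = None
    max_rate: Optional[float] = None

    @property
    def excluded(self) -> bool:
        return self.final_window is None


@dataclasses.dataclass
class OptimisationResult:
    """Per-type results plus the global ranking by maximum growth rate."""

    per_type: Dict[str, TypeResult]
    ranking: List[str]
    config: ConstraintConfig

    @property
    def best(self) -> Optional[TypeResult]:
        return self.per_type[self.ranking[0]] if self.ranking else None


def _intersect(a, b):
    if a is None or b is None:
        return None
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def constraint_windows(types: Sequence[str], config: ConstraintConfig
                       ) -> Dict[str, TypeResult]:
    """Pore window, stiffness window and final admissible window per type.

    With ``manual_windows`` present those intervals are used as the final
    windows (provenance "manual"); otherwise the pore analysis runs and, in
    "strict" mode only, is intersected with the Gibson-Ashby stiffness
    window (see module docstring for why that is not the default).
    """
    out = {}
    for ty in types:
        ty = _canonical_type(ty)
        law = TABLE_LAWS.get(ty)
        s_win = stiffness_window(law, config.envelope) if law else None

        if config.manual_windows is not None:
            if ty in config.manual_windows:
                final = config.manual_windows[ty]
                out[ty] = TypeResult(ty, None, s_win, tuple(final),
                                     window_provenance="manual")
            else:
                out[ty] = TypeResult(ty, None, s_win, None,
                                     window_provenance="manual",
                                     exclusion_reason="no manual window supplied")
            continue

        pw: PoreWindow = pore_window(ty, config.vf_sweep,
                                     resolution=config.pore_resolution,
                                     limits=config.pore_limits,
                                     cell_size=config.cell_size,
                                     refine_to=0.025)
        p_win = pw.as_tuple()
        if config.stiffness_mode == "strict":
            final = _intersect(p_win, s_win)
            provenance = "pore ∩ stiffness"
        else:
            final = p_win
            provenance = "pore (stiffness reported)"
        reason = None
        if final is None:
            reason = pw.exclusion_reason or "pore and stiffness windows do not overlap"
        out[ty] = TypeResult(ty, p_win, s_win, final,
                             window_provenance=provenance, exclusion_reason=reason)
    return out


def _cached_rate(ty: str, vf: float, config: ConstraintConfig) -> Optional[float]:
    """Average growth rate at lambda = 1, with optional on-disk caching."""
    key = None
    if config.cache_dir:
        gp = config.growth_params
        payload = json.dumps([ty, round(vf, 6), config.growth_resolution,
                              config.cell_size, gp.dt, gp.fill_threshold,
                              gp.cfl, gp.reinit_iters], sort_keys=True)
        key = hashlib.sha256(payload.encode()).hexdigest()[:24]
        path = Path(config.cache_dir) / f"growth_{key}.json"
        if path.exists():
            return json.loads(path.read_text())["rate"]
    params = dataclasses.replace(config.growth_params, lambda_coef=1.0)
    curve = simulate_type(ty, vf, resolution=config.growth_resolution,
                          cell_size=config.cell_size, params=params)
    rate = curve.average_rate
    if key is not None:
        Path(config.cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(config.cache_dir) / f"growth_{key}.json").write_text(
            json.dumps({"type": ty, "vf": vf, "rate": rate}))
    return rate


def growth_sweep(ty: str, window: Tuple[float, float],
                 config: ConstraintConfig) -> Tuple[List[float], List[Optional[float]]]:
    """Average growth rate (lambda = 1 units) across the admissible window.

    The window edges are always included; interior sweep points are taken
    from ``vf_sweep`` clipped to the window, thinned to
    ``growth_sweep_points`` total.  Unfilled simulations yield None and are
    excluded from the argmax with a warning.
    """
    lo, hi = window
    pts = sorted({round(lo, 4), round(hi, 4),
                  *(v for v in config.vf_sweep if lo < v < hi)})
    if len(pts) > config.growth_sweep_points:
        idx = np.unique(np.linspace(0, len(pts) - 1,
                                    config.growth_sweep_points).round().astype(int))
        pts = [pts[i] for i in idx]
    rates = []
    for vf in pts:
        r = _cached_rate(ty, vf, config)
        if r is None:
            log.warning("%s at vf=%.3f did not fill within the horizon; "
                        "excluded from the optimum search", ty, vf)
        rates.append(r)
    return pts, rates


def select_optimum(res: TypeResult) -> TypeResult:
    """Argmax of rate within the final window (ties -> lower VF)."""
    best_vf, best_rate = None, None
    for vf, rate in zip(res.sweep_vfs, res.sweep_rates):
        if rate is None:
            continue
        if best_rate is None or rate > best_rate + 1e-15:
            best_vf, best_rate = vf, rate
    res.optimal_vf, res.max_rate = best_vf, best_rate
    return res


def run_optimisation(types: Sequence[str] | None = None,
                     config: ConstraintConfig | None = None) -> OptimisationResult:
    """Full pipeline: windows, growth sweeps, optimum and ranking.

    Growth rates are computed at lambda = 1 (curvature-time units); the
    ranking and optimal volume fractions are invariant to lambda because all
    rates scale together.
    """
    types = list(types) if types is not None else list(TPMS_TYPES)
    config = config or ConstraintConfig()
    results = constraint_windows(types, config)
    for ty, res in results.items():
        if res.excluded:
            log.info("%s excluded: %s", ty, res.exclusion_reason)
            continue
        res.sweep_vfs, res.sweep_rates = growth_sweep(ty, res.final_window, config)
        select_optimum(res)
    ranking = sorted((ty for ty, r in results.items() if r.max_rate is not None),
                     key=lambda ty: (-results[ty].max_rate, ty))
    return OptimisationResult(per_type=results, ranking=ranking, config=config)


def report(result: OptimisationResult, outdir, lambda_coef: float | None = None,
           make_plots: bool = True) -> Dict[str, str]:
    """Write window/optimum tables (CSV), rate curves and a run manifest.

    ``lambda_coef`` (mm^2/day) rescales the lambda = 1 rates into mm^3/day;
    left as None the rates are reported in curvature-time units with a note.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lam = lambda_coef if lambda_coef is not None else 1.0
    files = {}

    rows_w, rows_o, rows_c = [], [], []
    for ty, r in result.per_type.items():
        rows_w.append({
            "type": ty,
            "pore_lo": r.pore_window[0] if r.pore_window else np.nan,
            "pore_hi": r.pore_window[1] if r.pore_window else np.nan,
            "stiff_lo": r.stiffness_window[0] if r.stiffness_window else np.nan,
            "stiff_hi": r.stiffness_window[1] if r.stiffness_window else np.nan,
            "final_lo": r.final_window[0] if r.final_window else np.nan,
            "final_hi": r.final_window[1] if r.final_window else np.nan,
            "provenance": r.window_provenance,
            "exclusion_reason": r.exclusion_reason or "",
        })
        if r.max_rate is not None:
            rows_o.append({"type": ty, "optimal_vf": r.optimal_vf,
                           "max_rate_mm3_day": r.max_rate * lam})
        for vf, rate in zip(r.sweep_vfs, r.sweep_rates):
            rows_c.append({"type": ty, "vf": vf,
                           "rate_mm3_day": np.nan if rate is None else rate * lam})

    def _write(name, df):
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.6g")
        files[name] = str(path)

    _write("windows.csv", pd.DataFrame(rows_w))
    _write("optima.csv", pd.DataFrame(rows_o).sort_values(
        "max_rate_mm3_day", ascending=False) if rows_o else pd.DataFrame(rows_o))
    _write("growth_rates.csv", pd.DataFrame(rows_c))

    manifest = {
        "lambda_mm2_day": lambda_coef,
        "rate_units": "mm^3/day" if lambda_coef is not None
                      else "mm^3 per unit curvature time (lambda = 1)",
        "ranking": result.ranking,
        "config": {
            "vf_sweep": list(result.config.vf_sweep),
            "pore_resolution": result.config.pore_resolution,
            "growth_resolution": result.config.growth_resolution,
            "pore_limits_um": [result.config.pore_limits.d_lo,
                               result.config.pore_limits.d_hi],
            "stiffness_N_mm": [result.config.envelope.k_lo,
                               result.config.envelope.k_hi],
            "stiffness_mode": result.config.stiffness_mode,
            "manual_windows": result.config.manual_windows,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    files["manifest.json"] = str(outdir / "manifest.json")

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for ty, r in result.per_type.items():
            vfs = [v for v, q in zip(r.sweep_vfs, r.sweep_rates) if q is not None]
            qs = [q * lam for q in r.sweep_rates if q is not None]
            if vfs:
                ax.plot(vfs, qs, "o-", label=ty)
        ax.set_xlabel("volume fraction")
        ax.set_ylabel(f"average growth rate ({manifest['rate_units']})")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "growth_rates.png", dpi=150)
        plt.close(fig)
        files["growth_rates.png"] = str(outdir / "growth_rates.png")
    return files
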