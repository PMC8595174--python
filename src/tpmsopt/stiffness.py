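"""Gibson-Ashby stiffness scaling and the axial-stiffness design window.

Cellular solids follow power-law stiffness scaling: the relative modulus
E* (scaffold modulus over bulk material modulus) varies with volume
fraction rho* as

    E*(rho*) = C1 * rho*^n + E0

with type-specific constants fitted over rho* in [0.2, 0.9].  For a
cylindrical scaffold of diameter D and length L loaded axially, the
structural stiffness is

    k_scaff = E* . E . pi D^2 / (4 L)    [N/mm]

A femoral critical-size graft must land between 1000 N/mm (enough
interfragmentary movement for bone formation) and 2700 N/mm (avoid stress
shielding); inverting the scaling law maps that stiffness window onto a
volume-fraction window.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .geometry import _canonical_type

__all__ = [
    "ScalingLaw",
    "StiffnessEnvelope",
    "TABLE_LAWS",
    "FitError",
    "relative_modulus",
    "axial_stiffness",
    "stiffness_window",
    "fit_scaling_law",
]

VF_RANGE = (0.2, 0.9)  # fit range of the shipped laws


class FitError(RuntimeError):
    """Raised when the Gibson-Ashby fit cannot be performed."""


@dataclasses.dataclass(frozen=True)
class ScalingLaw:
    """Gibson-Ashby constants for one TPMS type: E* = C1 rho^n + E0."""

    C1: float
    n_exp: float
    E0: float
    tpms_type: str = ""
    r_squared: Optional[float] = None

    def __post_init__(self):
        if self.C1 <= 0:
            raise ValueError(f"C1 must be > 0, got {self.C1}")
        if self.n_exp <= 1:
            raise ValueError(f"cellular-solid exponent must exceed 1, got {self.n_exp}")

    def __call__(self, vf: float) -> float:
        return relative_modulus(self, vf)


#: Scaling constants shipped as defaults for the four window-relevant types.
TABLE_LAWS: Dict[str, ScalingLaw] = {
    "split_p": ScalingLaw(1.33, 2.04, -0.078, "split_p"),
    "gyroid": ScalingLaw(1.33, 2.68, -0.002, "gyroid"),
    "diamond": ScalingLaw(1.26, 2.74, 0.039, "diamond"),
    "lidinoid": ScalingLaw(1.38, 2.59, -0.050, "lidinoid"),
}


@dataclasses.dataclass(frozen=True)
class StiffnessEnvelope:
    """Material, geometry and allowed axial-stiffness range.

    E : bulk material modulus in Pa (default 1.8 GPa, additively
        manufactured Nylon, a trabecular-bone-like model material).
    D, L : scaffold diameter and length in mm (default 30 mm each: femoral
        diameter and critical fracture length).
    k_lo, k_hi : allowed axial stiffness in N/mm (default 1000-2700).
    """

    E: float = 1.8e9
    D: float = 30.0
    L: float = 30.0
    k_lo: float = 1000.0
    k_hi: float = 2700.0

    def __post_init__(self):
        if min(self.E, self.D, self.L) <= 0:
            raise ValueError("E, D, L must be positive")
        if not 0 <= self.k_lo < self.k_hi:
            raise ValueError(f"require 0 <= k_lo < k_hi, got {self.k_lo}, {self.k_hi}")

    @property
    def geometry_factor(self) -> float:
        """E * pi D^2 / 4L with E in N/mm^2; stiffness at E* = 1, N/mm."""
        E_n_mm2 = self.E / 1e6  # Pa -> N/mm^2 (MPa)
        return E_n_mm2 * math.pi * self.D ** 2 / (4.0 * self.L)


def relative_modulus(law: ScalingLaw, vf: float) -> float:
    """E* = C1 vf^n + E0, clipped at zero (with a warning) if negative.

    ``vf`` must lie in the fit range [0.2, 0.9]; the power law is not
    validated outside it.
    """
    if not VF_RANGE[0] <= vf <= VF_RANGE[1]:
        raise ValueError(
            f"vf={vf} outside the Gibson-Ashby fit range {VF_RANGE}")
    e = law.C1 * vf ** law.n_exp + law.E0
    if e < 0:
        warnings.warn(
            f"E*({vf:.3g}) = {e:.3g} < 0 for {law.tpms_type or 'law'}; clipping to 0",
            stacklevel=2)
        return 0.0
    return float(e)


def axial_stiffness(e_star: float, env: StiffnessEnvelope | None = None) -> float:
    """Axial stiffness k_scaff = E* E pi D^2 / 4L in N/mm."""
    if e_star < 0:
        raise ValueError("E* must be >= 0")
    env = env or StiffnessEnvelope()
    return e_star * env.geometry_factor


def _invert_law(law: ScalingLaw, e_star: float) -> float:
    """vf with E*(vf) = e_star (clamped into the fit range)."""
    lo, hi = VF_RANGE
    if e_star <= law.E0:
        warnings.warn(
            f"required E* = {e_star:.4g} is below the law offset E0 = {law.E0}; "
            f"clamping to vf = {lo}", stacklevel=3)
        return lo
    vf = ((e_star - law.E0) / law.C1) ** (1.0 / law.n_exp)
    return float(min(max(vf, lo), hi))


def stiffness_window(law: ScalingLaw, env: StiffnessEnvelope | None = None
                     ) -> Optional[Tuple[float, float]]:
    """Volume-fraction interval whose axial stiffness lies in [k_lo, k_hi].

    Closed-form inversion of the scaling law at both stiffness bounds,
    intersected with the fit range [0.2, 0.9]; None when empty.
    """
    env = env or StiffnessEnvelope()
    gf = env.geometry_factor
    lo_vf = VF_RANGE[0] if env.k_lo == 0 else _invert_law(law, env.k_lo / gf)
    hi_vf = VF_RANGE[1] if not math.isfinite(env.k_hi) else _invert_law(law, env.k_hi / gf)
    # the window may be clipped away entirely by the fit range
    if axial_stiffness(relative_modulus(law, lo_vf), env) > env.k_hi:
        return None
    if axial_stiffness(relative_modulus(law, hi_vf), env) < env.k_lo:
        return None
    return (lo_vf, hi_vf) if lo_vf <= hi_vf else None


def fit_scaling_law(vf_values: Sequence[float], e_star_values: Sequence[float],
                    tpms_type: str = "") -> ScalingLaw:
    """Least-squares Gibson-Ashby fit E* = C1 vf^n + E0.

    Requires at least four points (three parameters); initialised at
    (C1, n, E0) = (1, 2, 0) with the exponent bounded in (1, 5], the
    physical range for bending/stretch-dominated lattices.
    """
    from scipy.optimize import curve_fit

    vf = np.asarray(vf_values, dtype=float)
    es = np.asarray(e_star_values, dtype=float)
    if vf.size != es.size:
        raise FitError("vf and E* arrays differ in length")
    if vf.size < 4:
        raise FitError(
            f"need >= 4 points to fit 3 parameters, got {vf.size}: vf={vf.tolist()}")

    def model(r, c1, n, e0):
        return c1 * r ** n + e0

    try:
        popt, _ = curve_fit(model, vf, es, p0=(1.0, 2.0, 0.0),
                            bounds=([1e-12, 1.0 + 1e-9, -np.inf], [np.inf, 5.0, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"Gibson-Ashby fit failed for {tpms_type or 'data'}: {exc}; "
            f"vf={vf.tolist()}, E*={es.tolist()}") from exc
    resid = es - model(vf, *popt)
    ss_tot = float(((es - es.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    ttype = _canonical_type(tpms_type) if tpms_type else ""
    return ScalingLaw(C1=float(popt[0]), n_exp=float(popt[1]), E0=float(popt[2]),
                      tpms_type=ttype, r_squared=r2)
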