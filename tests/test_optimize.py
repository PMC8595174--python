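"""Window algebra, optimum selection and reporting."""

import numpy as np
import pytest

from tpmsopt.optimize import (ConstraintConfig, OptimisationResult,
                              PUBLISHED_WINDOWS, TypeResult, _intersect,
                              constraint_windows, report, select_optimum)
from tpmsopt.pore_metrics import PoreLimits


def test_interval_intersection_algebra():
    a, b = (0.3, 0.7), (0.5, 0.9)
    assert _intersect(a, b) == _intersect(b, a) == (0.5, 0.7)
    assert _intersect(a, a) == a                      # idempotent
    assert _intersect(a, (0.8, 0.9)) is None          # disjoint
    assert _intersect(a, None) is None


def test_manual_windows_take_precedence():
    cfg = ConstraintConfig(manual_windows=dict(PUBLISHED_WINDOWS))
    wins = constraint_windows(["lidinoid", "gyroid", "primitive"], cfg)
    assert wins["lidinoid"].final_window == (0.49, 0.59)
    assert wins["gyroid"].final_window == (0.47, 0.66)
    assert wins["lidinoid"].window_provenance == "manual"
    # a type without a manual window is excluded with a reason, not silently
    assert wins["primitive"].excluded
    assert "manual" in wins["primitive"].exclusion_reason


def test_computed_windows_report_both_sources():
    cfg = ConstraintConfig(vf_sweep=(0.3, 0.6), pore_resolution=30,
                           pore_limits=PoreLimits(d_lo=1e-3, d_hi=1e9))
    wins = constraint_windows(["gyroid"], cfg)
    r = wins["gyroid"]
    # wide-open pore limits admit the whole sweep
    assert r.pore_window == pytest.approx((0.3, 0.6))
    assert r.final_window == pytest.approx((0.3, 0.6))
    assert r.stiffness_window is not None  # computed and reported alongside
    assert "stiffness" in r.window_provenance


def test_select_optimum_monotone_decreasing_curve():
    r = TypeResult("gyroid", None, None, (0.4, 0.6),
                   sweep_vfs=[0.4, 0.5, 0.6], sweep_rates=[3.0, 2.0, 1.0])
    select_optimum(r)
    assert r.optimal_vf == 0.4 and r.max_rate == 3.0


def test_select_optimum_tie_prefers_lower_vf():
    r = TypeResult("gyroid", None, None, (0.4, 0.6),
                   sweep_vfs=[0.4, 0.5, 0.6], sweep_rates=[2.0, 2.0, 1.0])
    select_optimum(r)
    assert r.optimal_vf == 0.4


def test_select_optimum_skips_unfilled_points():
    r = TypeResult("gyroid", None, None, (0.4, 0.6),
                   sweep_vfs=[0.4, 0.5, 0.6], sweep_rates=[None, 2.0, 1.0])
    select_optimum(r)
    assert r.optimal_vf == 0.5


def test_report_schema_and_exclusions(tmp_path):
    import pandas as pd
    good = TypeResult("lidinoid", (0.49, 0.59), (0.2, 0.3), (0.49, 0.59),
                      window_provenance="manual",
                      sweep_vfs=[0.49, 0.59], sweep_rates=[3.0, 1.5],
                      optimal_vf=0.49, max_rate=3.0)
    bad = TypeResult("primitive", None, None, None,
                     exclusion_reason="max pore > 400 um at all swept volume fractions")
    result = OptimisationResult(per_type={"lidinoid": good, "primitive": bad},
                                ranking=["lidinoid"], config=ConstraintConfig())
    files = report(result, tmp_path, lambda_coef=2.0, make_plots=False)
    optima = pd.read_csv(files["optima.csv"])
    assert list(optima.columns) == ["type", "optimal_vf", "max_rate_mm3_day"]
    assert optima.loc[0, "max_rate_mm3_day"] == pytest.approx(6.0)  # lambda applied
    windows = pd.read_csv(files["windows.csv"]).set_index("type")
    assert "max pore" in windows.loc["primitive", "exclusion_reason"]
    assert np.isnan(windows.loc["primitive", "final_lo"])


def test_config_validation():
    with pytest.raises(ValueError):
        ConstraintConfig(vf_sweep=(0.5, 0.3))
    with pytest.raises(ValueError):
        ConstraintConfig(stiffness_mode="maybe")
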