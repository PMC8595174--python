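"""Gibson-Ashby scaling laws, axial stiffness and window inversion."""

import math

import numpy as np
import pytest

from tpmsopt.stiffness import (FitError, ScalingLaw, StiffnessEnvelope,
                               TABLE_LAWS, axial_stiffness, fit_scaling_law,
                               relative_modulus, stiffness_window)


def test_relative_modulus_examples():
    # direct arithmetic checks of E* = C1 rho^n + E0
    assert relative_modulus(TABLE_LAWS["gyroid"], 0.5) == pytest.approx(
        1.33 * 0.5 ** 2.68 - 0.002, abs=1e-12)
    assert relative_modulus(TABLE_LAWS["gyroid"], 0.5) == pytest.approx(0.2055, abs=5e-4)
    assert relative_modulus(TABLE_LAWS["diamond"], 0.2) == pytest.approx(
        1.26 * 0.2 ** 2.74 + 0.039, abs=1e-12)


def test_relative_modulus_range_and_clipping():
    with pytest.raises(ValueError):
        relative_modulus(TABLE_LAWS["gyroid"], 0.1)
    # Split P has a negative offset: E* goes negative at the low end
    with pytest.warns(UserWarning):
        assert relative_modulus(TABLE_LAWS["split_p"], 0.2) == 0.0


def test_axial_stiffness_closed_form():
    env = StiffnessEnvelope()
    # E* = 1 with 1.8 GPa, D = L = 30 mm: 1800 N/mm^2 * pi*900/120 mm
    assert axial_stiffness(1.0, env) == pytest.approx(1800 * math.pi * 900 / 120,
                                                      rel=1e-12)
    assert axial_stiffness(0.0, env) == 0.0
    assert axial_stiffness(0.4, env) == pytest.approx(2 * axial_stiffness(0.2, env))


def test_default_e_star_bounds():
    env = StiffnessEnvelope()
    gf = env.geometry_factor
    assert env.k_lo / gf == pytest.approx(0.0236, abs=3e-4)
    assert env.k_hi / gf == pytest.approx(0.0637, abs=3e-4)


def test_stiffness_window_unconstrained():
    env = StiffnessEnvelope(k_lo=0.0, k_hi=float("inf"))
    assert stiffness_window(TABLE_LAWS["gyroid"], env) == (0.2, 0.9)


def test_stiffness_window_round_trip():
    # a window whose edges fall inside the fit range inverts exactly
    env = StiffnessEnvelope(k_lo=3000.0, k_hi=8000.0)
    lo, hi = stiffness_window(TABLE_LAWS["gyroid"], env)
    assert 0.2 < lo < hi < 0.9
    assert axial_stiffness(relative_modulus(TABLE_LAWS["gyroid"], lo), env) == \
        pytest.approx(3000.0, rel=1e-6)
    assert axial_stiffness(relative_modulus(TABLE_LAWS["gyroid"], hi), env) == \
        pytest.approx(8000.0, rel=1e-6)


def test_stiffness_window_nesting():
    narrow = StiffnessEnvelope(k_lo=3000.0, k_hi=6000.0)
    wide = StiffnessEnvelope(k_lo=2000.0, k_hi=9000.0)
    n = stiffness_window(TABLE_LAWS["diamond"], narrow)
    w = stiffness_window(TABLE_LAWS["diamond"], wide)
    assert w[0] <= n[0] and n[1] <= w[1]


@pytest.mark.parametrize("law", TABLE_LAWS.values(), ids=list(TABLE_LAWS))
def test_relative_modulus_strictly_increasing(law):
    vfs = np.linspace(0.2, 0.9, 15)
    es = [max(law.C1 * v ** law.n_exp + law.E0, 0.0) for v in vfs]
    diffs = np.diff(es)
    assert (diffs[np.array(es[:-1]) > 0] > 0).all()


def test_fit_recovers_noiseless_law():
    law = TABLE_LAWS["gyroid"]
    vfs = np.linspace(0.2, 0.9, 8)
    es = [law.C1 * v ** law.n_exp + law.E0 for v in vfs]
    fit = fit_scaling_law(vfs, es, "gyroid")
    assert fit.C1 == pytest.approx(law.C1, abs=1e-6)
    assert fit.n_exp == pytest.approx(law.n_exp, abs=1e-6)
    assert fit.E0 == pytest.approx(law.E0, abs=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_with_noise_recovers_exponent():
    law = TABLE_LAWS["gyroid"]
    rng = np.random.default_rng(7)
    vfs = np.linspace(0.2, 0.9, 15)
    es = law.C1 * vfs ** law.n_exp + law.E0 + rng.normal(0, 0.005, vfs.size)
    fit = fit_scaling_law(vfs, es)
    assert fit.n_exp == pytest.approx(law.n_exp, abs=0.1)


def test_fit_underdetermined():
    with pytest.raises(FitError):
        fit_scaling_law([0.2, 0.5, 0.9], [0.1, 0.3, 0.8])


def test_scaling_law_validation():
    with pytest.raises(ValueError):
        ScalingLaw(C1=-1.0, n_exp=2.0, E0=0.0)
    with pytest.raises(ValueError):
        ScalingLaw(C1=1.0, n_exp=0.9, E0=0.0)
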