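"""Plane-stress hyperelastic plate and pressurised thin shells."""

import numpy as np
import pytest

from wallmech.continuum import (
    HyperelasticMaterial,
    LinearWall,
    ShellSpec,
    StiffnessProfileWall,
    cylinder_axial_response,
    inflate_shell,
    plane_stress_uniaxial,
    uniaxial_curve,
)
from wallmech.errors import InvalidInputError

NEO = HyperelasticMaterial(mu=5.0 / 13.0, K=5.0 / 6.0)  # E0 = 1, nu = 0.3


def test_identity_state_is_stress_free():
    assert plane_stress_uniaxial(NEO, 1.0) == (1.0, 0.0)


def test_material_constant_conversion():
    assert NEO.C10 == pytest.approx(5.0 / 26.0)
    assert NEO.D1 == pytest.approx(12.0 / 5.0)
    other = HyperelasticMaterial(C10=5.0 / 26.0, D1=12.0 / 5.0)
    assert other.mu == pytest.approx(NEO.mu)
    assert other.K == pytest.approx(NEO.K)
    with pytest.raises(InvalidInputError):
        HyperelasticMaterial(mu=1.0, K=1.0, C10=0.5, D1=2.0)


def test_small_strain_poisson_ratio():
    """mu = 5/13, K = 5/6 normalise to E0 = 1, nu = 0.3; the uniaxial
    plane-stress solve must reproduce nu at small strain."""
    lt, _ = plane_stress_uniaxial(NEO, 1.001)
    assert -np.log(lt) / np.log(1.001) == pytest.approx(0.3, abs=1e-3)


def test_small_strain_initial_modulus_is_one():
    _, f1 = plane_stress_uniaxial(NEO, 1.0005)
    _, f2 = plane_stress_uniaxial(NEO, 1.0015)
    assert (f2 - f1) / 0.001 == pytest.approx(1.0, abs=1e-2)


def test_incompressible_limit_matches_closed_form():
    """K/mu = 1e4: nominal stress -> mu (lambda - lambda^-2) and
    lambda_tr -> lambda^-1/2."""
    mat = HyperelasticMaterial(mu=1.0, K=1e4)
    lt, f = plane_stress_uniaxial(mat, 1.3)
    assert f == pytest.approx(1.3 - 1.3**-2, rel=0.005)
    assert lt == pytest.approx(1.3**-0.5, rel=0.005)


def test_curve_starts_at_zero_force():
    curve = uniaxial_curve(NEO, np.linspace(1.0, 1.5, 51))
    assert curve.force_per_width[0] == 0.0


def test_energy_consistency_with_work_integral():
    """Material-frame consistency: stored energy density (x thickness)
    equals the work integral of the nominal force-stretch curve."""
    lam = np.linspace(1.0, 1.4, 2001)
    curve = uniaxial_curve(NEO, lam)
    work = np.trapezoid(curve.force_per_width, lam)
    lt, _ = plane_stress_uniaxial(NEO, lam[-1])
    energy = NEO.energy_density(lam[-1], lt, lt) * NEO.thickness_ref
    assert work == pytest.approx(energy, rel=1e-3)


@pytest.mark.parametrize("model,kw", [("neo-hookean", {}), ("yeoh", {"C20": 0.2, "C30": 0.5})])
def test_small_strain_limit_reproduces_prescribed_constants(model, kw):
    mat = HyperelasticMaterial.from_E_nu(1.0, 0.3, model=model, **kw)
    lt, _ = plane_stress_uniaxial(mat, 1.001)
    assert -np.log(lt) / np.log(1.001) == pytest.approx(0.3, abs=1e-3)
    _, f1 = plane_stress_uniaxial(mat, 1.0005)
    _, f2 = plane_stress_uniaxial(mat, 1.0015)
    assert (f2 - f1) / 0.001 == pytest.approx(1.0, abs=1e-2)


def test_yeoh_stiffens_at_large_stretch():
    mat = HyperelasticMaterial.from_E_nu(1.0, 0.3, model="yeoh", C20=0.2, C30=0.5)
    curve = uniaxial_curve(mat, np.linspace(1.0, 1.45, 91))
    k = curve.tangent_stiffness
    lam = curve.lambda_grid
    assert k[np.searchsorted(lam, 1.4)] > k[np.searchsorted(lam, 1.05)]


def test_neo_hookean_plate_has_no_three_regime_shape():
    """The homogeneous plate is smooth and convex-then-affine: its
    tangent stiffness has no initial plateau followed by a rise and a
    second plateau."""
    curve = uniaxial_curve(NEO, np.linspace(1.0, 1.5, 201))
    k = curve.tangent_stiffness
    inner = k[5:-5]
    assert np.all(np.diff(inner) < 1e-9)  # monotone softening, no regimes


# ---------------------------------------------------------------------------
# shells


def test_sphere_zero_pressure_means_no_stretch():
    spec = ShellSpec("sphere", 1.0, 0.01, LinearWall(1.0, 0.3))
    res = inflate_shell(spec, np.array([0.0]))
    assert res["stretch"][0] == 1.0


def test_linear_sphere_limit_point_matches_closed_form():
    """Hookean membrane with geometric thinning: the pressure maximum
    sits at eps* = -1 + sqrt(1 + 1/a), a = 2 nu / (1 - nu)."""
    nu = 0.3
    spec = ShellSpec("sphere", 1.0, 0.01, LinearWall(1.0, nu))
    res = inflate_shell(spec, np.linspace(0.0, 0.02, 21))
    assert res["limit_point"] is not None
    a = 2 * nu / (1 - nu)
    lam_star = np.sqrt(1 + 1 / a)
    assert res["limit_point"][1] == pytest.approx(lam_star, abs=0.005)


def test_stiffening_wall_resists_runaway_inflation():
    """A wall whose stiffness ramps 12 -> 70 keeps the pressure-stretch
    relation much steeper at high pressure than an always-12 wall."""

    def ramp(lam):
        t = np.clip((lam - 1.10) / 0.15, 0.0, 1.0)
        return 12.0 + 58.0 * (3 * t * t - 2 * t**3)

    p_grid = np.linspace(0.0, 8.0, 30)
    res_r = inflate_shell(ShellSpec("sphere", 1.0, 0.01, StiffnessProfileWall(ramp)), p_grid)
    res_12 = inflate_shell(
        ShellSpec("sphere", 1.0, 0.01, StiffnessProfileWall(lambda lam: 12.0)), p_grid
    )

    def top_slope(res):
        lam, p = res["stretch"], res["pressure"]
        return (lam[-1] - lam[-2]) / (p[-1] - p[-2])

    assert top_slope(res_r) < 0.25 * top_slope(res_12)


def test_cylinder_bar_stiffness_at_zero_pressure():
    spec = ShellSpec("cylinder", 1.0, 0.01, LinearWall(1.0, 0.3), pressure=0.0)
    res = cylinder_axial_response(spec, np.linspace(0.0, 1e-4, 5))
    assert res["tangent_stiffness"][2] == pytest.approx(2 * np.pi * 1.0 * 0.01 * 1.0, rel=1e-3)


def test_pressurised_cylinder_stiffer_with_higher_poisson():
    def stiffness(nu):
        spec = ShellSpec("cylinder", 1.0, 0.01, LinearWall(1.0, nu), pressure=0.005)
        res = cylinder_axial_response(spec, np.linspace(0.0, 1e-4, 5))
        return res["tangent_stiffness"][2]

    assert stiffness(0.45) > stiffness(0.0)


def test_doubling_thickness_doubles_stiffness():
    def stiffness(t):
        spec = ShellSpec("cylinder", 1.0, t, LinearWall(1.0, 0.3), pressure=0.0)
        res = cylinder_axial_response(spec, np.linspace(0.0, 1e-4, 5))
        return res["tangent_stiffness"][2]

    assert stiffness(0.02) == pytest.approx(2.0 * stiffness(0.01), rel=1e-3)


def test_thick_wall_warns():
    with pytest.warns(UserWarning):
        ShellSpec("sphere", 1.0, 0.2, LinearWall(1.0, 0.3))
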