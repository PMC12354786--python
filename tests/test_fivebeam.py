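"""Five-beam diamond model: geometry, plasticity, bending, equilibrium,
and emergence of the three-regime phenomenology."""

import math
from dataclasses import replace

import numpy as np
import pytest

from wallmech.analysis import extract_summary
from wallmech.errors import InvalidInputError
from wallmech.fivebeam import (
    FiveBeamParams,
    bending_energy,
    bending_force,
    build_geometry,
    connector_return_map,
    parameter_sweep,
    simulate_cyclic,
    simulate_monotonic,
    solve_equilibrium,
)

LAM_GRID = np.linspace(1.0, 1.5, 251)


# ---------------------------------------------------------------------------
# geometry


def test_square_diamond_geometry():
    p = FiveBeamParams(theta=90.0, scale=1.0)
    state = build_geometry(90.0, 1.0)
    pos = state.node_positions(p)
    assert pos["A"] == pytest.approx((0.0, 1.0))
    assert pos["B"] == pytest.approx((0.0, -1.0))
    assert pos["C"] == pytest.approx((1.0, 0.0))
    assert pos["D"] == pytest.approx((-1.0, 0.0))


def test_sixty_degree_transverse_half_span():
    p = FiveBeamParams(theta=60.0, scale=1.0)
    assert p.half_span_tr == pytest.approx(math.tan(math.radians(30.0)), abs=1e-12)


@pytest.mark.parametrize("theta", [40.0, 80.0, 120.0])
def test_diagonal_beams_equal_length(theta):
    p = FiveBeamParams(theta=theta)
    state = build_geometry(theta, 1.0)
    pos = state.node_positions(p)
    lengths = {
        round(math.dist(pos[a], pos[b]), 12)
        for a, b in (("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"))
    }
    assert len(lengths) == 1


@pytest.mark.parametrize("theta", [0.0, 180.0, -10.0])
def test_degenerate_angle_rejected(theta):
    with pytest.raises(InvalidInputError):
        build_geometry(theta, 1.0)


# ---------------------------------------------------------------------------
# connector return map


def test_elastic_step_below_threshold():
    p = FiveBeamParams()
    f, slip = connector_return_map(0.5 * p.f_slip, 0.0, p)
    assert f == 0.5 * p.f_slip
    assert slip == 0.0


def test_perfect_plasticity_return():
    p = replace(FiveBeamParams(), H=0.0)
    f, slip = connector_return_map(2.0 * p.f_slip, 0.0, p)
    assert f == pytest.approx(p.f_slip, rel=1e-12)
    assert slip == pytest.approx(p.f_slip / p.k_c, rel=1e-12)


def test_infinite_threshold_never_slips():
    p = replace(FiveBeamParams(), f_slip=math.inf)
    f, slip = connector_return_map(1e9, 0.0, p)
    assert f == 1e9 and slip == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_return_map_rate_independence_on_random_paths(seed):
    """Backward-Euler return mapping is rate independent: driving the
    same displacement path at 10x finer increments changes the final
    state by < 1e-8."""
    p = FiveBeamParams()
    rng = np.random.default_rng(seed)
    path = np.cumsum(rng.normal(0.0, 0.02, 50))

    def integrate(n_sub):
        slip, acc, u_prev, f = 0.0, 0.0, 0.0, 0.0
        for u in path:
            for uu in np.linspace(u_prev, u, n_sub + 1)[1:]:
                f, slip_new = connector_return_map(
                    p.k_c * (uu - slip), slip, p, acc_prev=acc
                )
                acc += abs(slip_new - slip)
                slip = slip_new
            u_prev = u
        return f, slip

    f1, s1 = integrate(1)
    f2, s2 = integrate(10)
    assert abs(f1 - f2) < 1e-8
    assert abs(s1 - s2) < 1e-8


# ---------------------------------------------------------------------------
# bending law


def test_bending_force_zero_at_zero_shortening():
    p = FiveBeamParams()
    force, flag = bending_force(0.0, p)
    assert force == 0.0 and not flag


def test_bending_force_monotone_nondecreasing():
    p = FiveBeamParams()
    deltas = np.linspace(0.0, 0.9 * p.ab_length0, 200)
    forces = [bending_force(d, p)[0] for d in deltas]
    assert np.all(np.diff(forces) >= -1e-12)


def test_plateau_without_hardening():
    p = replace(FiveBeamParams(), bend_harden=0.0)
    force, _ = bending_force(0.9 * p.ab_length0, p)
    assert force == pytest.approx(p.bend_Pcr, rel=0.01)


def test_negative_shortening_is_flagged_tension():
    p = FiveBeamParams()
    force, flag = bending_force(-0.01, p)
    assert flag and force < 0


def test_bending_energy_matches_work_integral():
    p = FiveBeamParams()
    deltas = np.linspace(0.0, 0.6, 4001)
    forces = np.array([bending_force(d, p)[0] for d in deltas])
    work = np.concatenate([[0.0], np.cumsum(0.5 * (forces[1:] + forces[:-1]) * np.diff(deltas))])
    for i in (1000, 2500, 4000):
        assert bending_energy(deltas[i], p) == pytest.approx(work[i], rel=1e-5)


# ---------------------------------------------------------------------------
# equilibrium and simulations


def test_rest_state_has_no_forces(default_params):
    state = build_geometry(default_params.theta, default_params.scale)
    state = solve_equilibrium(default_params, state, 1.0)
    assert state.force_per_width == pytest.approx(0.0, abs=1e-12)
    assert state.lambda_tr == pytest.approx(1.0, abs=1e-9)


def test_fully_elastic_load_unload_returns_to_origin(default_params):
    p = replace(default_params, f_slip=math.inf)
    _, rec = simulate_cyclic(p, [1.2])
    assert rec.cycles[0].recovery_percent == pytest.approx(100.0, abs=0.1)
    assert rec.cycles[0].residual_stretch == pytest.approx(1.0, abs=1e-4)


def test_energy_bookkeeping(fivebeam_monotonic):
    """External work = stored elastic energy + dissipation (trapezoid
    accuracy), dissipation nonnegative at every increment."""
    _, states = fivebeam_monotonic
    d = np.array([s.dissipation for s in states])
    assert np.all(np.diff(d) >= -1e-12)
    final = states[-1]
    assert final.dissipation > 0
    gap = abs(final.work - final.elastic_energy - final.dissipation)
    assert gap / final.work < 0.01


def test_zero_dissipation_without_slip(default_params):
    p = replace(default_params, f_slip=math.inf)
    _, states = simulate_monotonic(p, np.linspace(1.0, 1.4, 101))
    assert states[-1].dissipation == 0.0


def test_rate_independence_of_simulation(default_params, fivebeam_monotonic):
    _, states = fivebeam_monotonic
    _, states_fine = simulate_monotonic(default_params, np.linspace(1.0, 1.5, 501))
    assert states[-1].lambda_tr == pytest.approx(states_fine[-1].lambda_tr, rel=1e-6)
    assert states[-1].slip[0] == pytest.approx(states_fine[-1].slip[0], rel=1e-6, abs=1e-9)


def test_mirror_symmetry_of_connectors(fivebeam_monotonic):
    _, states = fivebeam_monotonic
    for s in states[::50]:
        assert np.ptp(s.slip) == 0.0
        assert np.ptp(s.beam_force) == 0.0


def test_force_scale_invariance(default_params, fivebeam_monotonic):
    """Scaling every force-like parameter by c scales forces by c and
    leaves the kinematics untouched."""
    curve, _ = fivebeam_monotonic
    c = 3.0
    p = replace(
        default_params,
        k_s=c * default_params.k_s,
        k_c=c * default_params.k_c,
        bend_Pcr=c * default_params.bend_Pcr,
        f_slip=c * default_params.f_slip,
        H=c * default_params.H,
    )
    scaled, _ = simulate_monotonic(p, LAM_GRID)
    np.testing.assert_allclose(scaled.force_per_width, c * curve.force_per_width, atol=1e-12)
    np.testing.assert_allclose(scaled.lambda_tr, curve.lambda_tr, atol=1e-12)


def test_three_regime_emergence(fivebeam_monotonic):
    """Defaults produce plateau-rise-plateau tangent stiffness and an
    interior maximum of the incremental Poisson's ratio."""
    curve, _ = fivebeam_monotonic
    lam, k, nu = curve.lambda_grid, curve.tangent_stiffness, curve.nu_inc
    s = extract_summary(curve.as_derived(), 1.5)
    m1 = (lam >= 1.02) & (lam <= 1.05)
    m3 = (lam >= s.regime_bounds[1]) & (lam <= 1.45)
    assert (k[m1].max() - k[m1].min()) / k[m1].mean() < 0.2  # flat within +-10%
    assert (k[m3].max() - k[m3].min()) / k[m3].mean() < 0.2
    assert s.E2 / s.E1 > 3.0
    i_peak = int(np.argmax(nu))
    assert 1.05 < lam[i_peak] < 1.45
    assert nu[i_peak] > 1.0
    assert nu[-1] < 0.8 * nu[i_peak]  # declines past the peak


def test_rigid_transverse_beam_suppresses_poisson_peak(default_params, fivebeam_monotonic):
    curve, _ = fivebeam_monotonic
    rigid = replace(default_params, bend_Pcr=1e6, bend_harden=0.0)
    curve_r, _ = simulate_monotonic(rigid, LAM_GRID)
    assert curve_r.nu_inc.max() < 0.05 * curve.nu_inc.max()


def test_cyclic_recovery_decreases_then_levels(fivebeam_cyclic):
    _, rec = fivebeam_cyclic
    r = rec.recovery_percents
    assert r[0] == pytest.approx(100.0, abs=0.5)  # regime I: fully recoverable
    assert np.all(np.diff(r) <= 1e-5)  # nonincreasing
    drops = -np.diff(r)
    assert drops[-1] < 0.7 * drops.max()  # decline slows: plateau forming


def test_residual_stretch_nondecreasing_in_peak_force(fivebeam_cyclic):
    from wallmech.analysis import residual_vs_force

    _, rec = fivebeam_cyclic
    table = residual_vs_force(rec)
    assert np.all(np.diff(table[:, 1]) >= -1e-12)


def test_cyclic_envelope_rejoins_monotonic(fivebeam_monotonic, fivebeam_cyclic):
    """Reloading beyond a previous peak follows the monotonic curve
    within 1%."""
    curve, _ = fivebeam_monotonic
    cyc, rec = fivebeam_cyclic
    raw = cyc.raw
    for c in range(2, cyc.n_cycles + 1):
        mask = cyc.segment(c, "loading")
        lam_l, f_l = raw.lambda_ax[mask], raw.force_per_width[mask]
        prev_peak = rec.cycles[c - 2].peak_stretch
        chk = prev_peak + 0.02
        if chk >= lam_l.max():
            continue
        f_cyc = np.interp(chk, lam_l, f_l)
        f_mono = np.interp(chk, curve.lambda_grid, curve.force_per_width)
        assert f_cyc == pytest.approx(f_mono, rel=0.01)


def test_connector_resistance_sweep(default_params):
    """Connector stiffness leaves E1 nearly unchanged but controls E2."""
    rows = parameter_sweep(default_params, "k_c", [50.0, 100.0, 200.0])
    e1 = [r["summary"].E1 for r in rows]
    e2 = [r["summary"].E2 for r in rows]
    assert (max(e1) - min(e1)) / min(e1) < 0.05
    assert e2[0] < e2[1] < e2[2]


def test_angle_sweep_orders_stiffness_and_poisson(default_params):
    """Fibers aligned with the pull (smaller angle) keep E1 similar but
    raise E2 and the Poisson peak; the perpendicular bias lowers them."""
    th0 = default_params.theta
    rows = parameter_sweep(default_params, "theta", [th0 - 1.0, th0, th0 + 1.0])
    s1, s0, s2 = (r["summary"] for r in rows)
    assert abs(s1.E1 / s0.E1 - 1.0) < 0.10
    assert abs(s2.E1 / s0.E1 - 1.0) < 0.10
    assert s1.E2 > s0.E2 > s2.E2
    assert s1.nu2 > s0.nu2 > s2.nu2
    assert s1.nu1 > s0.nu1 > s2.nu1


def test_unknown_sweep_field_rejected(default_params):
    with pytest.raises(InvalidInputError):
        parameter_sweep(default_params, "nonexistent", [1.0])
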