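"""Five-beam diamond model with elastoplastic connectors.

A diamond unit of four stretching beams (AC, AD, BC, BD) and one
transverse bending beam (AB) conceptualises a patch of the cellulose
microfibril network: the diagonals represent the bulk of the
microfibrils, which rotate towards the pull direction and elongate
elastically; the transverse beam represents microfibrils near the
transverse direction, which bend rather than shorten axially; and each
diagonal carries, in series, a connector representing fibril-fibril
load-transfer junctions, which deform elastically and slip plastically
once their force exceeds a threshold.

Loading nodes C, D sit on the axial axis, transverse nodes A, B on the
transverse axis; the whole problem is mirror-symmetric about both axes,
so the quasi-static solve reduces to a single transverse unknown (the
half-span of A) plus the connector internal variables, handled by a 1-D
rate-independent return map inside each increment.

Under monotonic stretch this unit reproduces the three-regime
phenomenology of the cell wall: a soft bending/rotation-dominated
plateau, a strain-stiffening rise as the diagonals align, and a final
stretch-dominated plateau, together with a nonmonotonic incremental
Poisson's ratio and recovery that decreases with stretch before
levelling off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .analysis import recovery_analysis, split_cycles
from .curves import CyclicCurve, ModelCurve, RawCurve, RecoveryResult
from .errors import InvalidInputError, SolverError

__all__ = [
    "FiveBeamParams",
    "FiveBeamState",
    "build_geometry",
    "connector_return_map",
    "bending_force",
    "bending_energy",
    "solve_equilibrium",
    "simulate_monotonic",
    "simulate_cyclic",
    "parameter_sweep",
]

_N_CONNECTORS = 4


@dataclass
class FiveBeamParams:
    """Geometry and constitutive constants of the diamond unit.

    All forces and lengths are in model units; only trends and curve
    shapes are meant to be compared with experiments, not magnitudes.

    k_s
        axial stiffness of a stretching beam, model force per unit beam
        stretch.
    bend_Pcr
        critical end-compression force of the transverse beam AB; the
        bending law rises to this plateau.
    bend_harden
        dimensionless post-buckling hardening coefficient: for large end
        shortening delta the bending force approaches
        ``bend_Pcr * (1 + bend_harden * (delta - delta_on) / L_AB)``.
    bend_onset
        end shortening, as a fraction of the transverse beam length, at
        which post-buckling hardening engages.  A buckled slender beam
        deflects at near-constant end force over a long arc before the
        fold tightens and re-stiffens; the onset sets how much
        transverse contraction is available at low force.
    bend_precrit
        end shortening, as a fraction of the transverse beam length,
        over which the compliant pre-critical branch rises towards
        ``bend_Pcr`` (initial bending stiffness
        ``bend_Pcr / (bend_precrit * L_AB)``).  Large enough that the
        branch stays nearly linear through the initial soft regime,
        keeping the regime-I stiffness flat.
    k_c
        connector elastic stiffness, model force per unit slip-element
        displacement.
    f_slip
        connector slip threshold (``math.inf`` disables slip).
    H
        connector hardening modulus, model force per unit accumulated
        slip.  The default is positive: with perfect plasticity the
        connector force saturates at ``f_slip`` and the final
        stretch-dominated regime cannot plateau at a high stiffness,
        so hardening is required for the three-regime response.
    theta
        full angle, in degrees, between the two stretching beams meeting
        at a loading node (theta smaller than 90 means fibers
        preferentially aligned with the pull direction).
    scale
        reference axial half-span of the diamond.
    """

    k_s: float = 100.0
    bend_Pcr: float = 0.4
    bend_harden: float = 2000.0
    bend_onset: float = 0.35
    bend_precrit: float = 0.18
    k_c: float = 100.0
    f_slip: float = 1.2
    H: float = 20.0
    theta: float = 80.0
    scale: float = 1.0

    def __post_init__(self):
        if min(self.k_s, self.k_c) <= 0 or self.bend_Pcr <= 0:
            raise InvalidInputError("stiffnesses and bend_Pcr must be positive")
        if not (0.0 < self.theta < 180.0):
            raise InvalidInputError("theta must lie strictly between 0 and 180 degrees")
        if self.f_slip <= 0:
            raise InvalidInputError("f_slip must be positive (inf = no slip)")
        if self.H < 0 or self.bend_harden < 0:
            raise InvalidInputError("H and bend_harden must be nonnegative")
        if not (0.0 <= self.bend_onset < 1.0):
            raise InvalidInputError("bend_onset must lie in [0, 1)")
        if not (0.0 < self.bend_precrit < 1.0):
            raise InvalidInputError("bend_precrit must lie in (0, 1)")
        if self.scale <= 0:
            raise InvalidInputError("scale must be positive")

    # derived reference geometry -------------------------------------
    @property
    def half_span_ax(self) -> float:
        return self.scale

    @property
    def half_span_tr(self) -> float:
        return self.scale * math.tan(math.radians(self.theta) / 2.0)

    @property
    def beam_length0(self) -> float:
        return math.hypot(self.half_span_ax, self.half_span_tr)

    @property
    def ab_length0(self) -> float:
        return 2.0 * self.half_span_tr

    @property
    def width_ref(self) -> float:
        """Reference transverse width of the unit (span A-B)."""
        return 2.0 * self.half_span_tr

    @property
    def k_series(self) -> float:
        """Elastic stiffness of beam + connector in series (force per
        unit elongation of the pair)."""
        return 1.0 / (self.beam_length0 / self.k_s + 1.0 / self.k_c)


@dataclass
class FiveBeamState:
    """Converged state of the diamond at one load level."""

    lambda_ax: float
    lambda_tr: float
    slip: np.ndarray  # signed plastic slip per connector (4,)
    beam_force: np.ndarray  # axial force in each diagonal (4,), tension > 0
    ab_force: float  # compressive force in beam AB (> 0 when shortened)
    force_per_width: float  # axial reaction per unit reference width
    work: float = 0.0  # cumulative external work
    elastic_energy: float = 0.0
    dissipation: float = 0.0
    ab_in_tension: bool = False

    def node_positions(self, params: FiveBeamParams) -> dict[str, tuple[float, float]]:
        x = params.half_span_ax * self.lambda_ax
        b = params.half_span_tr * self.lambda_tr
        return {"A": (0.0, b), "B": (0.0, -b), "C": (x, 0.0), "D": (-x, 0.0)}


def build_geometry(theta: float, scale: float = 1.0) -> FiveBeamState:
    """Initial (undeformed, force-free) state for a given diamond angle.

    Loading nodes C, D sit at (+-scale, 0); transverse nodes A, B at
    (0, +-scale*tan(theta/2)) so that the angle between beams CA and CB
    at the loading node equals ``theta`` degrees.
    """
    if not (0.0 < theta < 180.0):
        raise InvalidInputError("theta must lie strictly between 0 and 180 degrees")
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    return FiveBeamState(
        lambda_ax=1.0,
        lambda_tr=1.0,
        slip=np.zeros(_N_CONNECTORS),
        beam_force=np.zeros(_N_CONNECTORS),
        ab_force=0.0,
        force_per_width=0.0,
    )


def connector_return_map(
    f_trial: float,
    slip_prev: float,
    params: FiveBeamParams,
    k_elastic: float | None = None,
    acc_prev: float | None = None,
) -> tuple[float, float]:
    """1-D rate-independent elastoplastic return map.

    ``f_trial`` is the elastically predicted force at frozen slip.  If
    it lies inside the yield surface ``|f| <= f_slip + H * acc`` the
    step is elastic; otherwise the force returns to the surface and the
    excess is absorbed by plastic slip:
    ``dslip = (|f_trial| - yield) / (k + H) * sign(f_trial)``.

    ``acc_prev`` is the accumulated (isotropic-hardening) slip; it
    defaults to ``|slip_prev|``, which is identical for histories that
    never reverse the slip direction.  Callers integrating reversing
    load paths should carry ``acc`` explicitly
    (``acc += |slip_new - slip_prev|``): hardening on accumulated slip
    is what makes the map exactly rate independent on such paths.

    ``k_elastic`` is the elastic stiffness through which the slip
    relaxes the force; it defaults to the connector stiffness ``k_c``
    (the equilibrium solver passes the beam+connector series stiffness
    instead).
    """
    if not (math.isfinite(f_trial) and math.isfinite(slip_prev)):
        raise InvalidInputError("return map inputs must be finite")
    k = params.k_c if k_elastic is None else k_elastic
    if not math.isfinite(params.f_slip):
        return f_trial, slip_prev
    acc = abs(slip_prev) if acc_prev is None else acc_prev
    yield_force = params.f_slip + params.H * acc
    if abs(f_trial) <= yield_force:
        return f_trial, slip_prev
    dslip = (abs(f_trial) - yield_force) / (k + params.H) * math.copysign(1.0, f_trial)
    return f_trial - k * dslip, slip_prev + dslip


def bending_force(shortening: float, params: FiveBeamParams) -> tuple[float, bool]:
    """Compressive end force of the transverse beam AB.

    For end shortening ``delta >= 0`` the law is a smooth two-branch
    curve: a compliant pre-critical branch with initial stiffness
    ``bend_Pcr / (0.05 * L_AB)`` that saturates exponentially at the
    plateau ``bend_Pcr``, plus a post-buckling hardening branch that
    engages smoothly beyond the onset shortening
    ``bend_onset * L_AB`` and is asymptotically linear,
    ``P ~ bend_Pcr * (1 + bend_harden * (delta - delta_on) / L_AB)``.
    The law is monotone nondecreasing, continuous and differentiable
    with P(0) = 0.

    Negative shortening (AB longer than its reference) is off the
    physical loading path and is treated as straight-beam axial
    response with stiffness ``k_s``; the second return value flags it.
    """
    L0 = params.ab_length0
    if shortening < 0:
        return params.k_s * (shortening / L0), True
    pcr = params.bend_Pcr
    k0 = pcr / (params.bend_precrit * L0)
    p = pcr * (1.0 - math.exp(-k0 * shortening / pcr))
    if params.bend_harden > 0:
        k_h = pcr * params.bend_harden / L0
        d_on = params.bend_onset * L0
        w = 0.01 * L0  # smoothing width of the hardening knee
        d = shortening - d_on
        ramp = 0.5 * (d + math.hypot(d, w))
        ramp0 = 0.5 * (-d_on + math.hypot(d_on, w))
        p += k_h * (ramp - ramp0)
    return p, False


def _ramp_integral(d: float, w: float) -> float:
    """Integral from -inf-anchored smooth ramp 0.5*(d + hypot(d, w))."""
    return 0.25 * d * d + 0.25 * (d * math.hypot(d, w) + w * w * math.asinh(d / w))


def bending_energy(shortening: float, params: FiveBeamParams) -> float:
    """Stored energy of the bending law (path-independent, elastic)."""
    L0 = params.ab_length0
    if shortening < 0:
        return 0.5 * params.k_s * shortening**2 / L0
    pcr = params.bend_Pcr
    k0 = pcr / (params.bend_precrit * L0)
    u = pcr * (shortening + (pcr / k0) * (math.exp(-k0 * shortening / pcr) - 1.0))
    if params.bend_harden > 0:
        k_h = pcr * params.bend_harden / L0
        d_on = params.bend_onset * L0
        w = 0.01 * L0
        ramp0 = 0.5 * (-d_on + math.hypot(d_on, w))
        u += k_h * (
            _ramp_integral(shortening - d_on, w)
            - _ramp_integral(-d_on, w)
            - ramp0 * shortening
        )
    return u


def _diagonal_forces(
    params: FiveBeamParams, x: float, b: float, slip_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return-map evaluation of the four (identical) diagonal elements.

    Each diagonal is a stretching beam in series with a connector; for
    a trial geometry the pair elongation is split elastically at frozen
    slip and returned to the yield surface if needed.
    """
    L0 = params.beam_length0
    L = math.hypot(x, b)
    dL = L - L0
    k_ser = params.k_series
    forces = np.empty(_N_CONNECTORS)
    slips = np.empty(_N_CONNECTORS)
    for i in range(_N_CONNECTORS):
        f_trial = k_ser * (dL - slip_prev[i])
        f, s = connector_return_map(f_trial, slip_prev[i], params, k_elastic=k_ser)
        forces[i] = f
        slips[i] = s
    return forces, slips, L


def _transverse_residual(
    params: FiveBeamParams, x: float, b: float, slip_prev: np.ndarray
) -> float:
    """Net transverse force on node A (positive = pushes A outward)."""
    forces, _, L = _diagonal_forces(params, x, b, slip_prev)
    n_mean = float(forces.mean())
    delta = params.ab_length0 - 2.0 * b
    p_ab, _ = bending_force(delta, params)
    return p_ab - 2.0 * n_mean * b / L


def solve_equilibrium(
    params: FiveBeamParams,
    state_prev: FiveBeamState,
    lambda_ax_target: float,
    max_expand: int = 60,
) -> FiveBeamState:
    """Advance the diamond quasi-statically to a prescribed axial stretch.

    With the C-D span prescribed, the transverse half-span is found by
    bracketed root finding on the net transverse force at node A
    (mirror symmetry makes B automatic), with the connector return map
    evaluated implicitly inside the residual.  The converged residual
    is verified against ``1e-10 * k_s``.

    Energy bookkeeping: external work is accumulated by the trapezoid
    rule on the axial reaction, elastic energy is evaluated in closed
    form, and the dissipation increment is the plastic product
    ``sum(f * dslip)`` (nonnegative by construction of the return map).
    """
    if lambda_ax_target <= 0:
        raise InvalidInputError("lambda_ax_target must be positive")
    x = params.half_span_ax * lambda_ax_target
    b0 = params.half_span_tr
    slip_prev = state_prev.slip

    def g(b: float) -> float:
        return _transverse_residual(params, x, b, slip_prev)

    lo = 1e-9 * b0
    hi = max(b0 * state_prev.lambda_tr, b0) * 1.05
    glo = g(lo)
    ghi = g(hi)
    n_exp = 0
    while glo * ghi > 0 and n_exp < max_expand:
        hi *= 1.3
        ghi = g(hi)
        n_exp += 1
    if glo * ghi > 0:
        raise SolverError(
            f"transverse equilibrium not bracketed at lambda_ax={lambda_ax_target:g} "
            f"(residuals {glo:g}, {ghi:g})"
        )
    b = brentq(g, lo, hi, xtol=1e-14 * max(b0, 1.0), rtol=8.9e-16, maxiter=200)
    resid = g(b)
    # tolerance scales with the stiffest element in the residual, so the
    # check stays meaningful in stiff limits (e.g. a near-rigid beam AB)
    k_bend_scale = params.bend_Pcr / (params.bend_precrit * params.ab_length0) + (
        params.bend_Pcr * params.bend_harden / params.ab_length0
    )
    resid_tol = 1e-10 * max(params.k_s, params.k_c, k_bend_scale)
    if abs(resid) > resid_tol:
        raise SolverError(
            f"equilibrium residual {resid:g} exceeds tolerance at "
            f"lambda_ax={lambda_ax_target:g}"
        )

    forces, slips, L = _diagonal_forces(params, x, b, slip_prev)
    delta = params.ab_length0 - 2.0 * b
    p_ab, ab_tension_flag = bending_force(delta, params)

    # axial reaction at C: two diagonals pull with component x/L each
    f_axial = 2.0 * float(forces.mean()) * x / L
    fpw = f_axial / params.width_ref

    # energy bookkeeping ---------------------------------------------
    k_ser = params.k_series
    elastic = float(np.sum(forces**2)) / (2.0 * k_ser) + bending_energy(delta, params)
    d_slip = slips - slip_prev
    d_diss = float(np.sum(forces * d_slip))
    # external work: axial force through the motion of both loading nodes
    dx_total = 2.0 * (x - params.half_span_ax * state_prev.lambda_ax)
    f_axial_prev = state_prev.force_per_width * params.width_ref
    d_work = 0.5 * (f_axial + f_axial_prev) * dx_total

    return FiveBeamState(
        lambda_ax=float(lambda_ax_target),
        lambda_tr=float(b / b0),
        slip=slips,
        beam_force=forces,
        ab_force=p_ab,
        force_per_width=fpw,
        work=state_prev.work + d_work,
        elastic_energy=elastic,
        dissipation=state_prev.dissipation + d_diss,
        ab_in_tension=ab_tension_flag,
    )


def simulate_monotonic(
    params: FiveBeamParams, lambda_grid
) -> tuple[ModelCurve, list[FiveBeamState]]:
    """Quasi-static monotonic stretch over an increasing grid from 1."""
    lam = np.asarray(lambda_grid, dtype=float)
    if abs(lam[0] - 1.0) > 1e-9 or np.any(np.diff(lam) <= 0):
        raise InvalidInputError("lambda_grid must start at 1 and be strictly increasing")
    state = build_geometry(params.theta, params.scale)
    states = [state]
    ltr = np.empty_like(lam)
    f = np.empty_like(lam)
    ltr[0], f[0] = 1.0, 0.0
    for i, la in enumerate(lam[1:], start=1):
        state = solve_equilibrium(params, state, la)
        states.append(state)
        ltr[i] = state.lambda_tr
        f[i] = state.force_per_width
    return ModelCurve.from_primary(lam, f, ltr), states


def _unload_to_zero(
    params: FiveBeamParams,
    state: FiveBeamState,
    dlam: float,
    record,
) -> FiveBeamState:
    """Step the stretch down until the axial force crosses zero, then
    refine the zero crossing by bisection (elastic near zero force, so
    re-solving from the last positive-force state is path-consistent)."""
    while state.force_per_width > 0.0:
        la_next = state.lambda_ax - dlam
        if la_next < 1e-3:
            raise SolverError("unloading ran away below lambda_ax ~ 0")
        nxt = solve_equilibrium(params, state, la_next)
        if nxt.force_per_width <= 0.0:
            lo_lam, hi_lam = la_next, state.lambda_ax
            base = state
            tol = 1e-10 * params.k_s / params.width_ref
            lam_mid, mid = la_next, nxt
            for _ in range(200):
                lam_mid = 0.5 * (lo_lam + hi_lam)
                mid = solve_equilibrium(params, base, lam_mid)
                if abs(mid.force_per_width) <= tol:
                    break
                if mid.force_per_width > 0.0:
                    hi_lam = lam_mid
                else:
                    lo_lam = lam_mid
            record(mid)
            return mid
        state = nxt
        record(state)
    return state


def simulate_cyclic(
    params: FiveBeamParams,
    peak_list,
    dlam: float = 0.002,
    rate: float = 0.0025,
) -> tuple[CyclicCurve, RecoveryResult]:
    """Incremental cyclic loading: load to each peak, unload to zero force.

    Peaks must be increasing with the first above 1.  The trace is
    assembled into a labelled cyclic curve (pseudo-time advances at a
    constant stretch rate) and recovery is computed with the standard
    cyclic analysis.  Reloading past a previous peak rejoins the
    monotonic envelope because plastic history is carried through.
    """
    peaks = np.asarray(peak_list, dtype=float)
    if len(peaks) < 1 or peaks[0] <= 1.0 or np.any(np.diff(peaks) <= 0):
        raise InvalidInputError("peaks must be increasing and above 1")

    state = build_geometry(params.theta, params.scale)
    lam_tr, lam_ax, f = [1.0], [1.0], [0.0]

    def record(s: FiveBeamState):
        lam_ax.append(s.lambda_ax)
        lam_tr.append(s.lambda_tr)
        f.append(s.force_per_width)

    for peak in peaks:
        # load up to the peak
        while state.lambda_ax < peak - 1e-12:
            la_next = min(state.lambda_ax + dlam, peak)
            state = solve_equilibrium(params, state, la_next)
            record(state)
        # unload to zero axial force
        state = _unload_to_zero(params, state, dlam, record)

    lam_ax = np.asarray(lam_ax)
    time = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(lam_ax)))]) / rate
    # pseudo-time must be strictly increasing for the spline-based
    # reversal detection; the bisection endpoint can repeat a stretch
    time += np.arange(len(time)) * 1e-9
    raw = RawCurve(
        time=time,
        lambda_ax=lam_ax,
        lambda_tr=np.asarray(lam_tr),
        force_per_width=np.asarray(f),
        label="five-beam cyclic",
    )
    cyc = split_cycles(raw)
    rec = recovery_analysis(cyc)
    return cyc, rec


def parameter_sweep(
    base: FiveBeamParams,
    vary: str,
    values,
    lambda_max: float = 1.5,
    n_steps: int = 250,
    extraction_config=None,
    cyclic_peaks=None,
) -> list[dict]:
    """One summary row per parameter value.

    Each run simulates the monotonic response to ``lambda_max`` and
    extracts the standard summary; if ``cyclic_peaks`` is given, the
    per-cycle recovery table is attached as well.
    """
    from .analysis import extract_summary

    if not hasattr(base, vary):
        raise InvalidInputError(f"unknown parameter {vary!r}")
    rows = []
    grid = np.linspace(1.0, lambda_max, n_steps)
    for v in values:
        params = replace(base, **{vary: v})
        curve, _ = simulate_monotonic(params, grid)
        summary = extract_summary(curve.as_derived(), lambda_max, extraction_config)
        row = {"value": float(v), "summary": summary, "curve": curve}
        if cyclic_peaks is not None:
            _, rec = simulate_cyclic(params, cyclic_peaks)
            row["recovery"] = rec
        rows.append(row)
    return rows
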