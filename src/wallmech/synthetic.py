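"""Synthetic tensile curves with the structure the analysis assumes.

The generator emulates the phenomenology of epidermal-peel tensile
tests so the whole pipeline is testable without experimental data:

* a three-regime tangent-stiffness profile (soft plateau at
  ``E1_gen`` ~ 12 N/m, smoothstep ramp, stiff plateau at
  ``E2_gen`` ~ 70 N/m),
* a nonmonotonic incremental Poisson's ratio that rises past 1 to a
  peak then declines,
* incremental cyclic loading whose recovery decreases from its initial
  level (> 80 %) to a floor (~ 40 %) across the stiffening ramp and
  then plateaus,
* additive Gaussian measurement noise on force and transverse stretch
  (the axial stretch is the displacement-controlled variable).

Every generated dataset carries machine-readable ground truth: the
windowed summary values computed analytically from the noiseless
profiles with the same definitions the analysis uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import CyclicCurve, DerivedCurves, RawCurve
from .errors import InvalidInputError

__all__ = ["GeneratorProfile", "GroundTruth", "generate_monotonic", "generate_cyclic", "generate_from_model"]

_STRAIN_RATE = 0.0025  # 1/s; ~2.5 um/s on a ~1 mm gauge


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _smoothstep_int(t):
    """Integral of the cubic smoothstep from 0 (continues linearly with
    unit slope past t = 1, where the smoothstep has saturated)."""
    t = np.asarray(t, dtype=float)
    tc = np.clip(t, 0.0, 1.0)
    return tc**3 - 0.5 * tc**4 + np.where(t > 1.0, t - 1.0, 0.0)


@dataclass
class GeneratorProfile:
    """Target phenomenology of one synthetic test.

    Stiffness levels are the regime I / regime III plateaus in N/m;
    the ramp bounds are generator conventions for regime II.  The
    Poisson profile is a Gaussian bump over a baseline:
    ``nu(lambda) = nu1_gen + (nu2_gen - nu1_gen) *
    exp(-((lambda - nu_peak_at)/nu_width)^2)``.
    """

    E1_gen: float = 12.0
    E2_gen: float = 70.0
    ramp_start: float = 1.10
    ramp_end: float = 1.25
    nu1_gen: float = 0.30
    nu2_gen: float = 1.10
    nu_peak_at: float = 1.30
    nu_width: float = 0.10
    recovery_initial: float = 85.0
    recovery_floor: float = 40.0
    noise_sd_force: float = 0.01
    noise_sd_stretch: float = 0.001
    lambda_max: float = 1.5
    n_points: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (1.0 < self.ramp_start < self.ramp_end):
            raise InvalidInputError("need 1 < ramp_start < ramp_end")
        if not (self.E2_gen >= self.E1_gen > 0):
            raise InvalidInputError("need E2_gen >= E1_gen > 0")
        if not (0 <= self.recovery_floor <= self.recovery_initial <= 100):
            raise InvalidInputError("recovery schedule must satisfy 0 <= floor <= initial <= 100")
        if self.lambda_max <= self.ramp_end:
            raise InvalidInputError("lambda_max must exceed ramp_end")
        if self.n_points < 16:
            raise InvalidInputError("n_points too small")

    # ---- noiseless profiles ----------------------------------------
    def stiffness(self, lam):
        t = (np.asarray(lam, dtype=float) - self.ramp_start) / (self.ramp_end - self.ramp_start)
        return self.E1_gen + (self.E2_gen - self.E1_gen) * _smoothstep(t)

    def force(self, lam):
        """Exact integral of the stiffness profile from 1."""
        lam = np.asarray(lam, dtype=float)
        span = self.ramp_end - self.ramp_start
        t = (lam - self.ramp_start) / span
        return self.E1_gen * (lam - 1.0) + (self.E2_gen - self.E1_gen) * span * _smoothstep_int(t)

    def nu_inc(self, lam):
        lam = np.asarray(lam, dtype=float)
        return self.nu1_gen + (self.nu2_gen - self.nu1_gen) * np.exp(
            -(((lam - self.nu_peak_at) / self.nu_width) ** 2)
        )

    def lambda_tr(self, lam):
        """Transverse stretch from the Poisson profile:
        ``lambda_tr = exp(-int nu d ln(lambda))``."""
        lam = np.asarray(lam, dtype=float)
        dense = np.linspace(1.0, max(float(lam.max()), 1.0) + 1e-9, 4001)
        integrand = self.nu_inc(dense) / dense
        cumulative = np.concatenate(
            [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(dense))]
        )
        return np.exp(-np.interp(lam, dense, cumulative))

    def recovery_schedule(self, lam_peak):
        """Recovery percentage after unloading from ``lam_peak``:
        recovery_initial before the ramp, smoothstep down to
        recovery_floor at ramp_end, constant after."""
        t = (np.asarray(lam_peak, dtype=float) - self.ramp_start) / (
            self.ramp_end - self.ramp_start
        )
        return self.recovery_initial - (self.recovery_initial - self.recovery_floor) * _smoothstep(t)


@dataclass
class GroundTruth:
    """Windowed summary values of the noiseless profiles.

    Computed analytically (fine quadrature) with the same window
    definitions the analysis uses, independently of the spline
    pipeline.
    """

    E1: float
    E2: float
    nu1: float
    nu2: float
    derived: DerivedCurves
    recovery_by_peak: dict = field(default_factory=dict)


def _window_mean(fn, lo: float, hi: float, n: int = 2001) -> float:
    xs = np.linspace(lo, hi, n)
    return float(np.trapezoid(fn(xs), xs) / (hi - lo))


def _ground_truth(profile: GeneratorProfile) -> GroundTruth:
    lam_max = profile.lambda_max
    grid = np.linspace(1.0, lam_max, 2001)
    derived = DerivedCurves(grid, profile.stiffness(grid), profile.nu_inc(grid))
    peak = min(profile.nu_peak_at, lam_max)
    return GroundTruth(
        E1=_window_mean(profile.stiffness, 1.02, 1.05),
        E2=_window_mean(profile.stiffness, profile.ramp_end, lam_max - 0.05),
        nu1=_window_mean(profile.nu_inc, 1.02, 1.05),
        nu2=_window_mean(
            profile.nu_inc, max(1.0, peak - 0.05), min(lam_max, peak + 0.05)
        ),
        derived=derived,
    )


def generate_monotonic(profile: GeneratorProfile) -> tuple[RawCurve, GroundTruth]:
    """Monotonic tensile curve with seeded additive noise.

    The axial stretch is sampled uniformly at a constant stretch rate;
    Gaussian noise is added to the force and the transverse stretch
    only (displacement control).  The noiseless profile values are
    returned alongside as ground truth.
    """
    lam = np.linspace(1.0, profile.lambda_max, profile.n_points)
    time = (lam - 1.0) / _STRAIN_RATE
    force = profile.force(lam)
    ltr = profile.lambda_tr(lam)
    rng = np.random.default_rng(profile.seed)
    force = force + rng.normal(0.0, profile.noise_sd_force, size=lam.shape)
    ltr = ltr + rng.normal(0.0, profile.noise_sd_stretch, size=lam.shape)
    raw = RawCurve(
        time=time,
        lambda_ax=lam,
        lambda_tr=ltr,
        force_per_width=force,
        label=f"synthetic monotonic (seed={profile.seed})",
    )
    return raw, _ground_truth(profile)


def generate_cyclic(
    profile: GeneratorProfile, peak_list, points_per_unit_stretch: int = 600
) -> tuple[CyclicCurve, GroundTruth]:
    """Incremental cyclic curve with labelled ground truth.

    Loading follows the monotonic envelope exactly; unloading follows a
    straight chord in (stretch, force) down to the residual stretch set
    by the recovery schedule at that cycle's peak; reloading retraces
    the chord and rejoins the envelope at the previous peak.  The
    transverse stretch recovers by the same percentage towards 1.
    Noise is added as in the monotonic generator.
    """
    peaks = np.asarray(peak_list, dtype=float)
    if len(peaks) < 1 or peaks[0] <= 1.0 or np.any(np.diff(peaks) <= 0):
        raise InvalidInputError("peaks must be increasing and above 1")
    if peaks[-1] > profile.lambda_max:
        raise InvalidInputError("peaks must not exceed lambda_max")

    lam_parts, f_parts, ltr_parts = [], [], []
    cyc_parts, phase_parts = [], []
    truth = _ground_truth(profile)

    lam_prev_peak = 1.0
    residual_prev, residual_tr_prev = 1.0, 1.0
    for ci, peak in enumerate(peaks, start=1):
        r = float(profile.recovery_schedule(peak))
        residual = peak - (r / 100.0) * (peak - 1.0)
        f_peak = float(profile.force(peak))
        ltr_peak = float(profile.lambda_tr(peak))
        residual_tr = ltr_peak + (r / 100.0) * (1.0 - ltr_peak)
        truth.recovery_by_peak[round(peak, 12)] = r

        # loading: chord from the previous residual up to the previous
        # peak, then the envelope up to the new peak
        n_chord = max(int(points_per_unit_stretch * (lam_prev_peak - residual_prev)), 2)
        n_env = max(int(points_per_unit_stretch * (peak - lam_prev_peak)), 2)
        if ci == 1:
            lam_load = np.linspace(1.0, peak, n_env + n_chord)
            f_load = profile.force(lam_load)
            ltr_load = profile.lambda_tr(lam_load)
        else:
            lam_chord = np.linspace(residual_prev, lam_prev_peak, n_chord, endpoint=False)
            w = (lam_chord - residual_prev) / (lam_prev_peak - residual_prev)
            f_chord = w * float(profile.force(lam_prev_peak))
            ltr_chord = residual_tr_prev + w * (
                float(profile.lambda_tr(lam_prev_peak)) - residual_tr_prev
            )
            lam_env = np.linspace(lam_prev_peak, peak, n_env)
            lam_load = np.concatenate([lam_chord, lam_env])
            f_load = np.concatenate([f_chord, profile.force(lam_env)])
            ltr_load = np.concatenate([ltr_chord, profile.lambda_tr(lam_env)])

        # unloading chord down to zero force at the residual stretch
        n_un = max(int(points_per_unit_stretch * (peak - residual)), 2)
        lam_un = np.linspace(peak, residual, n_un + 1)[1:]
        w = (lam_un - residual) / (peak - residual)
        f_un = w * f_peak
        ltr_un = residual_tr + w * (ltr_peak - residual_tr)

        lam_parts += [lam_load, lam_un]
        f_parts += [f_load, f_un]
        ltr_parts += [ltr_load, ltr_un]
        cyc_parts += [np.full(len(lam_load), ci), np.full(len(lam_un), ci)]
        phase_parts += [
            np.full(len(lam_load), "loading", dtype=object),
            np.full(len(lam_un), "unloading", dtype=object),
        ]
        lam_prev_peak = peak
        residual_prev, residual_tr_prev = residual, residual_tr

    lam = np.concatenate(lam_parts)
    f = np.concatenate(f_parts)
    ltr = np.concatenate(ltr_parts)
    cycle = np.concatenate(cyc_parts).astype(int)
    phase = np.concatenate(phase_parts)
    time = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(lam)))]) / _STRAIN_RATE
    time += np.arange(len(time)) * 1e-9  # strictly increasing

    rng = np.random.default_rng(profile.seed)
    f = f + rng.normal(0.0, profile.noise_sd_force, size=lam.shape)
    ltr = ltr + rng.normal(0.0, profile.noise_sd_stretch, size=lam.shape)

    raw = RawCurve(
        time=time,
        lambda_ax=lam,
        lambda_tr=ltr,
        force_per_width=f,
        label=f"synthetic cyclic (seed={profile.seed})",
    )
    return CyclicCurve(raw, cycle, phase), truth


def generate_from_model(
    params,
    loading,
    noise_sd_force: float = 0.0,
    noise_sd_stretch: float = 0.0,
    seed: int = 0,
    n_resample: int = 400,
) -> RawCurve:
    """Five-beam-driven fixture: simulate, resample on a uniform time
    grid, add seeded noise.

    ``loading`` is either an increasing stretch grid (monotonic) or the
    dict ``{"peaks": [...]}`` for incremental cyclic loading.
    """
    from .fivebeam import simulate_cyclic, simulate_monotonic

    if isinstance(loading, dict):
        cyc, _ = simulate_cyclic(params, loading["peaks"])
        raw = cyc.raw
    else:
        curve, _ = simulate_monotonic(params, np.asarray(loading, dtype=float))
        lam = curve.lambda_grid
        time = (lam - 1.0) / _STRAIN_RATE
        raw = RawCurve(time, lam, curve.lambda_tr, curve.force_per_width, label="five-beam")

    t_new = np.linspace(raw.time[0], raw.time[-1], n_resample)
    lam = np.interp(t_new, raw.time, raw.lambda_ax)
    ltr = np.interp(t_new, raw.time, raw.lambda_tr)
    f = np.interp(t_new, raw.time, raw.force_per_width)
    rng = np.random.default_rng(seed)
    f = f + rng.normal(0.0, noise_sd_force, size=f.shape)
    ltr = ltr + rng.normal(0.0, noise_sd_stretch, size=ltr.shape)
    return RawCurve(t_new, lam, ltr, f, label=raw.label + " (resampled)")
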