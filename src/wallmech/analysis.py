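"""Tensile-curve analysis: smoothing, tangent quantities, regime summary,
cycle splitting and recovery.

The pipeline mirrors standard post-processing of displacement-controlled
membrane tensile tests: raw series are smoothed with a smoothing spline
constrained to R-squared > 0.999, and all tangent quantities (stiffness,
incremental Poisson's ratio) are evaluated from the smoothed
representation, never from finite differences of raw samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline

from .curves import (
    CycleRecovery,
    CyclicCurve,
    DerivedCurves,
    MechanicalSummary,
    RawCurve,
    RecoveryResult,
)
from .errors import (
    ConstraintInfeasibleError,
    ExtrapolationError,
    InvalidInputError,
    NotCyclicError,
    PlateauNotFoundError,
    RangeTooShortError,
)

__all__ = [
    "SmoothedCurve",
    "ExtractionConfig",
    "smooth_curve",
    "tangent_stiffness",
    "incremental_poisson",
    "derive_curves",
    "extract_summary",
    "split_cycles",
    "recovery_analysis",
    "residual_vs_force",
    "analyze_monotonic",
]


# ---------------------------------------------------------------------------
# Smoothing


@dataclass
class SmoothedCurve:
    """A smooth 1-D function fit: evaluable value and first derivative.

    Wraps a penalized cubic smoothing spline; ``fit_r2`` is the
    coefficient of determination on the samples the spline was fit to
    and ``smoothing_parameter`` the roughness-penalty weight used.
    """

    _spline: BSpline
    x_min: float
    x_max: float
    fit_r2: float
    smoothing_parameter: float

    def __call__(self, x):
        return self._spline(x)

    def derivative(self, x):
        return self._spline.derivative()(x)


def _dedupe(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average y over duplicated abscissae; x must then be increasing."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if len(ux) == len(x):
        return x, y
    sums = np.zeros(len(ux))
    np.add.at(sums, inverse, y)
    return ux, sums / counts


def _fit(x: np.ndarray, y: np.ndarray, lam: float, ss_tot: float):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spl = make_smoothing_spline(x, y, lam=lam)
    resid = y - spl(x)
    ss_res = float(resid @ resid)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return spl, r2, ss_res


def _noise_variance(y: np.ndarray) -> float:
    """Noise variance estimate from third differences.

    For a smooth signal plus white noise the third difference has
    variance 20 sigma^2 plus a bias of order (signal third derivative
    x h^3), which is negligible at any realistic sampling density --
    a model-free estimator suited to smoothing-parameter selection.
    """
    if len(y) < 4:
        return 0.0
    d3 = y[3:] - 3.0 * y[2:-1] + 3.0 * y[1:-2] - y[:-3]
    return float((d3 @ d3) / (20.0 * len(d3)))


_DERIV_OVERSMOOTH = 1e3  # penalty multiplier for derivative stability
_BANDWIDTH_FRAC = 0.04  # resolution ceiling: kernel bandwidth as a
# fraction of the abscissa range (bias control for the derivative)
_LAM_TINY = 1e-13  # effectively interpolating


def smooth_curve(x, y, r2_min: float = 0.999) -> SmoothedCurve:
    """Fit a penalized cubic smoothing spline with R-squared > ``r2_min``.

    The roughness penalty is the smallest of three scales:

    * a noise floor: the discrepancy-principle penalty (residual sum
      of squares equal to its expectation under the noise level
      estimated from third differences) times a fixed oversmoothing
      factor, because the quantities of interest are *derivatives* of
      the fit and the value-optimal penalty leaves them visibly rough.
      Noise-free data therefore gets an effectively interpolating fit;
    * a resolution ceiling: the penalty whose equivalent kernel
      bandwidth is a fixed fraction of the abscissa range, which
      bounds the smoothing bias of the derivative regardless of how
      noisy the data looks;
    * the largest penalty that still satisfies the R-squared
      constraint, found by log-scale bisection (the constraint alone
      leaves the smoothing level underdetermined by orders of
      magnitude).

    Raises
    ------
    InvalidInputError
        if fewer than 4 distinct abscissae remain after deduplication.
    ConstraintInfeasibleError
        if no smoothing level reaches ``r2_min`` (carries the best
        achievable R-squared).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    x, y = _dedupe(x, y)
    if len(x) < 4:
        raise InvalidInputError("need at least 4 distinct samples to smooth")
    if np.any(np.diff(x) <= 0):
        raise InvalidInputError("x must be strictly increasing after deduplication")

    ybar = y.mean()
    ss_tot = float(((y - ybar) ** 2).sum())
    if ss_tot == 0.0:
        # constant data: the (near-)interpolating spline is exact
        spl, _, _ = _fit(x, y, _LAM_TINY, 1.0)
        return SmoothedCurve(spl, float(x[0]), float(x[-1]), 1.0, _LAM_TINY)

    # feasibility anchor: near-interpolation
    spl_lo, r2_lo, _ = _fit(x, y, _LAM_TINY, ss_tot)
    if not r2_lo > r2_min:
        raise ConstraintInfeasibleError(
            f"no smoothing level achieves R^2 > {r2_min}; "
            f"best achievable R^2 = {r2_lo:.6f}",
            best_r2=r2_lo,
        )

    # cap: largest penalty still satisfying the R^2 constraint
    lam_cap, spl_cap, r2_cap = _LAM_TINY, spl_lo, r2_lo
    lo, hi = _LAM_TINY, 1e8
    spl_hi, r2_hi, _ = _fit(x, y, hi, ss_tot)
    if r2_hi > r2_min:
        lam_cap, spl_cap, r2_cap = hi, spl_hi, r2_hi
    else:
        for _ in range(60):
            mid = float(np.sqrt(lo * hi))
            spl, r2, _ = _fit(x, y, mid, ss_tot)
            if r2 > r2_min:
                lam_cap, spl_cap, r2_cap = mid, spl, r2
                lo = mid
            else:
                hi = mid
            if hi / lo < 1.001:
                break

    # noise floor: discrepancy level from the estimated noise, times
    # the derivative oversmoothing factor
    ss_target = _noise_variance(y) * len(y)
    if ss_target <= ss_tot * 1e-12:
        lam_op = _LAM_TINY
    else:
        lo, hi = _LAM_TINY, 1e8
        for _ in range(60):
            mid = float(np.sqrt(lo * hi))
            _, _, ss_res = _fit(x, y, mid, ss_tot)
            if ss_res < ss_target:
                lo = mid
            else:
                hi = mid
            if hi / lo < 1.001:
                break
        lam_op = float(np.sqrt(lo * hi)) * _DERIV_OVERSMOOTH

    # resolution ceiling: equivalent kernel bandwidth of the penalized
    # spline is h ~ (lam / density)^(1/4) with density n / X
    x_range = float(x[-1] - x[0])
    lam_bw = (len(x) / x_range) * (_BANDWIDTH_FRAC * x_range) ** 4

    lam_final = min(lam_op, lam_bw, lam_cap)
    if lam_final >= lam_cap:
        return SmoothedCurve(spl_cap, float(x[0]), float(x[-1]), r2_cap, lam_cap)
    spl, r2, _ = _fit(x, y, lam_final, ss_tot)
    if not r2 > r2_min:  # numerical safety: fall back to the cap fit
        return SmoothedCurve(spl_cap, float(x[0]), float(x[-1]), r2_cap, lam_cap)
    return SmoothedCurve(spl, float(x[0]), float(x[-1]), r2, lam_final)


# ---------------------------------------------------------------------------
# Tangent quantities


def _check_in_interval(curve: SmoothedCurve, grid: np.ndarray):
    tol = 1e-9 * max(1.0, abs(curve.x_max - curve.x_min))
    if grid.min() < curve.x_min - tol or grid.max() > curve.x_max + tol:
        raise ExtrapolationError(
            f"grid [{grid.min():g}, {grid.max():g}] extends outside the "
            f"fitted interval [{curve.x_min:g}, {curve.x_max:g}]"
        )


def tangent_stiffness(curve: SmoothedCurve, grid) -> np.ndarray:
    """First derivative of the smoothed force-stretch curve on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    _check_in_interval(curve, grid)
    return curve.derivative(grid)


def incremental_poisson(tr_curve: SmoothedCurve, grid) -> np.ndarray:
    """Incremental Poisson's ratio -d ln(lambda_tr)/d ln(lambda_ax).

    ``tr_curve`` is the smoothed transverse stretch as a function of the
    axial stretch; with lambda_tr > 0 the chain rule gives
    ``nu_inc = -(lambda_ax / lambda_tr) * d lambda_tr / d lambda_ax``.
    """
    grid = np.asarray(grid, dtype=float)
    _check_in_interval(tr_curve, grid)
    ltr = tr_curve(grid)
    if np.any(ltr <= 0):
        raise InvalidInputError("lambda_tr must be positive over the grid")
    return -(grid / ltr) * tr_curve.derivative(grid)


def derive_curves(raw: RawCurve, n_grid: int = 400, r2_min: float = 0.999) -> DerivedCurves:
    """Smooth a monotonic raw curve and tabulate the tangent quantities.

    Both the force-stretch and the transverse-axial stretch relations
    are smoothed against the axial stretch; the derived quantities are
    evaluated on an evenly spaced grid spanning the measured range.
    """
    f_curve = smooth_curve(raw.lambda_ax, raw.force_per_width, r2_min)
    tr_curve = smooth_curve(raw.lambda_ax, raw.lambda_tr, r2_min)
    grid = np.linspace(f_curve.x_min, f_curve.x_max, n_grid)
    k = tangent_stiffness(f_curve, grid)
    nu = incremental_poisson(tr_curve, grid)
    return DerivedCurves(grid, k, nu)


# ---------------------------------------------------------------------------
# Summary extraction


@dataclass
class ExtractionConfig:
    """Thresholds for regime identification.

    plateau_frac
        the final plateau starts where |dk/dlambda| first falls below
        ``plateau_frac * (range of k) / (range of lambda)`` beyond the
        end of regime I.  A relative criterion keeps the rule
        scale-free.
    regime1_factor
        regime I is taken to end where the stiffness first exceeds
        ``regime1_factor * E1``.
    e1_window
        stretch window over which E1 and nu1 are averaged.
    edge_margin
        the final-stiffness window stops this far short of the maximum
        stretch, avoiding spline edge effects.
    nu2_halfwidth
        half-width of the averaging window centred at the
        incremental-Poisson peak.
    """

    plateau_frac: float = 0.10
    regime1_factor: float = 1.2
    e1_window: tuple[float, float] = (1.02, 1.05)
    edge_margin: float = 0.05
    nu2_halfwidth: float = 0.05


def _window_mean(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Mean of y over [lo, hi], interpolation-based so the result does
    not depend on whether the window edges fall on grid nodes."""
    if hi <= lo:
        return float(np.interp(lo, x, y))
    xs = np.linspace(lo, hi, 201)
    return float(np.trapezoid(np.interp(xs, x, y), xs) / (hi - lo))


def _refine_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Abscissa of the maximum, refined by a local quadratic fit so the
    peak location varies continuously with resampling density."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1 : i + 2]
    coeffs = np.polyfit(x[i - 1 : i + 2] - x1, y[i - 1 : i + 2], 2)
    if coeffs[0] >= 0:  # not locally concave; keep the grid node
        return float(x1)
    vertex = x1 - coeffs[1] / (2.0 * coeffs[0])
    return float(min(max(vertex, x0), x2))


def extract_summary(
    derived: DerivedCurves,
    lambda_max: float,
    config: ExtractionConfig | None = None,
) -> MechanicalSummary:
    """Extract E1, E2, nu1, nu2 and regime bounds from derived curves.

    E1 and nu1 are means over the initial window (1.02-1.05); E2 is the
    mean tangent stiffness from the first stretch (past regime I) where
    the stiffness derivative settles near zero, up to
    ``lambda_max - edge_margin``; nu2 is the mean of the incremental
    Poisson's ratio over a +-0.05 window around its maximum, clipped to
    the data range.
    """
    cfg = config or ExtractionConfig()
    if lambda_max <= 1.1:
        raise RangeTooShortError("lambda_max must exceed 1.1 for summary extraction")
    lam = derived.lambda_grid
    k = derived.tangent_stiffness
    nu = derived.nu_inc
    w0, w1 = cfg.e1_window
    if lam[0] > w0 + 1e-9 or lam[-1] < lambda_max - 1e-9:
        raise RangeTooShortError(
            f"derived curves must cover [{w0:g}, {lambda_max:g}]; "
            f"got [{lam[0]:g}, {lam[-1]:g}]"
        )

    E1 = _window_mean(lam, k, w0, w1)
    nu1 = _window_mean(lam, nu, w0, w1)

    # End of regime I: stiffness first exceeds regime1_factor * E1.
    rise = np.nonzero((k > cfg.regime1_factor * E1) & (lam >= w1))[0]
    regime1_end = float(lam[rise[0]]) if len(rise) else w1

    # Start of regime III: |dk/dlambda| first settles below the
    # threshold AFTER the steepest point of the stiffening rise (a
    # transient flat spot between regimes I and II must not count as
    # the final plateau).
    k_range = float(k.max() - k.min())
    if k_range <= 1e-9 * max(1.0, float(np.abs(k).max())):
        lambda_star = regime1_end  # flat profile: everything is plateau
    else:
        # moving-average the slope signal over ~5% of the grid before
        # thresholding: residual spline wiggle on noisy data produces
        # local slopes far above the plateau threshold even where the
        # stiffness is flat on the window scale
        dk = np.gradient(k, lam)
        win = max(1, len(lam) // 20)
        if win > 1:
            kernel = np.ones(win) / win
            pad = win // 2
            dk_pad = np.concatenate([np.full(pad, dk[0]), dk, np.full(win - 1 - pad, dk[-1])])
            dk = np.convolve(dk_pad, kernel, mode="valid")
        threshold = cfg.plateau_frac * k_range / (lam[-1] - lam[0])
        past_r1 = lam >= regime1_end
        i_rise = int(np.argmax(np.where(past_r1, dk, -np.inf)))
        search = np.zeros_like(past_r1)
        search[i_rise:] = True
        candidates = np.nonzero((np.abs(dk) < threshold) & past_r1 & search)[0]
        if len(candidates) == 0:
            min_dk = float(np.abs(dk)[past_r1 & search].min())
            raise PlateauNotFoundError(
                "stiffness derivative never approaches zero past the "
                f"stiffening rise (min |dk/dlambda| = {min_dk:g}, "
                f"threshold {threshold:g})",
                min_abs_dk=min_dk,
            )
        lambda_star = float(lam[candidates[0]])

    e2_hi = lambda_max - cfg.edge_margin
    if lambda_star >= e2_hi:
        raise PlateauNotFoundError(
            f"plateau onset {lambda_star:g} leaves no room before "
            f"lambda_max - {cfg.edge_margin:g}",
            min_abs_dk=float("nan"),
        )
    E2 = _window_mean(lam, k, lambda_star, e2_hi)

    lam_p = _refine_peak(lam, nu)
    nu2 = _window_mean(
        lam, nu, max(lam[0], lam_p - cfg.nu2_halfwidth), min(lam[-1], lam_p + cfg.nu2_halfwidth)
    )

    return MechanicalSummary(
        E1=E1,
        E2=E2,
        nu1=nu1,
        nu2=nu2,
        regime_bounds=(regime1_end, lambda_star),
        lambda_max=float(lambda_max),
    )


# ---------------------------------------------------------------------------
# Cyclic curves


def split_cycles(raw: RawCurve, min_run: int = 2) -> CyclicCurve:
    """Label samples of a cyclic test by cycle index and loading phase.

    A reversal is a sign change of the smoothed d(lambda_ax)/dt.  Runs
    shorter than ``min_run`` samples are merged into their neighbours to
    suppress spurious reversals from smoothing wiggle near the peaks.
    """
    t, lam = raw.time, raw.lambda_ax
    try:
        sm = smooth_curve(t, lam)
        dlam = sm.derivative(t)
    except (InvalidInputError, ConstraintInfeasibleError):
        dlam = np.gradient(lam, t)

    scale = max(np.abs(dlam).max(), 1e-30)
    sign = np.where(dlam > 1e-9 * scale, 1, np.where(dlam < -1e-9 * scale, -1, 0))
    # carry the previous sign through near-zero samples
    for i in range(len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1] if i > 0 else 1

    # group into runs, merge short ones
    runs: list[list[int]] = []  # [sign, start, stop)
    start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[start]:
            runs.append([int(sign[start]), start, i])
            start = i
    while len(runs) > 1 and runs[0][2] - runs[0][1] < min_run:
        runs[1][1] = runs[0][1]  # fold a too-short leading run forward
        runs.pop(0)
    merged = [runs[0]]
    for s, a, b in runs[1:]:
        if b - a < min_run and len(runs) > 1:
            merged[-1][2] = b
        elif s == merged[-1][0]:
            merged[-1][2] = b
        else:
            merged.append([s, a, b])

    # a tensile test starts by loading: an initial "unloading" run can
    # only be smoothing wiggle at the left edge
    while len(merged) > 1 and merged[0][0] < 0:
        merged[1][1] = merged[0][1]
        merged.pop(0)

    if all(s > 0 for s, _, _ in merged):
        raise NotCyclicError("no load reversal found: the curve is monotone")

    # refine each run boundary to the local extremum of the raw stretch:
    # smoothing smears the derivative sign change by a sample or two
    # around sharp reversals
    for j in range(len(merged) - 1):
        s, a, b = merged[j]
        lo = max(a + 1, b - 3)
        hi = min(len(lam), b + 3, merged[j + 1][2])
        window = lam[lo - 1 : hi]
        k = int(np.argmax(window) if s > 0 else np.argmin(window))
        new_b = lo - 1 + k + 1  # extremum sample stays in the ending run
        new_b = max(new_b, a + 1)
        merged[j][2] = new_b
        merged[j + 1][1] = new_b

    cycle = np.empty(len(lam), dtype=int)
    phase = np.empty(len(lam), dtype=object)
    c = 1
    for s, a, b in merged:
        cycle[a:b] = c
        phase[a:b] = "loading" if s > 0 else "unloading"
        if s < 0:
            c += 1
    return CyclicCurve(raw, cycle, phase)


def recovery_analysis(cyc: CyclicCurve, zero_tol_frac: float = 0.005) -> RecoveryResult:
    """Per-cycle peak, residual stretch and recovery percentage.

    The residual stretch is the axial stretch interpolated at the
    zero-force crossing of the unloading branch; a crossing counts when
    the force drops below ``zero_tol_frac`` of that cycle's peak force
    (load-cell zero tolerance).  If unloading never reaches zero force,
    the residual is taken at the segment end and the cycle is flagged
    (``reached_zero=False``).

    Recovery is the recovered deformation relative to the total
    deformation at the peak:
    ``100 * (peak - residual) / (peak - 1)`` axially, and symmetrically
    with deformation ``1 - lambda_tr`` in the transverse direction.
    """
    raw = cyc.raw
    result = RecoveryResult()
    for c in range(1, cyc.n_cycles + 1):
        in_cycle = cyc.cycle == c
        if not in_cycle.any():
            continue
        lam_c = raw.lambda_ax[in_cycle]
        f_c = raw.force_per_width[in_cycle]
        ltr_c = raw.lambda_tr[in_cycle]
        peak = float(lam_c.max())
        f_peak = float(f_c.max())
        peak_tr = float(ltr_c.min())

        unload = cyc.segment(c, "unloading")
        if not unload.any():
            continue
        lam_u = raw.lambda_ax[unload]
        f_u = raw.force_per_width[unload]
        ltr_u = raw.lambda_tr[unload]
        tol = zero_tol_frac * max(f_peak, 1e-300)

        reached = True
        below = np.nonzero(f_u <= 0.0)[0]
        if len(below):
            j = below[0]
            if j == 0 or f_u[j] == 0.0:
                residual, residual_tr = float(lam_u[j]), float(ltr_u[j])
            else:
                w = f_u[j - 1] / (f_u[j - 1] - f_u[j])
                residual = float(lam_u[j - 1] + w * (lam_u[j] - lam_u[j - 1]))
                residual_tr = float(ltr_u[j - 1] + w * (ltr_u[j] - ltr_u[j - 1]))
        elif f_u.min() <= tol:
            j = int(np.argmin(f_u))  # closest approach to zero force
            residual, residual_tr = float(lam_u[j]), float(ltr_u[j])
        else:
            residual, residual_tr = float(lam_u[-1]), float(ltr_u[-1])
            reached = False

        rec = 100.0 * (peak - residual) / (peak - 1.0) if peak > 1.0 else float("nan")
        if peak_tr < 1.0:
            rec_tr = 100.0 * (residual_tr - peak_tr) / (1.0 - peak_tr)
        else:
            rec_tr = float("nan")
        result.cycles.append(
            CycleRecovery(
                cycle=c,
                peak_stretch=peak,
                peak_force_per_width=f_peak,
                residual_stretch=residual,
                recovery_percent=rec,
                residual_stretch_tr=residual_tr,
                recovery_percent_tr=rec_tr,
                reached_zero=reached,
            )
        )
    if not result.cycles:
        raise NotCyclicError("no complete load-unload cycle found")
    return result


def residual_vs_force(rec: RecoveryResult) -> np.ndarray:
    """Cycles ordered by peak force: columns (peak force, residual stretch).

    The residual stretch is cumulative, as measured at that cycle.
    """
    if len(rec) < 1:
        raise InvalidInputError("need at least one cycle")
    order = np.argsort(rec.peak_forces, kind="stable")
    return np.column_stack([rec.peak_forces[order], rec.residual_stretches[order]])


def analyze_monotonic(
    raw: RawCurve,
    n_grid: int = 400,
    config: ExtractionConfig | None = None,
) -> tuple[DerivedCurves, MechanicalSummary]:
    """Full monotonic pipeline: smooth, derive, and summarise one curve."""
    derived = derive_curves(raw, n_grid=n_grid)
    lam_max = float(raw.lambda_ax.max())
    return derived, extract_summary(derived, lam_max, config)
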