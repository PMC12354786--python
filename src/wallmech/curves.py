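"""Data containers for tensile curves and derived quantities.

Conventions used throughout the package:

* Stretches are dimensionless: ``lambda_ax`` is deformed length over
  initial length along the pull direction, ``lambda_tr`` deformed over
  initial width in the sheet plane.  Both equal 1 in the undeformed
  state.
* Force is normalised per REFERENCE (initial) sample width and carried
  in N/m ("membrane force").
* Tangent stiffness is the slope of force-per-width versus axial
  stretch, N/m per unit stretch.
* The incremental Poisson's ratio is
  ``nu_inc = -d ln(lambda_tr) / d ln(lambda_ax)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "RawCurve",
    "CyclicCurve",
    "DerivedCurves",
    "ModelCurve",
    "MechanicalSummary",
    "CycleRecovery",
    "RecoveryResult",
]


def _as1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass
class RawCurve:
    """One tensile test as sampled time series.

    Parameters
    ----------
    time : array, seconds, monotone nondecreasing
    lambda_ax : array, axial stretch (>= some positive minimum)
    lambda_tr : array, transverse stretch
    force_per_width : array, N/m
    width_ref : optional reference width in metres (metadata only)
    label : free-text identifier
    zeroed : if True, the first sample is checked to start at
        ``lambda_ax == 1`` within 1e-6 (freshly zeroed test).
    """

    time: np.ndarray
    lambda_ax: np.ndarray
    lambda_tr: np.ndarray
    force_per_width: np.ndarray
    width_ref: float | None = None
    label: str = ""
    zeroed: bool = False

    def __post_init__(self):
        self.time = _as1d(self.time, "time")
        self.lambda_ax = _as1d(self.lambda_ax, "lambda_ax")
        self.lambda_tr = _as1d(self.lambda_tr, "lambda_tr")
        self.force_per_width = _as1d(self.force_per_width, "force_per_width")
        n = len(self.time)
        if n < 4:
            raise InvalidInputError("a curve needs at least 4 samples")
        for name in ("lambda_ax", "lambda_tr", "force_per_width"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError("all series must have equal length")
        if np.any(np.diff(self.time) < 0):
            raise InvalidInputError("time must be monotone nondecreasing")
        if np.any(self.lambda_ax <= 0):
            raise InvalidInputError("lambda_ax must be positive")
        if self.zeroed and abs(self.lambda_ax[0] - 1.0) > 1e-6:
            raise InvalidInputError(
                "zeroed test must start at lambda_ax = 1 (within 1e-6); "
                f"got {self.lambda_ax[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class CyclicCurve:
    """A raw curve with per-sample cycle index and loading phase.

    ``cycle`` is a 1-based integer array, nondecreasing in time;
    ``phase`` holds the strings ``"loading"`` or ``"unloading"``.
    """

    raw: RawCurve
    cycle: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.cycle = np.asarray(self.cycle, dtype=int)
        self.phase = np.asarray(self.phase, dtype=object)
        n = len(self.raw)
        if len(self.cycle) != n or len(self.phase) != n:
            raise InvalidInputError("labels must match the curve length")
        if np.any(np.diff(self.cycle) < 0):
            raise InvalidInputError("cycle indices must be nondecreasing")
        bad = set(np.unique(self.phase)) - {"loading", "unloading"}
        if bad:
            raise InvalidInputError(f"unknown phase labels: {sorted(bad)}")

    @property
    def n_cycles(self) -> int:
        return int(self.cycle.max())

    def segment(self, cycle: int, phase: str) -> np.ndarray:
        """Boolean mask selecting one labelled segment."""
        return (self.cycle == cycle) & (self.phase == phase)


@dataclass
class DerivedCurves:
    """Tangent stiffness and incremental Poisson's ratio on a stretch grid."""

    lambda_grid: np.ndarray
    tangent_stiffness: np.ndarray
    nu_inc: np.ndarray

    def __post_init__(self):
        self.lambda_grid = _as1d(self.lambda_grid, "lambda_grid")
        self.tangent_stiffness = _as1d(self.tangent_stiffness, "tangent_stiffness")
        self.nu_inc = _as1d(self.nu_inc, "nu_inc")
        if np.any(np.diff(self.lambda_grid) <= 0):
            raise InvalidInputError("lambda_grid must be strictly increasing")
        if not (len(self.lambda_grid) == len(self.tangent_stiffness) == len(self.nu_inc)):
            raise InvalidInputError("derived arrays must have equal length")


@dataclass
class ModelCurve:
    """Uniaxial response of a constitutive or structural model.

    Same semantics as :class:`DerivedCurves` plus the force itself and
    the transverse stretch.
    """

    lambda_grid: np.ndarray
    force_per_width: np.ndarray
    lambda_tr: np.ndarray
    tangent_stiffness: np.ndarray
    nu_inc: np.ndarray

    @classmethod
    def from_primary(cls, lambda_grid, force_per_width, lambda_tr) -> "ModelCurve":
        """Build a model curve, deriving stiffness and nu_inc numerically.

        The grids produced by the models are smooth and dense, so
        centred finite differences (``np.gradient``) are adequate here;
        experimental data goes through the spline pipeline instead.
        """
        lam = _as1d(lambda_grid, "lambda_grid")
        f = _as1d(force_per_width, "force_per_width")
        ltr = _as1d(lambda_tr, "lambda_tr")
        k = np.gradient(f, lam)
        dltr = np.gradient(ltr, lam)
        nu = -(lam / ltr) * dltr
        return cls(lam, f, ltr, k, nu)

    def as_derived(self) -> DerivedCurves:
        return DerivedCurves(self.lambda_grid, self.tangent_stiffness, self.nu_inc)


@dataclass
class MechanicalSummary:
    """Scalar descriptors of a three-regime tensile curve.

    ``E1``/``nu1`` are means of tangent stiffness / incremental
    Poisson's ratio over the initial stretch window (1.02-1.05 by
    default); ``E2`` over the final plateau; ``nu2`` over a +-0.05
    stretch window centred at the Poisson-ratio peak.
    ``regime_bounds`` is (end of regime I, start of regime III).
    """

    E1: float
    E2: float
    nu1: float
    nu2: float
    regime_bounds: tuple[float, float]
    lambda_max: float

    def __post_init__(self):
        if self.E1 <= 0 or self.E2 <= 0:
            raise InvalidInputError("stiffnesses must be positive")
        lo, hi = self.regime_bounds
        if not (lo <= hi <= self.lambda_max + 1e-12):
            raise InvalidInputError(
                "regime bounds must satisfy bounds[0] <= bounds[1] <= lambda_max"
            )

    def to_dict(self) -> dict:
        return {
            "E1": self.E1,
            "E2": self.E2,
            "nu1": self.nu1,
            "nu2": self.nu2,
            "regime_bounds": list(self.regime_bounds),
            "lambda_max": self.lambda_max,
        }


@dataclass
class CycleRecovery:
    """Recovery metrics for one load-unload cycle."""

    cycle: int
    peak_stretch: float
    peak_force_per_width: float
    residual_stretch: float
    recovery_percent: float
    residual_stretch_tr: float | None = None
    recovery_percent_tr: float | None = None
    reached_zero: bool = True


@dataclass
class RecoveryResult:
    """Per-cycle recovery table for an incremental cyclic test."""

    cycles: list[CycleRecovery] = field(default_factory=list)

    def __iter__(self):
        return iter(self.cycles)

    def __len__(self):
        return len(self.cycles)

    @property
    def peak_stretches(self) -> np.ndarray:
        return np.array([c.peak_stretch for c in self.cycles])

    @property
    def recovery_percents(self) -> np.ndarray:
        return np.array([c.recovery_percent for c in self.cycles])

    @property
    def residual_stretches(self) -> np.ndarray:
        return np.array([c.residual_stretch for c in self.cycles])

    @property
    def peak_forces(self) -> np.ndarray:
        return np.array([c.peak_force_per_width for c in self.cycles])

    def to_records(self) -> list[dict]:
        return [
            {
                "cycle": c.cycle,
                "peak_stretch": c.peak_stretch,
                "peak_force_per_width": c.peak_force_per_width,
                "residual_stretch": c.residual_stretch,
                "recovery_percent": c.recovery_percent,
                "residual_stretch_tr": c.residual_stretch_tr,
                "recovery_percent_tr": c.recovery_percent_tr,
                "reached_zero": c.reached_zero,
            }
            for c in self.cycles
        ]
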