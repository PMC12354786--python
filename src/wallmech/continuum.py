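"""Homogeneous plane-stress hyperelastic plate and thin-shell analyses.

The plate response is the homogeneous reference for the tensile tests:
an isotropic compressible neo-Hookean or Yeoh sheet pulled uniaxially
with zero transverse and through-thickness Cauchy stress.  The energy
uses the isochoric/volumetric split

    W = sum_i Ci0 (I1_bar - 3)^i + (1/D1) (J - 1)^2,

with ``I1_bar = J^(-2/3) (l1^2 + l2^2 + l3^2)`` and ``J = l1 l2 l3``,
so published (C10, D1) constants carry over unchanged; for neo-Hookean
``C10 = mu/2`` and ``D1 = 2/K``.

The shell helpers support the pressurised-shell arguments: membrane
(Laplace) equilibrium with current geometry shows that a linear wall
has a pressure limit point while a strain-stiffening wall keeps the
pressure-stretch curve single valued, and a closed pressurised
cylinder under axial force stiffens with the wall Poisson's ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.optimize import brentq

from .curves import ModelCurve
from .errors import InvalidInputError, SolverError

__all__ = [
    "HyperelasticMaterial",
    "LinearWall",
    "StiffnessProfileWall",
    "ShellSpec",
    "plane_stress_uniaxial",
    "uniaxial_curve",
    "inflate_shell",
    "cylinder_axial_response",
]


@dataclass
class HyperelasticMaterial:
    """Isotropic compressible hyperelastic material (neo-Hookean or Yeoh).

    For neo-Hookean, give exactly one of the pairs (mu, K) or
    (C10, D1); the other is derived (C10 = mu/2, D1 = 2/K).  For Yeoh,
    give C10, C20, C30 and D1 (mu, K derived from C10, D1).
    ``thickness_ref`` converts nominal stress to membrane force.
    """

    model: Literal["neo-hookean", "yeoh"] = "neo-hookean"
    mu: float | None = None
    K: float | None = None
    C10: float | None = None
    C20: float = 0.0
    C30: float = 0.0
    D1: float | None = None
    thickness_ref: float = 1.0

    def __post_init__(self):
        if self.model not in ("neo-hookean", "yeoh"):
            raise InvalidInputError(f"unknown material model {self.model!r}")
        have_muK = self.mu is not None or self.K is not None
        have_CD = self.C10 is not None or self.D1 is not None
        if self.model == "neo-hookean" and have_muK and have_CD:
            raise InvalidInputError("give (mu, K) or (C10, D1), not both")
        if have_muK:
            if self.mu is None or self.K is None:
                raise InvalidInputError("give both mu and K")
            self.C10 = self.mu / 2.0
            self.D1 = 2.0 / self.K
        elif have_CD:
            if self.C10 is None or self.D1 is None:
                raise InvalidInputError("give both C10 and D1")
            self.mu = 2.0 * self.C10
            self.K = 2.0 / self.D1
        else:
            raise InvalidInputError("material constants missing")
        if self.mu <= 0 or self.K <= 0 or self.thickness_ref <= 0:
            raise InvalidInputError("mu, K and thickness_ref must be positive")

    @classmethod
    def from_E_nu(
        cls, E: float, nu: float, model: str = "neo-hookean", thickness_ref: float = 1.0, **kw
    ) -> "HyperelasticMaterial":
        """Construct from small-strain Young's modulus and Poisson's ratio."""
        mu = E / (2.0 * (1.0 + nu))
        K = E / (3.0 * (1.0 - 2.0 * nu))
        if model == "yeoh":
            return cls(model="yeoh", C10=mu / 2.0, D1=2.0 / K, thickness_ref=thickness_ref, **kw)
        return cls(model=model, mu=mu, K=K, thickness_ref=thickness_ref, **kw)

    # -- energy derivatives -------------------------------------------
    def _dW_dI1bar(self, i1b: float) -> float:
        x = i1b - 3.0
        w1 = self.C10
        if self.model == "yeoh":
            w1 = self.C10 + 2.0 * self.C20 * x + 3.0 * self.C30 * x * x
        return w1

    def principal_pk1(self, l1: float, l2: float, l3: float) -> tuple[float, float, float]:
        """Principal first Piola-Kirchhoff stresses dW/dlambda_i."""
        J = l1 * l2 * l3
        if J <= 0:
            raise InvalidInputError("stretches must be positive")
        i1 = l1 * l1 + l2 * l2 + l3 * l3
        jm23 = J ** (-2.0 / 3.0)
        i1b = jm23 * i1
        w1 = self._dW_dI1bar(i1b)
        wj = (2.0 / self.D1) * (J - 1.0)
        out = []
        for li in (l1, l2, l3):
            di1b = 2.0 * jm23 * (li - i1 / (3.0 * li))
            out.append(w1 * di1b + wj * (J / li))
        return tuple(out)

    def principal_cauchy(self, l1: float, l2: float, l3: float) -> tuple[float, float, float]:
        J = l1 * l2 * l3
        p1, p2, p3 = self.principal_pk1(l1, l2, l3)
        return (l1 * p1 / J, l2 * p2 / J, l3 * p3 / J)

    def energy_density(self, l1: float, l2: float, l3: float) -> float:
        J = l1 * l2 * l3
        i1b = J ** (-2.0 / 3.0) * (l1 * l1 + l2 * l2 + l3 * l3)
        x = i1b - 3.0
        w = self.C10 * x
        if self.model == "yeoh":
            w += self.C20 * x * x + self.C30 * x**3
        return w + (1.0 / self.D1) * (J - 1.0) ** 2


def plane_stress_uniaxial(
    material: HyperelasticMaterial, lambda_ax: float
) -> tuple[float, float]:
    """Uniaxial plane-stress solve: returns (lambda_tr, force per width).

    The transverse in-plane and through-thickness Cauchy stresses must
    vanish; for an isotropic material both lateral stretches coincide,
    leaving one scalar root find.  The membrane force is the nominal
    (first Piola-Kirchhoff) axial stress times the reference thickness.
    """
    if lambda_ax <= 0:
        raise InvalidInputError("lambda_ax must be positive")
    if abs(lambda_ax - 1.0) < 1e-14:
        return 1.0, 0.0

    def g(lt: float) -> float:
        return material.principal_cauchy(lambda_ax, lt, lt)[1]

    lo, hi = 0.05, max(2.0, lambda_ax)
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        raise SolverError(
            f"lateral stretch not bracketed at lambda_ax={lambda_ax:g} "
            f"(g({lo})={glo:g}, g({hi})={ghi:g})"
        )
    lt = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    p1 = material.principal_pk1(lambda_ax, lt, lt)[0]
    return float(lt), float(p1 * material.thickness_ref)


def uniaxial_curve(material: HyperelasticMaterial, lambda_grid) -> ModelCurve:
    """Map the plane-stress solve over a stretch grid starting at 1."""
    lam = np.asarray(lambda_grid, dtype=float)
    if abs(lam[0] - 1.0) > 1e-9 or np.any(np.diff(lam) <= 0):
        raise InvalidInputError("lambda_grid must start at 1 and be strictly increasing")
    ltr = np.empty_like(lam)
    f = np.empty_like(lam)
    for i, la in enumerate(lam):
        ltr[i], f[i] = plane_stress_uniaxial(material, la)
    return ModelCurve.from_primary(lam, f, ltr)


# ---------------------------------------------------------------------------
# Thin shells


@dataclass
class LinearWall:
    """Hookean wall: Cauchy stress linear in engineering strain, with
    first-order geometric thinning under plane stress."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0 or not (-1.0 < self.nu < 0.5):
            raise InvalidInputError("need E > 0 and -1 < nu < 0.5")


@dataclass
class StiffnessProfileWall:
    """Wall defined directly by a membrane tangent-stiffness profile
    ``k(lambda)`` (force per length per unit equibiaxial stretch); the
    membrane tension is its integral from 1."""

    stiffness: Callable[[float], float]


@dataclass
class ShellSpec:
    """Thin pressurised shell (sphere or cylinder)."""

    geometry: Literal["sphere", "cylinder"]
    radius: float
    wall_thickness: float
    wall: HyperelasticMaterial | LinearWall | StiffnessProfileWall
    pressure: float = 0.0

    def __post_init__(self):
        if self.geometry not in ("sphere", "cylinder"):
            raise InvalidInputError(f"unknown geometry {self.geometry!r}")
        if self.radius <= 0 or self.wall_thickness <= 0:
            raise InvalidInputError("radius and wall_thickness must be positive")
        if self.wall_thickness / self.radius >= 0.1:
            warnings.warn(
                "wall_thickness/radius >= 0.1: thin-wall membrane theory is "
                "inaccurate for this geometry",
                stacklevel=2,
            )


def _membrane_tension(spec: ShellSpec, lam: float) -> float:
    """In-plane membrane tension (force per current length) at
    equibiaxial stretch ``lam``."""
    t0 = spec.wall_thickness
    wall = spec.wall
    if isinstance(wall, StiffnessProfileWall):
        # integral of the tangent-stiffness profile
        if lam <= 1.0:
            return 0.0
        xs = np.linspace(1.0, lam, 200)
        ks = np.array([wall.stiffness(x) for x in xs])
        return float(np.trapezoid(ks, xs))
    if isinstance(wall, LinearWall):
        eps = lam - 1.0
        sigma = wall.E / (1.0 - wall.nu) * eps  # equibiaxial Hooke
        eps_t = -2.0 * wall.nu / (1.0 - wall.nu) * eps  # thickness strain
        return sigma * t0 * (1.0 + eps_t)
    # hyperelastic: equibiaxial stretch, zero thickness Cauchy stress
    def g(l3: float) -> float:
        return wall.principal_cauchy(lam, lam, l3)[2]

    l3 = brentq(g, 1e-3, 2.0, xtol=1e-14, rtol=8.9e-16)
    # current tension = Cauchy in-plane stress x current thickness
    sig = wall.principal_cauchy(lam, lam, l3)[0]
    return sig * t0 * l3


def _laplace_pressure(spec: ShellSpec, lam: float) -> float:
    factor = 2.0 if spec.geometry == "sphere" else 1.0
    return factor * _membrane_tension(spec, lam) / (lam * spec.radius)


def inflate_shell(
    spec: ShellSpec, pressure_grid, lam_hi: float = 2.0, n_scan: int = 2000
) -> dict:
    """Quasi-static inflation: hoop stretch at each pressure.

    Membrane equilibrium uses the Laplace relation with the current
    geometry.  If the pressure-stretch relation has a limit point
    (dp/dlambda = 0) inside the scan range -- as it does for a linear
    wall -- the curve is returned up to the limit point and flagged;
    a wall whose stiffness ramps up (three-regime profile) keeps the
    relation single valued.

    Returns a dict with keys ``pressure``, ``stretch``,
    ``limit_point`` (None or (pressure, stretch)).
    """
    p_req = np.asarray(pressure_grid, dtype=float)
    if np.any(p_req < 0) or np.any(np.diff(p_req) < 0):
        raise InvalidInputError("pressures must be nonnegative and nondecreasing")
    lam_scan = np.linspace(1.0, lam_hi, n_scan)
    p_scan = np.array([_laplace_pressure(spec, la) for la in lam_scan])
    dp = np.diff(p_scan)
    turn = np.nonzero(dp <= 0)[0]
    limit_point = None
    if len(turn):
        i = int(turn[0])
        limit_point = (float(p_scan[i]), float(lam_scan[i]))
        lam_scan, p_scan = lam_scan[: i + 1], p_scan[: i + 1]

    stretches, pressures = [], []
    for p in p_req:
        if limit_point is not None and p > limit_point[0]:
            break
        if p == 0.0:
            stretches.append(1.0)
            pressures.append(0.0)
            continue
        j = int(np.searchsorted(p_scan, p))
        if j >= len(lam_scan):
            break
        la = brentq(
            lambda l: _laplace_pressure(spec, l) - p,
            lam_scan[max(j - 1, 0)],
            lam_scan[j],
            xtol=1e-12,
        )
        stretches.append(float(la))
        pressures.append(float(p))
    return {
        "pressure": np.asarray(pressures),
        "stretch": np.asarray(stretches),
        "limit_point": limit_point,
    }


def cylinder_axial_response(spec: ShellSpec, axial_force_grid) -> dict:
    """Closed pressurised thin cylinder under superposed axial force.

    Linear-elastic wall with first-order kinematics and current-radius
    pressure coupling: axial equilibrium includes the pressure cap
    force ``p * pi * r^2`` at the current radius, and the hoop stress
    follows ``p r / t``.

    ``spec.radius`` is the radius of the TURGID reference state (the
    cell as measured, at pressure ``p`` and zero axial force), so cells
    with different wall Poisson's ratios are compared at the same
    geometry; the axial stretch is likewise measured from that state.
    Axial stretch then couples to radial shrinkage through nu, which
    unloads the cap force and the hoop stress, making the pressurised
    cell effectively stiffer for a higher wall Poisson's ratio.

    Returns the axial stretch per force and the effective tangent
    stiffness dF/dlambda_ax (finite differenced on the force grid).
    """
    if spec.geometry != "cylinder":
        raise InvalidInputError("cylinder_axial_response needs a cylinder spec")
    if not isinstance(spec.wall, LinearWall):
        raise InvalidInputError("cylinder_axial_response expects a linear wall")
    E, nu = spec.wall.E, spec.wall.nu
    r_turgid, t, p = spec.radius, spec.wall_thickness, spec.pressure
    F_grid = np.asarray(axial_force_grid, dtype=float)

    # unpressurised reference radius such that (p, F=0) gives r_turgid
    sig_h0 = p * r_turgid / t
    sig_a0 = p * r_turgid / (2.0 * t)
    eps_h0 = (sig_h0 - nu * sig_a0) / E
    eps_a0 = (sig_a0 - nu * sig_h0) / E
    r_ref = r_turgid / (1.0 + eps_h0)

    def solve_one(F: float) -> float:
        r = r_turgid
        for _ in range(400):
            sig_h = p * r / t
            sig_a = (F + p * math.pi * r * r) / (2.0 * math.pi * r * t)
            eps_h = (sig_h - nu * sig_a) / E
            r_new = r_ref * (1.0 + eps_h)
            if abs(r_new - r) < 1e-15 * r_turgid:
                r = r_new
                break
            r = r_new
        sig_h = p * r / t
        sig_a = (F + p * math.pi * r * r) / (2.0 * math.pi * r * t)
        eps_a = (sig_a - nu * sig_h) / E
        return 1.0 + (eps_a - eps_a0)  # stretch relative to the turgid state

    lam = np.array([solve_one(F) for F in F_grid])
    if len(F_grid) > 1:
        stiff = np.gradient(F_grid, lam)
    else:
        stiff = np.array([float("nan")])
    return {"axial_force": F_grid, "lambda_ax": lam, "tangent_stiffness": stiff}
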