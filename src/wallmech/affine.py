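"""Affine isotropic fiber-network model.

Every fiber is assumed to follow the macroscopic in-plane deformation
gradient exactly (affine kinematics): a fiber at initial orientation
``theta0`` maps to direction ``(lambda_ax cos(theta0),
lambda_tr sin(theta0))`` and stretches to the length of that vector.
The membrane response is the orientation average, over a uniform
distribution on [0, pi), of the fiber nominal forces projected onto the
two in-plane axes.  The uniaxial curve is obtained by enforcing zero
transverse membrane force at each axial stretch.

This is the classical null model for strain stiffening by fiber
re-orientation alone: with linear fibers it produces a two-regime
stiffening curve and a monotonically increasing incremental Poisson's
ratio (small-strain limit 1/3), i.e. it cannot reproduce the
three-regime behaviour of the cell-wall data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .curves import ModelCurve
from .errors import InvalidInputError, SolverError

__all__ = ["AffineNetworkParams", "fiber_stretch", "membrane_force", "uniaxial_response"]


@dataclass
class AffineNetworkParams:
    """Parameters of the affine isotropic network.

    kappa_f
        fiber stiffness density, N/m per unit fiber stretch: the
        orientation-averaged nominal fiber force is
        ``kappa_f * (lambda_f - 1)`` per fiber direction.
    n_orient
        number of midpoint quadrature nodes on [0, pi); 360 keeps the
        isotropy error below 1e-6 at negligible cost.
    tension_only
        if True, fibers with lambda_f < 1 carry no force (buckled).
    matrix_k
        optional linear isotropic background stiffness, N/m.
    """

    kappa_f: float = 30.0
    n_orient: int = 360
    tension_only: bool = False
    matrix_k: float = 0.0

    def __post_init__(self):
        if self.kappa_f <= 0:
            raise InvalidInputError("kappa_f must be positive")
        if self.n_orient < 8 or self.n_orient % 2:
            raise InvalidInputError("n_orient must be even and at least 8")
        if self.matrix_k < 0:
            raise InvalidInputError("matrix_k must be nonnegative")

    def _theta_nodes(self) -> np.ndarray:
        n = self.n_orient
        return (np.arange(n) + 0.5) * np.pi / n


def fiber_stretch(theta0, lambda_ax: float, lambda_tr: float):
    """Stretch of a fiber initially at angle ``theta0`` (radians).

    Affine kinematics:
    ``lambda_f = sqrt(lambda_ax^2 cos^2 + lambda_tr^2 sin^2)``.
    """
    if lambda_ax <= 0 or lambda_tr <= 0:
        raise InvalidInputError("stretches must be positive")
    theta0 = np.asarray(theta0, dtype=float)
    c, s = np.cos(theta0), np.sin(theta0)
    return np.sqrt((lambda_ax * c) ** 2 + (lambda_tr * s) ** 2)


def membrane_force(
    params: AffineNetworkParams, lambda_ax: float, lambda_tr: float
) -> tuple[float, float]:
    """Nominal membrane forces (f_ax, f_tr) in N/m.

    The first Piola-Kirchhoff membrane tensor of the network is the
    orientation average of ``p(lambda_f) * (a_hat (x) a0)`` with ``a0``
    the reference fiber direction and ``a_hat`` the current one; its
    two diagonal components are the axial and transverse nominal
    forces.  ``matrix_k`` adds an uncoupled linear isotropic term.
    """
    if lambda_ax <= 0 or lambda_tr <= 0:
        raise InvalidInputError("stretches must be positive")
    theta = params._theta_nodes()
    c, s = np.cos(theta), np.sin(theta)
    lam_f = np.sqrt((lambda_ax * c) ** 2 + (lambda_tr * s) ** 2)
    p = params.kappa_f * (lam_f - 1.0)
    if params.tension_only:
        p = np.where(lam_f >= 1.0, p, 0.0)
    # current direction components: (lambda_ax c, lambda_tr s)/lam_f
    f_ax = np.mean(p * (lambda_ax * c / lam_f) * c)
    f_tr = np.mean(p * (lambda_tr * s / lam_f) * s)
    f_ax += params.matrix_k * (lambda_ax - 1.0)
    f_tr += params.matrix_k * (lambda_tr - 1.0)
    return float(f_ax), float(f_tr)


def uniaxial_response(params: AffineNetworkParams, lambda_grid) -> ModelCurve:
    """Uniaxial membrane response: zero transverse force at each stretch.

    For each axial stretch the transverse stretch solves
    ``f_tr(lambda_ax, lambda_tr) = 0`` by bracketed root finding in
    (0.05, max(1, lambda_ax)].
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if abs(lam[0] - 1.0) > 1e-9 or np.any(np.diff(lam) <= 0):
        raise InvalidInputError("lambda_grid must start at 1 and be strictly increasing")

    ltr = np.empty_like(lam)
    f = np.empty_like(lam)
    for i, la in enumerate(lam):
        if abs(la - 1.0) < 1e-14:
            ltr[i], f[i] = 1.0, 0.0
            continue

        def g(lt, la=la):
            return membrane_force(params, la, lt)[1]

        lo, hi = 0.05, max(1.0, la)
        glo, ghi = g(lo), g(hi)
        if glo * ghi > 0:
            raise SolverError(
                "transverse root not bracketed in (0.05, "
                f"{hi:g}] at lambda_ax={la:g}: f_tr({lo:g})={glo:g}, "
                f"f_tr({hi:g})={ghi:g}"
            )
        root = brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)
        ltr[i] = root
        f[i] = membrane_force(params, la, root)[0]
    return ModelCurve.from_primary(lam, f, ltr)
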