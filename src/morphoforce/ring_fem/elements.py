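"""Plane-strain quadrilateral element kernels (batched over elements).

The wall of the sensor is thin relative to its diameter, so the coarse
structured mesh puts high-aspect-ratio quadrilaterals in bending — the regime
where plain bilinear elements shear-lock — while the hydrogel's near
incompressibility (nu -> 0.5) volumetric-locks them.  The element used here
combats both:

* Wilson/Taylor incompatible bending modes (two internal quadratic modes per
  element, statically condensed), with the centroid-Jacobian correction that
  restores the patch test on non-parallelogram shapes;
* a volumetric/isochoric split of the elasticity tensor in which the
  Lame-lambda (dilatational) energy is evaluated on the element-mean in-plane
  dilatation, i.e. mean-dilatation selective integration applied only to the
  term that blows up as nu -> 0.5.  The mu-part is fully integrated, so the
  bending response is untouched in the compressible limit.

The stiffness is linear-elastic about the element's reference shape with the
moduli (E, nu) of the linearized neo-Hookean solid; geometric nonlinearity is
supplied by the corotational wrapper in the solver, appropriate because the
material strains stay small even at large ring deflections.
"""

from __future__ import annotations

import numpy as np

_G = 1.0 / np.sqrt(3.0)
#: 2x2 Gauss points and weights on [-1, 1]^2
GAUSS_POINTS = [(-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G)]
GAUSS_WEIGHTS = [1.0, 1.0, 1.0, 1.0]

# bilinear shape functions on the reference square, node order CCW
_XI_N = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])


def shape_dn(xi: float, eta: float) -> np.ndarray:
    """Natural derivatives dN_i/d(xi, eta), shape (4, 2)."""
    out = np.empty((4, 2))
    out[:, 0] = 0.25 * _XI_N[:, 0] * (1.0 + _XI_N[:, 1] * eta)
    out[:, 1] = 0.25 * _XI_N[:, 1] * (1.0 + _XI_N[:, 0] * xi)
    return out


def lame_constants(E: float, nu: float) -> tuple[float, float]:
    """(mu, lambda) from (E, nu)."""
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


def plane_strain_dmat(E: float, nu: float) -> np.ndarray:
    """Full plane-strain elasticity matrix, Voigt order (e_xx, e_yy, g_xy)."""
    f = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return f * np.array([
        [1.0 - nu, nu, 0.0],
        [nu, 1.0 - nu, 0.0],
        [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
    ])


def _jacobians(X: np.ndarray, dn: np.ndarray):
    """Batched Jacobians at one quadrature point.

    X: (M, 4, 2) element node coords; dn: (4, 2) natural derivatives.
    Returns J (M, 2, 2), detJ (M,), dndx (M, 4, 2).
    """
    J = np.einsum("mia,ib->mab", X, dn)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    Jinv = np.empty_like(J)
    Jinv[:, 0, 0] = J[:, 1, 1]
    Jinv[:, 1, 1] = J[:, 0, 0]
    Jinv[:, 0, 1] = -J[:, 0, 1]
    Jinv[:, 1, 0] = -J[:, 1, 0]
    Jinv /= detJ[:, None, None]
    dndx = np.einsum("ib,mba->mia", dn, Jinv)
    return J, detJ, dndx


def _compat_b(dndx: np.ndarray) -> np.ndarray:
    """Compatible strain-displacement matrix, (M, 3, 8)."""
    m = dndx.shape[0]
    B = np.zeros((m, 3, 8))
    B[:, 0, 0::2] = dndx[:, :, 0]
    B[:, 1, 1::2] = dndx[:, :, 1]
    B[:, 2, 0::2] = dndx[:, :, 1]
    B[:, 2, 1::2] = dndx[:, :, 0]
    return B


def qm6_stiffness(X: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Condensed 8x8 stiffness of the incompatible-modes element with
    mean-dilatation volumetric treatment.

    X: (M, 4, 2) reference node coordinates.  Returns (M, 8, 8) per unit
    out-of-plane thickness, in the units of E times length.
    """
    X = np.asarray(X, dtype=float)
    M = X.shape[0]
    mu, lam = lame_constants(E, nu)
    Dmu = np.array([[2.0 * mu, 0.0, 0.0],
                    [0.0, 2.0 * mu, 0.0],
                    [0.0, 0.0, mu]])

    # centroid Jacobian for the Taylor-modified incompatible modes
    J0, detJ0, _ = _jacobians(X, shape_dn(0.0, 0.0))
    J0inv = np.empty_like(J0)
    J0inv[:, 0, 0] = J0[:, 1, 1]
    J0inv[:, 1, 1] = J0[:, 0, 0]
    J0inv[:, 0, 1] = -J0[:, 0, 1]
    J0inv[:, 1, 0] = -J0[:, 1, 0]
    J0inv /= detJ0[:, None, None]

    Kuu = np.zeros((M, 8, 8))
    Kua = np.zeros((M, 8, 4))
    Kaa = np.zeros((M, 4, 4))
    vol = np.zeros(M)
    bvol = np.zeros((M, 8))      # element-mean in-plane dilatation operator
    for (xi, eta), w in zip(GAUSS_POINTS, GAUSS_WEIGHTS):
        _, detJ, dndx = _jacobians(X, shape_dn(xi, eta))
        B = _compat_b(dndx)
        # incompatible modes P1 = 1 - xi^2, P2 = 1 - eta^2, centroid mapping;
        # the detJ0/detJ factor zeroes their mean strain (patch test) and
        # keeps them free of the lambda-term by construction.
        dpdxi = np.array([[-2.0 * xi, 0.0], [0.0, -2.0 * eta]])
        dpdx = (detJ0 / detJ)[:, None, None] * np.einsum(
            "pb,mba->mpa", dpdxi, J0inv)
        Ba = np.zeros((M, 3, 4))
        Ba[:, 0, 0::2] = dpdx[:, :, 0]
        Ba[:, 1, 1::2] = dpdx[:, :, 1]
        Ba[:, 2, 0::2] = dpdx[:, :, 1]
        Ba[:, 2, 1::2] = dpdx[:, :, 0]
        wd = (w * detJ)[:, None, None]
        DB = np.einsum("ab,mbj->maj", Dmu, B)
        DBa = np.einsum("ab,mbj->maj", Dmu, Ba)
        Kuu += wd * np.einsum("mai,maj->mij", B, DB)
        Kua += wd * np.einsum("mai,maj->mij", B, DBa)
        Kaa += wd * np.einsum("mai,maj->mij", Ba, DBa)
        vol += w * detJ
        bvol += (w * detJ)[:, None] * (B[:, 0, :] + B[:, 1, :])
    bvol /= vol[:, None]

    Klam = lam * vol[:, None, None] * np.einsum("mi,mj->mij", bvol, bvol)
    Kaa_inv = np.linalg.inv(Kaa)
    return Kuu + Klam - np.einsum("mij,mjk,mlk->mil", Kua, Kaa_inv, Kua)


def centroid_dndx(X: np.ndarray) -> np.ndarray:
    """Cartesian shape-function derivatives at element centroids, (M, 4, 2).

    Used by the corotational wrapper to extract each element's mean rotation
    from the deformation gradient at the centroid.
    """
    _, _, dndx = _jacobians(np.asarray(X, dtype=float), shape_dn(0.0, 0.0))
    return dndx
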