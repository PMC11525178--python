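"""Constitutive models and modulus estimation.

The hydrogel sensors are soft, nearly incompressible elastomers that follow a
neo-Hookean response over the working strain range.  This module holds the
material container used by the mechanical solvers, the incompressible
neo-Hookean uniaxial closed form, and the two experimental routes to Young's
modulus: Hertz-type fits of AFM indentation curves acquired with pyramidal
tips, and slope fits of uniaxial stress-strain records.

Unit conventions: moduli/stresses in kPa, depths in um, forces in nN
(see :mod:`morphoforce.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateCurveError,
    ConvergenceError,
    InsufficientDataError,
    InvalidArgumentError,
    UnsupportedConfigurationError,
)

#: Geometric prefactor of the four-sided pyramidal indenter contact model
#: F = c * E/(1-nu^2) * tan(theta) * delta^2.  Configurable because vendor
#: software sometimes uses the paraboloid or cone variant instead.
PYRAMID_PREFACTOR = 0.7453


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic hyperelastic material parameters.

    Parameters
    ----------
    E:
        Young's modulus in kPa.
    nu:
        Poisson ratio, in [0, 0.5]; 0.5 is the incompressible limit.

    The shear modulus ``mu = E / (2 (1 + nu))`` and the neo-Hookean constant
    ``c10 = mu / 2`` are derived, never stored independently.
    """

    E: float
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise InvalidArgumentError(f"Young's modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu <= 0.5):
            raise InvalidArgumentError(f"Poisson ratio must be in [0, 0.5], got {self.nu}")

    @property
    def mu(self) -> float:
        """Shear modulus (kPa)."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def c10(self) -> float:
        """Neo-Hookean strain-energy constant (kPa), mu / 2."""
        return self.mu / 2.0


@dataclass
class AFMCurve:
    """One AFM indentation curve (approach segment).

    ``depth`` is the indentation in um (non-negative, strictly increasing),
    ``force`` the cantilever load in nN, ``tip_half_angle`` the pyramidal
    face half-angle in degrees, ``spring_constant`` the nominal cantilever
    constant in N/m.
    """

    depth: np.ndarray
    force: np.ndarray
    tip_half_angle: float = 20.0
    spring_constant: float = 0.2

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.depth.shape != self.force.shape:
            raise InvalidArgumentError("depth and force must have equal length")
        if np.any(np.diff(self.depth) <= 0):
            raise InvalidArgumentError("depth must be strictly increasing")
        if not (0.0 < self.tip_half_angle < 90.0):
            raise InvalidArgumentError("tip half-angle must lie in (0, 90) degrees")


@dataclass(frozen=True)
class HertzFit:
    """Result of a pyramidal Hertz fit: modulus (kPa), contact point (um),
    RMS force residual (nN)."""

    E_est: float
    contact_point: float
    rms_residual: float

    def __post_init__(self) -> None:
        if self.E_est <= 0:
            raise InvalidArgumentError("fitted modulus must be positive")
        if self.rms_residual < 0:
            raise InvalidArgumentError("residual must be non-negative")


@dataclass
class StressStrainRecord:
    """Uniaxial nominal stress (kPa) versus nominal strain (signed;
    negative = compression)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape:
            raise InvalidArgumentError("strain and stress must have equal length")


def neo_hookean_uniaxial(lambda_, material: MaterialModel):
    """Incompressible neo-Hookean nominal stress in uniaxial loading.

    For stretch ratio ``lambda_`` the nominal (first Piola-Kirchhoff) stress is
    ``mu * (lambda - lambda^-2)`` with mu = E/3 at nu = 0.5.  The small-strain
    tangent at lambda = 1 is exactly E.

    Parameters
    ----------
    lambda_:
        Stretch ratio (scalar or array), > 0.
    material:
        Must be incompressible (nu = 0.5); other Poisson ratios have no
        single-field closed form and raise ``UnsupportedConfigurationError``.

    Returns
    -------
    Nominal stress in the units of ``material.E``.
    """
    lam = np.asarray(lambda_, dtype=float)
    if np.any(lam <= 0):
        raise InvalidArgumentError("stretch ratio must be positive")
    if material.nu != 0.5:
        raise UnsupportedConfigurationError(
            "closed-form uniaxial response is only defined for the "
            f"incompressible case nu = 0.5 (got nu = {material.nu})")
    stress = material.mu * (lam - lam ** -2)
    return float(stress) if np.isscalar(lambda_) else stress


def linearity_deviation(record: StressStrainRecord, strain_limit: float) -> float:
    """Maximum relative deviation of a stress-strain record from a straight
    line through the origin, over strains in [0, strain_limit].

    The fit is constrained through the origin (the physical reference state);
    deviation is max |stress - slope*strain| / max |stress| over the window.
    """
    mask = (record.strain >= 0) & (record.strain <= strain_limit)
    eps = record.strain[mask]
    sig = record.stress[mask]
    if eps.size < 5:
        raise InsufficientDataError(
            f"need at least 5 points in [0, {strain_limit}], found {eps.size}")
    denom = float(np.max(np.abs(sig)))
    if denom == 0.0:
        return 0.0
    slope = float(np.dot(sig, eps) / np.dot(eps, eps))
    return float(np.max(np.abs(sig - slope * eps)) / denom)


def _pyramid_force(depth, contact_point, E, nu, tan_theta, prefactor):
    d = np.clip(depth - contact_point, 0.0, None)
    return prefactor * (E / (1.0 - nu ** 2)) * tan_theta * d ** 2


def fit_hertz_pyramidal(curve: AFMCurve, nu: float = 0.5, *,
                        prefactor: float = PYRAMID_PREFACTOR) -> HertzFit:
    """Fit the pyramidal-indenter Hertz model to an AFM force curve.

    Model: ``F = c * E/(1-nu^2) * tan(theta) * (depth - contact_point)^2`` for
    depths past the contact point, zero before.  E (kPa) and the contact point
    (um) are estimated jointly by nonlinear least squares.  The contact point
    is initialised at the first depth whose force exceeds 3x the pre-contact
    noise SD (or the first sample when the curve starts loaded).

    Raises ``DegenerateCurveError`` on an identically-zero curve and
    ``ConvergenceError`` when the optimizer fails.
    """
    depth, force = curve.depth, curve.force
    if depth.size < 10:
        raise InsufficientDataError("need at least 10 points for a Hertz fit")
    if np.all(force == 0):
        raise DegenerateCurveError("force is identically zero")
    tan_theta = float(np.tan(np.deg2rad(curve.tip_half_angle)))

    # contact-point initial guess: first sustained excursion above baseline noise
    n_pre = max(3, depth.size // 10)
    noise_sd = float(np.std(force[:n_pre]))
    threshold = 3.0 * noise_sd if noise_sd > 0 else 0.0
    above = np.nonzero(force > threshold)[0]
    cp0 = float(depth[above[0]]) if above.size else float(depth[0])

    # modulus initial guess from the last quarter of the curve
    tail = slice(3 * depth.size // 4, None)
    d_tail = np.clip(depth[tail] - cp0, 1e-9, None)
    a0 = max(float(np.median(force[tail] / d_tail ** 2)), 1e-9)
    e0 = a0 * (1.0 - nu ** 2) / (prefactor * tan_theta)

    def residual(p):
        log_e, cp = p
        return _pyramid_force(depth, cp, np.exp(log_e), nu, tan_theta, prefactor) - force

    span = float(depth[-1] - depth[0])
    sol = least_squares(residual, x0=[np.log(e0), cp0],
                        bounds=([-np.inf, depth[0] - span], [np.inf, depth[-1]]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise ConvergenceError(f"Hertz fit did not converge: {sol.message}",
                               residual=float(np.sqrt(np.mean(sol.fun ** 2))))
    E_est = float(np.exp(sol.x[0]))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return HertzFit(E_est=E_est, contact_point=float(sol.x[1]), rms_residual=rms)


def hertz_forward(depth, E: float, tip_half_angle: float, *,
                  contact_point: float = 0.0, nu: float = 0.5,
                  prefactor: float = PYRAMID_PREFACTOR) -> np.ndarray:
    """Forward pyramidal contact model: force (nN) at given depths (um)."""
    if E <= 0:
        raise InvalidArgumentError("modulus must be positive")
    tan_theta = float(np.tan(np.deg2rad(tip_half_angle)))
    return _pyramid_force(np.asarray(depth, dtype=float), contact_point, E, nu,
                          tan_theta, prefactor)


def fit_uniaxial_modulus(record: StressStrainRecord,
                         window: tuple[float, float] = (0.0, 0.05)) -> float:
    """Young's modulus as the slope of a stress-strain record over a strain
    window.

    The least-squares line is forced through the origin whenever the window
    contains (or brackets) zero strain; otherwise a free line is fitted and
    its slope returned.  Default window is the 0-5% small-strain range.
    """
    lo, hi = min(window), max(window)
    mask = (record.strain >= lo) & (record.strain <= hi)
    eps = record.strain[mask]
    sig = record.stress[mask]
    if eps.size < 2:
        raise InsufficientDataError(
            f"strain window [{lo}, {hi}] contains {eps.size} points; need >= 2")
    if lo <= 0.0 <= hi:
        # through-origin slope; drop exact zeros that carry no information
        nz = eps != 0
        if not np.any(nz):
            raise InsufficientDataError("window contains only zero-strain points")
        return float(np.dot(sig[nz], eps[nz]) / np.dot(eps[nz], eps[nz]))
    slope, _ = np.polyfit(eps, sig, 1)
    return float(slope)
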