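"""Displacement-controlled diametral compression of the sensor cross-section.

The tissue folds are modelled as two rigid, frictionless surfaces approaching
symmetrically along the mediolateral (x) axis; the ring resists by bending.
Geometric nonlinearity is handled corotationally: each element carries its
precomputed small-strain stiffness (see :mod:`.elements`) and its current
mean rotation, extracted from the deformation gradient at the element
centroid, so large rotations at small material strains are represented
exactly to leading order.

All internal mechanics are per unit cylinder height; reported forces are
multiplied by H.  Units: um, kPa (= nN/um^2), nN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..errors import (
    ContactResolutionError,
    ConvergenceError,
    InsufficientDataError,
    InvalidArgumentError,
)
from ..materials import MaterialModel
from .elements import centroid_dndx, qm6_stiffness
from .mesh import RingMesh

#: Poisson ratio actually used in plane strain for incompressible materials;
#: nu = 0.5 exactly is singular, and 0.4995 keeps the volumetric stiffness
#: ~1000x the shear stiffness, numerically indistinguishable from
#: incompressible at the force levels resolved here.
NU_PLANE_STRAIN_CAP = 0.4995


@dataclass(frozen=True)
class ContactConfig:
    """How the rigid tissue surfaces touch the ring.

    ``mode`` is one of ``flat_plates`` (two rigid planes, contact arc grows
    with load), ``point_load`` (displacement prescribed at the two
    mediolateral extremes — the classical ring-bending configuration), or
    ``conforming_arc`` (rigid circular surfaces that hug the undeformed outer
    wall over ``arc_half_angle`` degrees, emulating distributed tissue
    contact).  ``penalty`` scales the contact stiffness in units of E times
    the per-node tributary arc length.  Contact is always frictionless.
    """

    mode: str = "flat_plates"
    arc_half_angle: float = 60.0
    penalty: float = 1e3
    friction: str = "frictionless"

    def __post_init__(self) -> None:
        if self.mode not in ("flat_plates", "point_load", "conforming_arc"):
            raise InvalidArgumentError(f"unknown contact mode {self.mode!r}")
        if not (0.0 < self.arc_half_angle <= 90.0):
            raise InvalidArgumentError("arc_half_angle must be in (0, 90] degrees")
        if self.penalty <= 0:
            raise InvalidArgumentError("penalty must be positive")
        if self.friction != "frictionless":
            raise InvalidArgumentError("only frictionless contact is supported")


@dataclass
class ForceDisplacementCurve:
    """Contact force F (nN) versus mediolateral narrowing delta (um).

    ``width0`` is the undeformed outer width (= D) when the curve came from a
    solve; synthetic curves may leave it None and pass the width explicitly
    to the analysis helpers.
    """

    narrowing: np.ndarray
    force: np.ndarray
    width0: float | None = None

    def __post_init__(self) -> None:
        self.narrowing = np.asarray(self.narrowing, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.narrowing.shape != self.force.shape:
            raise InvalidArgumentError("narrowing and force must have equal length")
        if self.narrowing.size and abs(self.narrowing[0]) > 1e-12:
            raise InvalidArgumentError("curve must start at zero narrowing")
        if np.any(np.diff(self.narrowing) <= 0):
            raise InvalidArgumentError("narrowing must be strictly increasing")


@dataclass
class RingSolution:
    """Full solver output: reference nodes, final displacement field, and the
    per-step force/energy history (forces on each rigid surface separately,
    for balance checks; energies for the whole cylinder, in fJ = nN um)."""

    node_coords: np.ndarray
    u: np.ndarray
    narrowing: np.ndarray
    force_left: np.ndarray
    force_right: np.ndarray
    strain_energy: np.ndarray
    external_work: np.ndarray
    newton_iterations: list = field(default_factory=list)

    @property
    def u_x(self) -> np.ndarray:
        """Mediolateral displacement component per node."""
        return self.u[0::2]


class _CorotAssembler:
    """Batched corotational internal force / tangent for one mesh+material."""

    def __init__(self, mesh: RingMesh, E: float, nu: float):
        self.mesh = mesh
        X = mesh.nodes[mesh.elems]                      # (M, 4, 2)
        self.X = X
        self.Ke = qm6_stiffness(X, E, nu)               # (M, 8, 8)
        self.Ke5 = self.Ke.reshape(-1, 4, 2, 4, 2)
        self.dndx0 = centroid_dndx(X)                   # (M, 4, 2)
        self.Xc = X.mean(axis=1)                        # (M, 2)
        dofs = np.empty((mesh.n_elems, 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * mesh.elems
        dofs[:, 1::2] = 2 * mesh.elems + 1
        self.dofs = dofs
        self.rows = np.repeat(dofs, 8, axis=1).ravel()
        self.cols = np.tile(dofs, (1, 8)).ravel()
        self.ndof = 2 * mesh.n_nodes

    def internal(self, u: np.ndarray, need_tangent: bool = True):
        """Internal force vector, tangent matrix (optional) and strain energy
        at u."""
        mesh = self.mesh
        ue = u.reshape(-1, 2)[mesh.elems]               # (M, 4, 2)
        xe = self.X + ue
        # mean deformation gradient at centroid -> element rotation
        F = np.einsum("mia,mib->mab", ue, self.dndx0)
        F[:, 0, 0] += 1.0
        F[:, 1, 1] += 1.0
        ang = np.arctan2(F[:, 1, 0] - F[:, 0, 1], F[:, 0, 0] + F[:, 1, 1])
        c, s = np.cos(ang), np.sin(ang)
        R = np.empty((len(c), 2, 2))
        R[:, 0, 0] = c
        R[:, 0, 1] = -s
        R[:, 1, 0] = s
        R[:, 1, 1] = c
        # deformational displacement, back-rotated to the reference frame
        rel = xe - xe.mean(axis=1, keepdims=True)       # (M, 4, 2)
        ud = np.einsum("mba,mib->mia", R, rel) - (self.X - self.Xc[:, None, :])
        udf = ud.reshape(-1, 8)
        fl = np.einsum("mij,mj->mi", self.Ke, udf)      # local internal force
        energy = 0.5 * float(np.einsum("mi,mi->", fl, udf))
        fg = np.einsum("mab,mib->mia", R, fl.reshape(-1, 4, 2)).reshape(-1, 8)
        fvec = np.zeros(self.ndof)
        np.add.at(fvec, self.dofs.ravel(), fg.ravel())
        if not need_tangent:
            return fvec, None, energy
        # tangent: rotated element stiffness (the omitted geometric terms are
        # O(strain) smaller; they slow Newton slightly, never change the root)
        Kg = np.einsum("mab,mibjd,mcd->miajc", R, self.Ke5, R).reshape(-1, 8, 8)
        K = sp.coo_matrix((Kg.ravel(), (self.rows, self.cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        return fvec, K, energy


def _contact_forces(mesh: RingMesh, u: np.ndarray, config: ContactConfig,
                    E: float, delta: float):
    """External nodal forces from the rigid surfaces at narrowing ``delta``,
    the contact tangent (COO triplets) and the worst penetration.

    Forces are per unit height.  Returns
    (f_ext, rows, cols, vals, F_left, F_right, max_pen).
    """
    outer = mesh.outer_nodes
    geo = mesh.geometry
    r_out = geo.D / 2.0
    trib = 2.0 * np.pi * r_out / mesh.n_circ
    k_n = config.penalty * E * trib      # per-node stiffness (conforming_arc)
    # C1-smoothed penalty: quadratic ramp over eps, linear beyond.  The kink
    # of the plain penalty makes Newton cycle through active sets; smoothing
    # removes the kink at the cost of an extra eps/2 of effective penetration,
    # accounted for in the penetration check.
    eps = 5e-4 * geo.t

    def make_pen_force(stiff):
        def pen_force(p):
            f = np.where(p < eps, stiff * p ** 2 / (2.0 * eps),
                         stiff * (p - eps / 2.0))
            k = np.where(p < eps, stiff * p / eps, stiff)
            return f, k
        return pen_force

    pos = mesh.nodes[outer] + u.reshape(-1, 2)[outer]
    f_ext = np.zeros(u.size)
    rows: list = []
    cols: list = []
    vals: list = []
    F_left = F_right = 0.0
    max_pen = 0.0

    if config.mode == "flat_plates":
        # lumped nodal penalty with tributary-arc scaling; gaps evaluated at
        # the outer nodes so the intra-edge bending of the surface elements
        # is not excited by mid-edge loads
        x_plate = r_out - delta / 2.0
        pen_force = make_pen_force(k_n)
        for side in (+1, -1):
            pen = side * pos[:, 0] - x_plate
            active = pen > 0
            if not np.any(active):
                continue
            max_pen = max(max_pen, float(pen[active].max()))
            f_nodes, k_nodes = pen_force(pen[active])
            dx = 2 * outer[active]
            f_ext[dx] += -side * f_nodes
            rows.extend(dx)
            cols.extend(dx)
            vals.extend(k_nodes)
            if side > 0:
                F_right = float(f_nodes.sum())
            else:
                F_left = -float(f_nodes.sum())
    else:  # conforming_arc
        pen_force = make_pen_force(k_n)
        phi = np.deg2rad(config.arc_half_angle)
        theta_ref = np.arctan2(mesh.nodes[outer, 1], mesh.nodes[outer, 0])
        for side, center_x in ((+1, -delta / 2.0), (-1, +delta / 2.0)):
            if side > 0:
                in_arc = np.abs(theta_ref) <= phi
            else:
                in_arc = np.abs(np.abs(theta_ref) - np.pi) <= phi
            rel = pos[in_arc] - np.array([center_x, 0.0])
            dist = np.linalg.norm(rel, axis=1)
            pen = dist - r_out
            active = pen > 0
            if not np.any(active):
                continue
            max_pen = max(max_pen, float(pen[active].max()))
            n_hat = rel[active] / dist[active, None]
            f_nodes, k_nodes = pen_force(pen[active])
            idx = outer[in_arc][active]
            f_ext[2 * idx] += -f_nodes * n_hat[:, 0]
            f_ext[2 * idx + 1] += -f_nodes * n_hat[:, 1]
            for a in range(2):
                for b in range(2):
                    rows.extend(2 * idx + a)
                    cols.extend(2 * idx + b)
                    vals.extend(k_nodes * n_hat[:, a] * n_hat[:, b])
            total = float(np.sum(f_nodes * n_hat[:, 0]))
            if side > 0:
                F_right = total
            else:
                F_left = total
    return f_ext, rows, cols, vals, F_left, F_right, max_pen


def _symmetry_bcs(mesh: RingMesh) -> dict[int, float]:
    """u_x = 0 on the y symmetry plane, u_y = 0 on the x symmetry plane."""
    n_c = mesh.n_circ
    fixed: dict[int, float] = {}
    for layer in range(mesh.n_rad + 1):
        base = layer * n_c
        fixed[2 * (base + n_c // 4)] = 0.0
        fixed[2 * (base + 3 * n_c // 4)] = 0.0
        fixed[2 * base + 1] = 0.0
        fixed[2 * (base + n_c // 2) + 1] = 0.0
    return fixed


def solve_diametral_compression(
    mesh: RingMesh,
    material: MaterialModel,
    contact: ContactConfig | None = None,
    max_narrowing: float = 10.0,
    n_steps: int | None = None,
    *,
    newton_tol_scale: float = 1e-8,
    max_newton_iter: int = 60,
) -> tuple[RingSolution, ForceDisplacementCurve]:
    """Incrementally compress the ring to ``max_narrowing`` (um of outer-width
    reduction) and return the solution history and force-narrowing curve.

    The solve is displacement controlled: the narrowing is ramped in
    ``n_steps`` equal increments (default: steps of at most 1% of D) and each
    step equilibrated by Newton iteration to a residual below
    ``newton_tol_scale * E * H * t`` (the natural force scale of the wall).
    On non-convergence the step is bisected up to four times before
    ``ConvergenceError`` is raised with the failing step index.
    """
    contact = contact or ContactConfig()
    geo = mesh.geometry
    if max_narrowing < 0:
        raise InvalidArgumentError("max_narrowing must be non-negative")
    if max_narrowing >= 0.4 * geo.D:
        raise InvalidArgumentError(
            f"max_narrowing must stay below 0.4 D = {0.4 * geo.D:g} um")
    E = material.E
    nu = min(material.nu, NU_PLANE_STRAIN_CAP)
    if max_narrowing == 0:
        zero = np.array([0.0])
        solution = RingSolution(
            node_coords=mesh.nodes.copy(), u=np.zeros(2 * mesh.n_nodes),
            narrowing=zero, force_left=zero.copy(), force_right=zero.copy(),
            strain_energy=zero.copy(), external_work=zero.copy())
        return solution, ForceDisplacementCurve(narrowing=zero.copy(),
                                                force=zero.copy(),
                                                width0=geo.D)
    if n_steps is None:
        n_steps = max(1, int(np.ceil(max_narrowing / (0.01 * geo.D))))

    asm = _CorotAssembler(mesh, E, nu)
    ndof = asm.ndof
    fixed = _symmetry_bcs(mesh)

    n_c = mesh.n_circ
    load_right = [layer * n_c for layer in range(mesh.n_rad + 1)]
    load_left = [layer * n_c + n_c // 2 for layer in range(mesh.n_rad + 1)]
    point_load = contact.mode == "point_load"

    tol = newton_tol_scale * E * geo.t          # per-unit-height force scale
    u = np.zeros(ndof)
    deltas = np.linspace(0.0, max_narrowing, n_steps + 1)
    forces_l = [0.0]
    forces_r = [0.0]
    energies = [0.0]
    works = [0.0]
    iter_log: list[int] = []

    def newton_at(delta: float, u_in: np.ndarray):
        uu = u_in.copy()
        bc = dict(fixed)
        if point_load:
            for n in load_right:
                bc[2 * n] = -delta / 2.0
            for n in load_left:
                bc[2 * n] = +delta / 2.0
        bc_idx = np.fromiter(bc.keys(), dtype=np.int64)
        bc_val = np.fromiter(bc.values(), dtype=float)
        free = np.setdiff1d(np.arange(ndof), bc_idx)
        uu[bc_idx] = bc_val

        def evaluate(uv, need_tangent):
            f_int, K, energy = asm.internal(uv, need_tangent)
            if point_load:
                resid = f_int
                cK = None
                F_l = float(sum(f_int[2 * n] for n in load_left))
                F_r = float(-sum(f_int[2 * n] for n in load_right))
                max_pen = 0.0
            else:
                f_c, cr, cc, cv, F_l, F_r, max_pen = _contact_forces(
                    mesh, uv, contact, E, delta)
                resid = f_int - f_c
                cK = (sp.coo_matrix((cv, (cr, cc)), shape=(ndof, ndof)).tocsr()
                      if need_tangent and cr else None)
            if K is not None and cK is not None:
                K = K + cK
            rn = float(np.linalg.norm(resid[free]))
            return resid, K, rn, (energy, F_l, F_r, max_pen)

        resid, Kt, rn, aux = evaluate(uu, True)
        for it in range(max_newton_iter):
            if rn < tol:
                return uu, (*aux, it + 1)
            du = np.zeros(ndof)
            du[free] = spla.spsolve(Kt[free][:, free].tocsc(), -resid[free])
            # backtracking on the residual norm guards against contact
            # active-set overshoot; trials skip the tangent assembly
            alpha = 1.0
            for _ in range(10):
                trial = evaluate(uu + alpha * du, False)
                if trial[2] < rn:
                    break
                alpha *= 0.5
            uu = uu + alpha * du
            resid, _, rn, aux = trial
            if rn >= tol:
                resid, Kt, rn, aux = evaluate(uu, True)
        raise ConvergenceError("Newton iteration stalled", residual=rn)

    prev_force = 0.0
    prev_delta = 0.0
    for step in range(1, n_steps + 1):
        target = deltas[step]
        try:
            u, info = newton_at(target, u)
        except ConvergenceError:
            ok = False
            for n_sub in (2, 4, 8, 16):
                try:
                    uu = u.copy()
                    for sub in np.linspace(prev_delta, target, n_sub + 1)[1:]:
                        uu, info = newton_at(sub, uu)
                    u = uu
                    ok = True
                    break
                except ConvergenceError:
                    continue
            if not ok:
                raise ConvergenceError(
                    f"diametral compression failed to converge at step {step} "
                    f"(narrowing {target:.3g} um)", step=step)
        energy, F_l, F_r, max_pen, iters = info
        if max_pen > 1e-3 * geo.t:
            raise ContactResolutionError(
                f"contact penetration {max_pen:.3g} um exceeds tolerance "
                f"{1e-3 * geo.t:.3g} um at step {step}; increase the penalty")
        iter_log.append(iters)
        force = 0.5 * (abs(F_l) + abs(F_r)) * geo.H
        forces_l.append(F_l * geo.H)
        forces_r.append(F_r * geo.H)
        energies.append(energy * geo.H)
        works.append(works[-1] + 0.5 * (prev_force + force) * (target - prev_delta))
        prev_force, prev_delta = force, target

    narrow = np.asarray(deltas)
    force_total = 0.5 * (np.abs(np.asarray(forces_l)) +
                         np.abs(np.asarray(forces_r)))
    solution = RingSolution(
        node_coords=mesh.nodes.copy(), u=u, narrowing=narrow,
        force_left=np.asarray(forces_l), force_right=np.asarray(forces_r),
        strain_energy=np.asarray(energies), external_work=np.asarray(works),
        newton_iterations=iter_log)
    curve = ForceDisplacementCurve(narrowing=narrow, force=force_total,
                                   width0=geo.D)
    return solution, curve


def extract_stiffness(curve: ForceDisplacementCurve, window: float = 0.02,
                      width0: float | None = None) -> float:
    """Small-displacement stiffness k (nN/um): least-squares slope through the
    origin of the force-narrowing curve over narrowing <= window * width.

    ``window`` is a fraction of the undeformed outer width (default 2%);
    ``width0`` overrides the width stored on the curve.
    """
    w0 = width0 if width0 is not None else curve.width0
    if w0 is None:
        raise InvalidArgumentError(
            "curve carries no width0; pass width0 explicitly")
    mask = (curve.narrowing > 0) & (curve.narrowing <= window * w0 + 1e-12)
    if int(mask.sum()) < 1:
        raise InsufficientDataError(
            f"no curve points inside the {window:.3g} * width window")
    d = curve.narrowing[mask]
    f = curve.force[mask]
    return float(np.dot(f, d) / np.dot(d, d))


def linearity_limit(curve: ForceDisplacementCurve, width0: float | None = None,
                    tolerance: float = 0.10, *,
                    tangent_window: float = 0.02) -> float:
    """Largest strain (% change of width) up to which the secant stiffness
    F/delta stays within ``tolerance`` of the initial tangent stiffness.

    The tangent is the through-origin slope over the small-displacement
    window; the curve is scanned outward and the strain of the last point
    before the first violation is returned (the full extent if none occurs).
    """
    w0 = width0 if width0 is not None else curve.width0
    if w0 is None:
        raise InvalidArgumentError("curve carries no width0; pass width0")
    mask = curve.narrowing > 0
    if int(mask.sum()) < 3:
        raise InsufficientDataError("curve too short for a linearity scan")
    k_tan = extract_stiffness(curve, window=tangent_window, width0=w0)
    d = curve.narrowing[mask]
    secant = curve.force[mask] / d
    dev = np.abs(secant / k_tan - 1.0)
    bad = np.nonzero(dev > tolerance)[0]
    if bad.size == 0:
        return float(d[-1] / w0 * 100.0)
    if bad[0] == 0:
        return 0.0
    return float(d[bad[0] - 1] / w0 * 100.0)
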