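"""Corotational planar frame solver for printed bar / spring shapes.

Bars printed along the tissue folds and V-shaped spring interconnects behave
like slender planar frames: their response to end shortening is dominated by
initial curvature and buckling, which is why the cylinder — with its
quasilinear diametral response — is the calibrated sensor shape.  This module
provides the geometrically nonlinear (corotational Euler-Bernoulli) solver
used to demonstrate those qualitative differences.

Units: um, kPa, nN; forces include the out-of-plane extrusion depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..errors import ConvergenceError, InvalidArgumentError
from ..materials import MaterialModel
from .solver import ForceDisplacementCurve


@dataclass
class FrameShape:
    """Planar frame defined by an ordered centerline polyline (um), a
    rectangular cross-section (in-plane ``section_width`` x out-of-plane
    ``depth``, um) and the end support condition (pinned or clamped)."""

    centerline: np.ndarray
    section_width: float
    depth: float
    end_constraint: str = "pinned"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2 \
                or self.centerline.shape[1] != 2:
            raise InvalidArgumentError("centerline must be (n>=2, 2) points")
        if self.section_width <= 0 or self.depth <= 0:
            raise InvalidArgumentError("section dimensions must be positive")
        if self.end_constraint not in ("pinned", "clamped"):
            raise InvalidArgumentError("end_constraint must be pinned or clamped")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0),
                                           axis=1)))


def _discretize(points: np.ndarray, n_target: int) -> np.ndarray:
    """Subdivide a polyline into ~n_target roughly equal elements."""
    segs = np.diff(points, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    total = lengths.sum()
    nodes = [points[0]]
    for p0, seg, ln in zip(points[:-1], segs, lengths):
        n = max(1, int(round(n_target * ln / total)))
        for i in range(1, n + 1):
            nodes.append(p0 + seg * (i / n))
    return np.asarray(nodes)


def _element_force(Xi, Xj, ui, uj, EA, EI, l0, beta0):
    """Corotational beam internal force (6,) for one element."""
    xi = Xi + ui[:2]
    xj = Xj + uj[:2]
    dx = xj - xi
    l = float(np.hypot(dx[0], dx[1]))
    beta = float(np.arctan2(dx[1], dx[0]))
    c, s = dx[0] / l, dx[1] / l
    rot = beta - beta0
    rot = (rot + np.pi) % (2.0 * np.pi) - np.pi
    t1 = ui[2] - rot
    t2 = uj[2] - rot
    ubar = (l * l - l0 * l0) / (l + l0)
    N = EA / l0 * ubar
    M1 = EI / l0 * (4.0 * t1 + 2.0 * t2)
    M2 = EI / l0 * (2.0 * t1 + 4.0 * t2)
    r = np.array([-c, -s, 0.0, c, s, 0.0])
    z = np.array([s, -c, 0.0, -s, c, 0.0]) / l
    f = r * N + (np.array([0, 0, 1.0, 0, 0, 0]) - z) * M1 \
        + (np.array([0, 0, 0, 0, 0, 1.0]) - z) * M2
    return f


def solve_frame_compression(
    shape: FrameShape,
    material: MaterialModel,
    end_shortening: float,
    n_steps: int = 20,
    *,
    n_elements: int = 48,
    imperfection: float = 1e-3,
    max_newton_iter: int = 100,
) -> ForceDisplacementCurve:
    """Compress a frame between its two end points and return the axial
    force versus end-shortening curve.

    The geometry is rotated so the end-to-end axis lies along x; the first
    end is held, the second is driven inward by ``end_shortening`` um in
    ``n_steps`` increments with the transverse displacement constrained
    (a slider).  Perfectly straight centerlines receive a half-sine
    transverse imperfection of amplitude ``imperfection * length`` so that
    buckling can break the symmetry.

    Element tangents are formed by central differences of the exact
    corotational internal force; this keeps the Newton loop simple and is
    plenty accurate for the modest problem sizes involved.
    """
    if end_shortening < 0:
        raise InvalidArgumentError("end_shortening must be non-negative")
    if end_shortening == 0:
        span0 = float(np.linalg.norm(shape.centerline[-1] - shape.centerline[0]))
        return ForceDisplacementCurve(narrowing=np.array([0.0]),
                                      force=np.array([0.0]), width0=span0)
    pts = shape.centerline.copy()
    chord = pts[-1] - pts[0]
    span = float(np.linalg.norm(chord))
    if span <= 0:
        raise InvalidArgumentError("frame ends coincide")
    if shape.section_width > shape.length / 5.0:
        raise InvalidArgumentError(
            "frame members must be slender (section_width <= length / 5)")
    # rotate so the compression axis is x
    ca, sa = chord / span
    Q = np.array([[ca, sa], [-sa, ca]])
    pts = (pts - pts[0]) @ Q.T

    nodes = _discretize(pts, n_elements)
    # seed an imperfection if the line is perfectly straight
    if np.max(np.abs(nodes[:, 1])) < 1e-9 * span and imperfection > 0:
        nodes[:, 1] += imperfection * span * np.sin(np.pi * nodes[:, 0] / span)

    n_nodes = nodes.shape[0]
    ndof = 3 * n_nodes
    EA = material.E * shape.depth * shape.section_width
    EI = material.E * shape.depth * shape.section_width ** 3 / 12.0

    elems = np.column_stack([np.arange(n_nodes - 1), np.arange(1, n_nodes)])
    l0s, beta0s = [], []
    for i, j in elems:
        d = nodes[j] - nodes[i]
        l0s.append(float(np.hypot(d[0], d[1])))
        beta0s.append(float(np.arctan2(d[1], d[0])))

    fixed_dofs = {0: 0.0, 1: 0.0, 3 * (n_nodes - 1) + 1: 0.0}
    if shape.end_constraint == "clamped":
        fixed_dofs[2] = 0.0
        fixed_dofs[3 * (n_nodes - 1) + 2] = 0.0
    drive_dof = 3 * (n_nodes - 1)

    def assemble(u):
        f = np.zeros(ndof)
        rows, cols, vals = [], [], []
        h = 1e-7 * span
        for (i, j), l0, b0 in zip(elems, l0s, beta0s):
            edofs = [3 * i, 3 * i + 1, 3 * i + 2, 3 * j, 3 * j + 1, 3 * j + 2]
            ue = u[edofs]
            fe = _element_force(nodes[i], nodes[j], ue[:3], ue[3:], EA, EI, l0, b0)
            f[edofs] += fe
            Ke = np.empty((6, 6))
            for d in range(6):
                up = ue.copy()
                um = ue.copy()
                up[d] += h
                um[d] -= h
                fp = _element_force(nodes[i], nodes[j], up[:3], up[3:], EA, EI, l0, b0)
                fm = _element_force(nodes[i], nodes[j], um[:3], um[3:], EA, EI, l0, b0)
                Ke[:, d] = (fp - fm) / (2.0 * h)
            for a, da in enumerate(edofs):
                rows.extend([da] * 6)
                cols.extend(edofs)
                vals.extend(Ke[a])
        K = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, ndof)).tocsr()
        return f, K

    tol = 1e-9 * EA / span * max(span, 1.0)
    u = np.zeros(ndof)
    shortenings = np.linspace(0.0, end_shortening, n_steps + 1)
    forces = [0.0]
    for step, sh in enumerate(shortenings[1:], start=1):
        bc = dict(fixed_dofs)
        bc[drive_dof] = -sh
        bc_idx = np.fromiter(bc.keys(), dtype=np.int64)
        bc_val = np.fromiter(bc.values(), dtype=float)
        free = np.setdiff1d(np.arange(ndof), bc_idx)
        u[bc_idx] = bc_val
        converged = False
        for _ in range(max_newton_iter):
            f, K = assemble(u)
            rn = float(np.linalg.norm(f[free]))
            if rn < tol:
                converged = True
                break
            du = np.zeros(ndof)
            du[free] = spla.spsolve(K[free][:, free].tocsc(), -f[free])
            u += du
        if not converged:
            raise ConvergenceError(
                f"frame compression failed to converge at step {step}",
                step=step, residual=rn)
        forces.append(-float(f[drive_dof]))   # compression positive
    return ForceDisplacementCurve(narrowing=shortenings,
                                  force=np.asarray(forces), width0=span)
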