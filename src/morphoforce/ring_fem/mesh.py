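"""Annulus meshing for the cylinder cross-section.

The cylinder (height H, outer diameter D, wall thickness t) is reduced to its
annular cross-section, meshed with a structured grid of quadrilaterals:
``n_circ`` elements around the circumference and ``n_rad`` through the wall.
Node ordering is deterministic: radial layer major, angular index minor, with
layer 0 on the inner surface and angle 0 on the +x (mediolateral) axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import InvalidGeometryError

#: parameter ranges covered by the calibration sweep (um); geometries outside
#: these warn because the fitted stiffness law is only validated inside.
SWEEP_RANGES = {"H": (20.0, 100.0), "D": (140.0, 220.0), "t": (5.0, 25.0)}


@dataclass(frozen=True)
class CylinderGeometry:
    """Sensor dimensions in um: height ``H``, outer diameter ``D``, wall
    thickness ``t``."""

    H: float
    D: float
    t: float

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise InvalidGeometryError(f"height must be positive, got {self.H}")
        if not (0.0 < self.t < self.D / 2.0):
            raise InvalidGeometryError(
                f"wall thickness must satisfy 0 < t < D/2, got t={self.t}, D={self.D}")
        for name, value in (("H", self.H), ("D", self.D), ("t", self.t)):
            lo, hi = SWEEP_RANGES[name]
            if not (lo <= value <= hi):
                warnings.warn(
                    f"{name}={value} um is outside the sweep-validated range "
                    f"[{lo}, {hi}] um; stiffness predictions are extrapolations",
                    stacklevel=3)

    @property
    def inner_diameter(self) -> float:
        return self.D - 2.0 * self.t

    @property
    def mid_diameter(self) -> float:
        """Wall mid-surface diameter D - t."""
        return self.D - self.t


@dataclass(frozen=True)
class RingMesh:
    """Structured quadrilateral annulus mesh.

    ``nodes`` is (n_nodes, 2) reference coordinates in um; ``elems`` is
    (n_elems, 4) counter-clockwise node indices.
    """

    geometry: CylinderGeometry
    nodes: np.ndarray
    elems: np.ndarray
    n_circ: int
    n_rad: int

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def layer_nodes(self, layer: int) -> np.ndarray:
        """Node indices of one radial layer (0 = inner, n_rad = outer)."""
        return np.arange(layer * self.n_circ, (layer + 1) * self.n_circ)

    @property
    def outer_nodes(self) -> np.ndarray:
        return self.layer_nodes(self.n_rad)

    def element_areas(self) -> np.ndarray:
        """Signed polygon area of each quadrilateral (shoelace)."""
        quad = self.nodes[self.elems]          # (M, 4, 2)
        x, y = quad[..., 0], quad[..., 1]
        xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * yn - xn * y, axis=1)


def build_ring_mesh(geometry: CylinderGeometry,
                    resolution: tuple[int, int] = (96, 4)) -> RingMesh:
    """Build the structured annulus mesh.

    ``resolution`` is (circumferential, radial) element counts, at least
    (96, 4); the circumferential count must be divisible by 4 so that nodes
    fall exactly on both symmetry axes.
    """
    n_circ, n_rad = resolution
    if n_circ < 96 or n_rad < 4:
        raise InvalidGeometryError(
            f"resolution must be at least (96, 4), got {resolution}")
    if n_circ % 4 != 0:
        raise InvalidGeometryError(
            "circumferential resolution must be divisible by 4 "
            "(symmetry-plane nodes)")

    r_in = geometry.inner_diameter / 2.0
    r_out = geometry.D / 2.0
    radii = np.linspace(r_in, r_out, n_rad + 1)
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ

    rr, tt = np.meshgrid(radii, theta, indexing="ij")
    nodes = np.column_stack([(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel()])

    i = np.repeat(np.arange(n_rad), n_circ)
    j = np.tile(np.arange(n_circ), n_rad)
    jp = (j + 1) % n_circ
    # counter-clockwise winding: inner j -> outer j -> outer j+1 -> inner j+1
    elems = np.column_stack([i * n_circ + j, (i + 1) * n_circ + j,
                             (i + 1) * n_circ + jp, i * n_circ + jp])

    return RingMesh(geometry=geometry, nodes=nodes, elems=elems.astype(np.int64),
                    n_circ=n_circ, n_rad=n_rad)
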