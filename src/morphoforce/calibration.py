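"""Calibration of the parametric stiffness law k = alpha * H * (t/D)^3 * E.

The sensor's structural stiffness k (contact force per um of mediolateral
narrowing) follows thin-ring bending scaling: linear in height H and Young's
modulus E, cubic in the wall slenderness t/D.  A single dimensionless
constant alpha absorbs the load geometry; it is fitted by least squares over
a finite-element parameter sweep and then reused to convert measured sensor
narrowing into force without further simulation.

The shipped default ``ALPHA_DEFAULT = 7.718`` is the constant used by the
inference pipeline; locally refitted values are reported alongside it, never
silently substituted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError
from .materials import MaterialModel
from .ring_fem import (
    ContactConfig,
    CylinderGeometry,
    build_ring_mesh,
    extract_stiffness,
    solve_diametral_compression,
)
from .ring_fem.mesh import SWEEP_RANGES

#: Default stiffness-law constant used for force inference.
ALPHA_DEFAULT = 7.718

#: Young's modulus sweep range, kPa.
E_RANGE = (5.0, 80.0)


@dataclass(frozen=True)
class SweepRecord:
    """One sweep cell: geometry (um), modulus E (kPa), stiffness k (nN/um)
    and solve status ('ok' or an error description)."""

    H: float
    D: float
    t: float
    E: float
    k: float
    status: str = "ok"

    @property
    def x(self) -> float:
        """The stiffness-law regressor H * (t/D)^3 * E."""
        return self.H * (self.t / self.D) ** 3 * self.E


@dataclass
class AlphaFit:
    """Fitted stiffness-law constant with goodness-of-fit diagnostics."""

    alpha: float
    records: list[SweepRecord] = field(default_factory=list)
    r_squared: float = float("nan")
    max_rel_residual: float = float("nan")


def run_sweep(
    H_values,
    D_values,
    t_values,
    E_values,
    *,
    resolution: tuple[int, int] = (96, 4),
    contact: ContactConfig | None = None,
    nu: float = 0.5,
    stiffness_window: float = 0.02,
    n_steps: int = 4,
    cache_dir: str | Path | None = None,
) -> list[SweepRecord]:
    """Run one ring solve per grid cell and extract the stiffness k.

    The narrowing is ramped to ``stiffness_window`` of D in ``n_steps``
    increments and k is the through-origin slope over that window.  Failed
    cells are recorded with ``status`` set to the error and k = nan; the
    sweep continues.  With ``cache_dir`` set, each cell's result is stored
    as a small JSON file keyed by its parameters so interrupted sweeps
    resume for free.
    """
    grids = [np.atleast_1d(np.asarray(v, dtype=float))
             for v in (H_values, D_values, t_values, E_values)]
    if any(g.size == 0 for g in grids):
        raise InvalidArgumentError("empty parameter grid")
    contact = contact or ContactConfig()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    records: list[SweepRecord] = []
    for H in grids[0]:
        for D in grids[1]:
            for t in grids[2]:
                for E in grids[3]:
                    key = (f"H{H:g}_D{D:g}_t{t:g}_E{E:g}_"
                           f"{contact.mode}_{resolution[0]}x{resolution[1]}")
                    if cache is not None and (cache / f"{key}.json").exists():
                        data = json.loads((cache / f"{key}.json").read_text())
                        records.append(SweepRecord(**data))
                        continue
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            geo = CylinderGeometry(H=float(H), D=float(D),
                                                   t=float(t))
                            mesh = build_ring_mesh(geo, resolution)
                            _, curve = solve_diametral_compression(
                                mesh, MaterialModel(E=float(E), nu=nu),
                                contact,
                                max_narrowing=stiffness_window * float(D),
                                n_steps=n_steps)
                        k = extract_stiffness(curve, window=stiffness_window)
                        rec = SweepRecord(H=float(H), D=float(D), t=float(t),
                                          E=float(E), k=k)
                    except Exception as exc:  # recorded, sweep continues
                        rec = SweepRecord(H=float(H), D=float(D), t=float(t),
                                          E=float(E), k=float("nan"),
                                          status=f"{type(exc).__name__}: {exc}")
                    records.append(rec)
                    if cache is not None:
                        (cache / f"{key}.json").write_text(json.dumps({
                            "H": rec.H, "D": rec.D, "t": rec.t, "E": rec.E,
                            "k": rec.k, "status": rec.status}))
    return records


def paper_grid(n_per_param: int = 3):
    """Evenly spaced (H, D, t, E) grids spanning the validated sweep ranges."""
    H = np.linspace(*SWEEP_RANGES["H"], n_per_param)
    D = np.linspace(*SWEEP_RANGES["D"], n_per_param)
    t = np.linspace(*SWEEP_RANGES["t"], n_per_param)
    E = np.linspace(*E_RANGE, n_per_param)
    return H, D, t, E


def fit_alpha(records: list[SweepRecord], *, method: str = "closed_form",
              weighting: str = "absolute") -> AlphaFit:
    """Least-squares fit of alpha in k = alpha * H * (t/D)^3 * E.

    With ``weighting='absolute'`` (default) the objective is
    sum_i (k_i - alpha x_i)^2 with x_i = H_i (t_i/D_i)^3 E_i, whose closed
    form is alpha = sum(k x) / sum(x^2).  ``method='numeric'`` solves the
    same problem through LAPACK's SVD least squares instead (the two routes
    must agree to machine precision).  ``weighting='relative'`` minimizes
    the relative residuals instead, down-weighting the stiffest cells.
    """
    good = [r for r in records if r.status == "ok" and np.isfinite(r.k)]
    if len(good) < 2:
        raise InsufficientDataError(
            f"need >= 2 successful sweep records, have {len(good)}")
    x = np.array([r.x for r in good])
    k = np.array([r.k for r in good])
    if np.any(x <= 0):
        raise InvalidArgumentError("stiffness-law regressor must be positive")

    if weighting == "relative":
        w = 1.0 / k ** 2
    elif weighting == "absolute":
        w = np.ones_like(k)
    else:
        raise InvalidArgumentError(f"unknown weighting {weighting!r}")

    if method == "closed_form":
        alpha = float(np.sum(w * k * x) / np.sum(w * x * x))
    elif method == "numeric":
        # independent route: SVD-based linear least squares (LAPACK), must
        # agree with the closed-form normal-equation solution
        sw = np.sqrt(w)
        sol, *_ = np.linalg.lstsq((sw * x)[:, None], sw * k, rcond=None)
        alpha = float(sol[0])
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")

    pred = alpha * x
    ss_res = float(np.sum((k - pred) ** 2))
    ss_tot = float(np.sum((k - np.mean(k)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    max_rel = float(np.max(np.abs(pred - k) / k))
    return AlphaFit(alpha=alpha, records=list(records), r_squared=r2,
                    max_rel_residual=max_rel)


def predict_stiffness(geometry: CylinderGeometry, E: float,
                      alpha: float = ALPHA_DEFAULT) -> float:
    """Stiffness k (nN/um) from the parametric law k = alpha H (t/D)^3 E.

    E in kPa, geometry in um.  Warns when E is outside the calibrated range
    (geometry ranges are checked by ``CylinderGeometry`` itself).
    """
    if E <= 0:
        raise InvalidArgumentError("E must be positive")
    if alpha < 0:
        raise InvalidArgumentError("alpha must be non-negative")
    if not (E_RANGE[0] <= E <= E_RANGE[1]):
        warnings.warn(
            f"E={E} kPa is outside the calibrated range {E_RANGE}; "
            "the stiffness law is an extrapolation", stacklevel=2)
    return alpha * geometry.H * (geometry.t / geometry.D) ** 3 * E
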