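"""CSV / YAML interchange for traces, curves, records and configs.

File conventions (all plain text):

* deformation trace: columns ``time_min, width_um`` (+ optional ``embryo``)
* force profile:     ``time_min, strain_pct, force_nN, energy_pJ, valid``
* force-displacement curve: ``narrowing_um, force_nN``
* AFM curve:         ``depth_um, force_nN``
* stress-strain:     ``strain, stress_kPa``
* sweep table:       ``H_um, D_um, t_um, E_kPa, k_nN_per_um, status``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .calibration import SweepRecord
from .errors import InvalidArgumentError
from .inference import DeformationTrace, ForceProfile
from .materials import AFMCurve, StressStrainRecord
from .ring_fem import ForceDisplacementCurve


def _require(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"{path}: missing columns {missing}")


def read_trace(path) -> DeformationTrace:
    df = pd.read_csv(path)
    _require(df, ("time_min", "width_um"), path)
    return DeformationTrace(times=df["time_min"].to_numpy(float),
                            width=df["width_um"].to_numpy(float))


def write_trace(trace: DeformationTrace, path) -> None:
    pd.DataFrame({"time_min": trace.times, "width_um": trace.width}
                 ).to_csv(path, index=False)


def read_traces_dir(directory) -> dict[str, DeformationTrace]:
    """All ``*.csv`` traces in a directory, keyed by file stem."""
    out = {}
    for p in sorted(Path(directory).glob("*.csv")):
        out[p.stem] = read_trace(p)
    if not out:
        raise InvalidArgumentError(f"no trace CSVs found in {directory}")
    return out


def write_profile(profile: ForceProfile, path) -> None:
    pd.DataFrame({
        "time_min": profile.times,
        "strain_pct": profile.strain,
        "force_nN": profile.force,
        "energy_pJ": profile.energy,
        "valid": profile.valid.astype(int),
    }).to_csv(path, index=False)


def write_curve(curve: ForceDisplacementCurve, path) -> None:
    pd.DataFrame({"narrowing_um": curve.narrowing,
                  "force_nN": curve.force}).to_csv(path, index=False)


def read_curve(path) -> ForceDisplacementCurve:
    df = pd.read_csv(path)
    _require(df, ("narrowing_um", "force_nN"), path)
    return ForceDisplacementCurve(narrowing=df["narrowing_um"].to_numpy(float),
                                  force=df["force_nN"].to_numpy(float))


def read_afm_curve(path, tip_half_angle: float = 20.0,
                   spring_constant: float = 0.2) -> AFMCurve:
    df = pd.read_csv(path)
    _require(df, ("depth_um", "force_nN"), path)
    return AFMCurve(depth=df["depth_um"].to_numpy(float),
                    force=df["force_nN"].to_numpy(float),
                    tip_half_angle=tip_half_angle,
                    spring_constant=spring_constant)


def write_afm_curve(curve: AFMCurve, path) -> None:
    pd.DataFrame({"depth_um": curve.depth,
                  "force_nN": curve.force}).to_csv(path, index=False)


def read_stress_strain(path) -> StressStrainRecord:
    df = pd.read_csv(path)
    _require(df, ("strain", "stress_kPa"), path)
    return StressStrainRecord(strain=df["strain"].to_numpy(float),
                              stress=df["stress_kPa"].to_numpy(float))


def write_sweep(records: list[SweepRecord], path) -> None:
    pd.DataFrame([{
        "H_um": r.H, "D_um": r.D, "t_um": r.t, "E_kPa": r.E,
        "k_nN_per_um": r.k, "status": r.status} for r in records]
    ).to_csv(path, index=False)


def read_sweep(path) -> list[SweepRecord]:
    df = pd.read_csv(path)
    _require(df, ("H_um", "D_um", "t_um", "E_kPa", "k_nN_per_um"), path)
    status = df["status"] if "status" in df.columns else ["ok"] * len(df)
    return [SweepRecord(H=row.H_um, D=row.D_um, t=row.t_um, E=row.E_kPa,
                        k=row.k_nN_per_um, status=s)
            for row, s in zip(df.itertuples(), status)]
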