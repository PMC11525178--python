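"""Run configuration: schema-checked YAML/JSON configs and stage dispatch.

A run config names one pipeline stage (subcommand), its input files and
parameter overrides.  ``validate_config`` normalizes units to the internal
system and fills defaults; ``run`` executes the stage, writes its outputs
and a provenance JSON (config hash, package version, seed) into the output
directory, and returns a non-zero status on any stage error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibration import ALPHA_DEFAULT
from .errors import ConfigError, MorphoForceError
from .units import n_per_m_to_nn_per_um

logger = logging.getLogger("morphoforce")

SUBCOMMANDS = ("simulate-ring", "calibrate-alpha", "fit-afm", "fit-uniaxial",
               "extract", "infer-force", "cohort", "synth")

#: recognized top-level keys -> default value (``...`` = required/no default)
_SCHEMA = {
    "subcommand": ...,
    "inputs": {},
    "out_dir": "results",
    "seed": 0,
    "log_level": "INFO",
    "alpha": ALPHA_DEFAULT,
    "nu": 0.5,
    "impulse_window_min": 60.0,
    "k_nN_per_um": None,
    "k_N_per_m": None,
    "E_kPa": None,
    "geometry": None,          # {"H_um": .., "D_um": .., "t_um": ..}
    "contact_mode": "flat_plates",
    "max_narrowing_um": None,
    "resolution": [96, 4],
    "grid": None,              # {"H_um": [...], "D_um": [...], ...}
    "pixel_size_um": 0.59,
    "time_step_min": 30.0,
    "half_angle_deg": 20.0,
    "strain_window": [0.0, 0.05],
    "synth_kind": "trajectory",
    "synth_params": {},
}


@dataclass
class RunConfig:
    """Normalized run configuration (internal units)."""

    subcommand: str
    inputs: dict = field(default_factory=dict)
    out_dir: Path = Path("results")
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)
    source_text: str = ""

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Parse, schema-check and normalize a YAML/JSON config file.

    Unknown keys raise ``ConfigError`` naming them; a stiffness given in
    N/m is converted exactly to nN/um (x1000).
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not parseable as YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")

    unknown = sorted(set(raw) - set(_SCHEMA))
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {unknown}")
    if "subcommand" not in raw:
        raise ConfigError(f"{path}: missing required key 'subcommand'")
    sub = raw["subcommand"]
    if sub not in SUBCOMMANDS:
        raise ConfigError(
            f"{path}: unknown subcommand {sub!r}; choose from {SUBCOMMANDS}")

    params = {k: raw.get(k, d) for k, d in _SCHEMA.items()
              if k not in ("subcommand", "inputs", "out_dir", "seed",
                           "log_level")}
    if params.get("k_N_per_m") is not None:
        if params.get("k_nN_per_um") is not None:
            raise ConfigError(f"{path}: give k in only one unit")
        params["k_nN_per_um"] = n_per_m_to_nn_per_um(params.pop("k_N_per_m"))
    else:
        params.pop("k_N_per_m", None)

    inputs = raw.get("inputs", {}) or {}
    for name, p in inputs.items():
        if not Path(p).exists():
            raise ConfigError(f"{path}: input {name!r} does not exist: {p}")

    return RunConfig(subcommand=sub, inputs=dict(inputs),
                     out_dir=Path(raw.get("out_dir", "results")),
                     seed=int(raw.get("seed", 0)),
                     log_level=str(raw.get("log_level", "INFO")),
                     params=params, source_text=text)


def write_provenance(config: RunConfig, extra: dict | None = None) -> Path:
    config.out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "morphoforce",
        "version": __version__,
        "subcommand": config.subcommand,
        "config_hash": config.config_hash,
        "seed": config.seed,
    }
    if extra:
        payload.update(extra)
    path = config.out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2))
    return path


def run(config: RunConfig) -> int:
    """Execute the configured stage; returns 0 on success, 1 on stage error.

    Outputs land in ``config.out_dir`` together with a provenance JSON.
    Imports are local so that a config error surfaces before any heavy
    module loads.
    """
    from . import calibration, inference, io, materials, synthetic
    from .imaging import load_stack, extract_trace
    from .materials import MaterialModel
    from .ring_fem import (ContactConfig, CylinderGeometry, build_ring_mesh,
                           extract_stiffness, solve_diametral_compression)

    logging.basicConfig(level=config.log_level)
    p = config.params
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    try:
        if config.subcommand == "simulate-ring":
            g = p["geometry"] or {}
            geo = CylinderGeometry(H=g.get("H_um", 20.0),
                                   D=g.get("D_um", 180.0),
                                   t=g.get("t_um", 15.0))
            mesh = build_ring_mesh(geo, tuple(p["resolution"]))
            contact = ContactConfig(mode=p["contact_mode"])
            max_n = p["max_narrowing_um"] or 0.02 * geo.D
            _, curve = solve_diametral_compression(
                mesh, MaterialModel(E=p["E_kPa"] or 80.0, nu=p["nu"]),
                contact, max_narrowing=max_n)
            io.write_curve(curve, out / "curve.csv")
            (out / "stiffness.json").write_text(json.dumps(
                {"k_nN_per_um": extract_stiffness(curve)}))
        elif config.subcommand == "calibrate-alpha":
            grid = p["grid"] or {}
            n = int(grid.get("n_per_param", 3))
            H, D, t, E = calibration.paper_grid(n)
            recs = calibration.run_sweep(
                grid.get("H_um", H), grid.get("D_um", D),
                grid.get("t_um", t), grid.get("E_kPa", E),
                resolution=tuple(p["resolution"]),
                contact=ContactConfig(mode=p["contact_mode"]))
            fit = calibration.fit_alpha(recs)
            io.write_sweep(recs, out / "sweep.csv")
            (out / "alpha.json").write_text(json.dumps({
                "alpha": fit.alpha, "alpha_default": ALPHA_DEFAULT,
                "r_squared": fit.r_squared,
                "max_rel_residual": fit.max_rel_residual,
                "n_records": len(fit.records)}))
        elif config.subcommand == "fit-afm":
            curve = io.read_afm_curve(config.inputs["curve"],
                                      tip_half_angle=p["half_angle_deg"])
            fit = materials.fit_hertz_pyramidal(curve, nu=p["nu"])
            (out / "hertz.json").write_text(json.dumps({
                "E_kPa": fit.E_est, "contact_point_um": fit.contact_point,
                "rms_residual_nN": fit.rms_residual}))
        elif config.subcommand == "fit-uniaxial":
            rec = io.read_stress_strain(config.inputs["record"])
            E = materials.fit_uniaxial_modulus(rec, tuple(p["strain_window"]))
            (out / "uniaxial.json").write_text(json.dumps({"E_kPa": E}))
        elif config.subcommand == "extract":
            stack = load_stack(config.inputs["stack"], p["pixel_size_um"],
                               p["time_step_min"])
            trace = extract_trace(stack)
            io.write_trace(trace, out / "trace.csv")
        elif config.subcommand == "infer-force":
            trace = io.read_trace(config.inputs["trace"])
            k = p.get("k_nN_per_um")
            if k is None:
                g = p["geometry"] or {}
                geo = CylinderGeometry(H=g.get("H_um", 20.0),
                                       D=g.get("D_um", 180.0),
                                       t=g.get("t_um", 15.0))
                k = calibration.predict_stiffness(geo, p["E_kPa"] or 80.0,
                                                  p["alpha"])
            profile = inference.infer_profile(trace, k)
            io.write_profile(profile, out / "profile.csv")
            summary = {"k_nN_per_um": k,
                       "final_energy_pJ": float(profile.energy[-1]),
                       "atp_equivalent": inference.atp_equivalent(
                           max(float(profile.energy[-1]), 0.0))}
            if profile.max_impulse_60 is not None:
                summary["max_impulse_60_nN_min"] = profile.max_impulse_60
            (out / "summary.json").write_text(json.dumps(summary))
        elif config.subcommand == "cohort":
            traces = io.read_traces_dir(config.inputs["traces"])
            k = p.get("k_nN_per_um") or 7.15
            profiles = [inference.infer_profile(t, k)
                        for t in traces.values()]
            summary = inference.cohort_profile(profiles)
            import pandas as pd
            pd.DataFrame({
                "time_min": summary.times, "mean_force_nN": summary.mean,
                "ci_low_nN": summary.ci_low, "ci_high_nN": summary.ci_high,
                "n": summary.n}).to_csv(out / "cohort.csv", index=False)
        elif config.subcommand == "synth":
            kind = p["synth_kind"]
            sp = dict(p["synth_params"] or {})
            if kind == "trajectory":
                tp = synthetic.TrajectoryParams(seed=config.seed, **sp)
                trace, truth = synthetic.make_trajectory(tp)
                io.write_trace(trace, out / "trace.csv")
                (out / "truth.json").write_text(json.dumps(
                    {k2: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k2, v in truth.items()}))
            elif kind == "cohort":
                cp = synthetic.CohortParams(seed=config.seed, **sp)
                traces, truths = synthetic.make_cohort(cp)
                for i, tr in enumerate(traces):
                    io.write_trace(tr, out / f"embryo_{i:02d}.csv")
                (out / "truth.json").write_text(json.dumps([
                    {k2: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k2, v in tt.items()} for tt in truths]))
            elif kind == "afm":
                curve, truth = synthetic.make_afm_curve(seed=config.seed, **sp)
                io.write_afm_curve(curve, out / "afm.csv")
                (out / "truth.json").write_text(json.dumps(truth))
            elif kind == "movie":
                tp = synthetic.TrajectoryParams(seed=config.seed)
                trace, _ = synthetic.make_trajectory(tp)
                stack, truth = synthetic.render_movie(trace,
                                                      seed=config.seed, **sp)
                import tifffile
                tifffile.imwrite(out / "movie.tif",
                                 stack.frames.astype(np.float32))
                (out / "truth.json").write_text(json.dumps(
                    {k2: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k2, v in truth.items()}))
            else:
                raise ConfigError(f"unknown synth kind {kind!r}")
        write_provenance(config)
    except MorphoForceError as exc:
        logger.error("%s failed: %s", config.subcommand, exc)
        return 1
    except KeyError as exc:
        logger.error("%s: missing input %s", config.subcommand, exc)
        return 1
    return 0
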