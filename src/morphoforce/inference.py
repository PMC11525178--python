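"""Force quantification from sensor deformation traces.

A time-lapse of the embedded sensor yields its mediolateral width over time;
with the calibrated stiffness k the pipeline converts that trace to strain,
force, stored elastic energy, impulse, an ATP-equivalent energy scale, and
cohort statistics.  Sign convention: compression (narrowing) is positive —
a widening sensor (e.g. under ROCK inhibition, where the neural folds splay
apart) carries negative strain and force.

Units: minutes, um, nN, pJ (see :mod:`morphoforce.units`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidArgumentError,
    InvalidTraceError,
)
from .units import PJ_PER_NN_UM

#: Strain magnitude (% of width) beyond which the constant-k conversion
#: leaves its validated linear range; forces are still reported but flagged.
LINEAR_STRAIN_LIMIT_PCT = 20.0

#: Free energy of ATP hydrolysis per molecule (J): ~60 kJ/mol / Avogadro.
ATP_DG_PER_MOLECULE_J = 1e-19


@dataclass
class DeformationTrace:
    """Sensor mediolateral width (um) over time (minutes, t0 = 0)."""

    times: np.ndarray
    width: np.ndarray
    width0: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if self.times.shape != self.width.shape:
            raise InvalidTraceError("times and width must have equal length")
        if self.times.size == 0:
            raise InvalidTraceError("trace is empty")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidTraceError("times must be strictly increasing")
        if abs(self.times[0]) > 1e-12:
            raise InvalidTraceError("trace must start at t = 0")
        if self.width0 is None:
            self.width0 = float(self.width[0])
        if not self.width0 > 0:
            raise InvalidTraceError("initial width must be positive")
        finite = self.width[np.isfinite(self.width)]
        if finite.size and np.any(finite <= 0):
            raise InvalidTraceError("widths must be positive")


@dataclass
class ForceProfile:
    """Derived per-timepoint quantities for one sensor.

    ``strain`` is the % change of width (positive = compression), ``force``
    the inferred contact force (nN, sign follows strain), ``energy`` the
    cumulative stored elastic energy (pJ), ``valid`` flags points inside the
    +-20% linear strain range.  ``max_impulse_60`` is filled by
    :func:`max_impulse` when the trace is long enough.
    """

    times: np.ndarray
    strain: np.ndarray
    force: np.ndarray
    energy: np.ndarray
    valid: np.ndarray
    k: float
    max_impulse_60: float | None = None


@dataclass
class CohortSummary:
    """Per-timepoint mean force and 95% confidence band over embryos."""

    times: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray


def widths_to_strain(trace: DeformationTrace) -> np.ndarray:
    """Sensor strain (%) per timepoint: 100 (width0 - width) / width0.

    Positive for narrowing (tissue compression), negative for widening.
    """
    if not trace.width0 > 0:
        raise InvalidTraceError("width0 must be positive")
    return 100.0 * (trace.width0 - trace.width) / trace.width0


def strain_to_force(trace: DeformationTrace, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Force series F_i = k (width0 - width_i) and per-point validity flags.

    ``k`` is the sensor stiffness in nN/um.  Points whose strain magnitude
    exceeds the 20% linear range are returned but flagged invalid, mirroring
    how late, strongly-deformed timepoints should not be read as absolute
    forces.
    """
    if k <= 0:
        raise InvalidArgumentError("stiffness k must be positive")
    strain = widths_to_strain(trace)
    force = k * (trace.width0 - trace.width)
    valid = np.abs(strain) <= LINEAR_STRAIN_LIMIT_PCT
    return force, valid


def elastic_energy(force: np.ndarray, narrowing: np.ndarray) -> np.ndarray:
    """Cumulative stored elastic energy (pJ): trapezoidal area under the
    force-displacement path F(delta), converted from nN um (fJ) to pJ."""
    force = np.asarray(force, dtype=float)
    narrowing = np.asarray(narrowing, dtype=float)
    if force.shape != narrowing.shape:
        raise InvalidArgumentError("force and narrowing must have equal length")
    if force.size == 0:
        return np.zeros(0)
    increments = 0.5 * (force[1:] + force[:-1]) * np.diff(narrowing)
    return np.concatenate([[0.0], np.cumsum(increments)]) * PJ_PER_NN_UM


def infer_profile(trace: DeformationTrace, k: float) -> ForceProfile:
    """Full pipeline for one trace: strain, force, cumulative energy,
    validity flags, and the 60-min maximum impulse when computable."""
    strain = widths_to_strain(trace)
    force, valid = strain_to_force(trace, k)
    narrowing = trace.width0 - trace.width
    energy = elastic_energy(force, narrowing)
    profile = ForceProfile(times=trace.times.copy(), strain=strain,
                           force=force, energy=energy, valid=valid, k=k)
    if trace.times[-1] - trace.times[0] >= 60.0:
        profile.max_impulse_60 = max_impulse(profile)
    return profile


def max_impulse(profile: ForceProfile, window: float = 60.0,
                *, mode: str = "force_generated") -> float:
    """Maximum impulse (nN min) over all sliding windows of ``window`` min.

    The default reading of impulse is the force *generated* within the
    window multiplied by its duration: (F(t + w) - F(t)) * w, so a constant
    force carries zero impulse and the statistic summarizes the rate of
    force generation.  ``mode='mean_force'`` instead integrates |F| over the
    window (classical impulse), provided for comparison.
    """
    t = profile.times
    f = profile.force
    if t[-1] - t[0] < window:
        raise InsufficientDataError(
            f"trace spans {t[-1] - t[0]:g} min; need >= {window:g}")
    # evaluate on a dense grid so windows need not align with samples
    starts = t[t <= t[-1] - window]
    extra = np.setdiff1d(t[t >= t[0] + window] - window, starts)
    starts = np.sort(np.concatenate([starts, extra]))
    f_start = np.interp(starts, t, f)
    f_end = np.interp(starts + window, t, f)
    if mode == "force_generated":
        values = (f_end - f_start) * window
    elif mode == "mean_force":
        values = np.array([
            np.trapezoid(np.interp(
                np.linspace(s, s + window, 61), t, f),
                np.linspace(s, s + window, 61))
            for s in starts])
    else:
        raise InvalidArgumentError(f"unknown impulse mode {mode!r}")
    return float(np.max(values))


def atp_equivalent(energy_pj: float,
                   dG_per_molecule: float = ATP_DG_PER_MOLECULE_J) -> float:
    """Number of ATP molecules whose hydrolysis free energy equals the given
    elastic energy (pJ); 1 pJ is about 1e7 molecules at 1e-19 J each."""
    if energy_pj < 0:
        raise InvalidArgumentError("energy must be non-negative")
    if dG_per_molecule <= 0:
        raise InvalidArgumentError("dG per molecule must be positive")
    return energy_pj * 1e-12 / dG_per_molecule


def cohort_profile(profiles: list[ForceProfile],
                   time_grid: np.ndarray | None = None,
                   *, confidence: float = 0.95,
                   valid_only: bool = False) -> CohortSummary:
    """Mean force and t-distribution confidence band across embryos.

    Profiles are linearly interpolated onto the common grid; no profile is
    extrapolated beyond its own last timepoint, so n can vary along the
    grid.  Timepoints with a single contributing profile get NaN bounds and
    a warning.  ``valid_only`` drops points outside the linear strain range
    before interpolation.
    """
    if not profiles:
        raise InsufficientDataError("no profiles given")
    if time_grid is None:
        time_grid = profiles[0].times
    time_grid = np.asarray(time_grid, dtype=float)

    samples = np.full((len(profiles), time_grid.size), np.nan)
    for i, p in enumerate(profiles):
        t, f = p.times, p.force
        if valid_only:
            t, f = t[p.valid], f[p.valid]
        inside = (time_grid >= t[0]) & (time_grid <= t[-1])
        samples[i, inside] = np.interp(time_grid[inside], t, f)

    n = np.sum(np.isfinite(samples), axis=0)
    mean = np.full(time_grid.size, np.nan)
    lo = np.full(time_grid.size, np.nan)
    hi = np.full(time_grid.size, np.nan)
    warned = False
    for j in range(time_grid.size):
        col = samples[np.isfinite(samples[:, j]), j]
        if col.size == 0:
            continue
        mean[j] = col.mean()
        if col.size < 2:
            if not warned:
                warnings.warn(
                    "confidence interval omitted where only one profile "
                    "covers a timepoint", stacklevel=2)
                warned = True
            continue
        sem = col.std(ddof=1) / np.sqrt(col.size)
        tq = stats.t.ppf(0.5 + confidence / 2.0, col.size - 1)
        lo[j] = mean[j] - tq * sem
        hi[j] = mean[j] + tq * sem
    return CohortSummary(times=time_grid, mean=mean, ci_low=lo, ci_high=hi, n=n)


def compare_groups(a, b, *, test: str = "t") -> tuple[float, float]:
    """Two-sided comparison of two embryo-level samples.

    ``test='t'`` runs the equal-variance Student t-test (the default for
    normally distributed data of similar spread); ``test='mannwhitney'`` the
    Mann-Whitney U test for non-parametric data.  Returns (statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise InvalidArgumentError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
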