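"""Seeded generators for every input class the pipeline consumes.

These emulate the study's measurement situations without any wet-lab data:
saturating compression (and widening) trajectories of the sensor width,
embryo cohorts with inter-embryo variability, time-lapse movies of a
deforming autofluorescent annulus with drift and shot noise, and AFM
indentation curves from a pyramidal tip.  Every generator is a pure function
of its parameters and seed, and always returns the noise-free ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidArgumentError, InvalidRenderError
from .imaging import ImageStack
from .inference import DeformationTrace
from .materials import AFMCurve, hertz_forward

#: default printed sensor width (um), the representative cylinder diameter
DEFAULT_WIDTH0 = 180.0
#: default sensor stiffness (nN/um): parametric law at the representative
#: geometry (H=20, t=15, D=180 um) and E=80 kPa with alpha=7.718
DEFAULT_K = 7.15


@dataclass(frozen=True)
class TrajectoryParams:
    """Saturating-exponential strain history.

    ``s_max`` is the plateau strain in % of the printed width, ``tau`` the
    time constant in minutes (the pro-closure force builds over one to two
    hours), ``mode`` selects compression (narrowing) or widening traces,
    ``noise_sd`` the width measurement noise in um (about one pixel).
    """

    s_max: float = 8.0
    tau: float = 60.0
    mode: str = "compressive"
    noise_sd: float = 0.0
    seed: int | None = None
    profile: str = "saturating"    # or "piecewise_linear" for edge cases

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InvalidArgumentError("tau must be positive")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        if self.mode not in ("compressive", "widening"):
            raise InvalidArgumentError("mode must be compressive or widening")
        if self.profile not in ("saturating", "piecewise_linear"):
            raise InvalidArgumentError(
                "profile must be saturating or piecewise_linear")


@dataclass(frozen=True)
class CohortParams:
    """Cohort of n embryos; ``variability`` is the lognormal coefficient of
    variation applied multiplicatively to s_max and tau per embryo."""

    n: int = 10
    variability: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidArgumentError("cohort needs n >= 1")
        if self.variability < 0:
            raise InvalidArgumentError("variability must be non-negative")


def make_trajectory(params: TrajectoryParams, width0: float = DEFAULT_WIDTH0,
                    times: np.ndarray | None = None, *, k: float = DEFAULT_K):
    """Generate one width-versus-time trace plus its noise-free truth.

    The strain history is s(t) = s_max (1 - exp(-t/tau)) (sign set by
    ``mode``); widths follow from the strain definition, Gaussian width
    noise is added with the seed, and the ground-truth force k * narrowing
    is computed from the noise-free widths.

    Returns (trace, truth) where truth is a dict with the noise-free widths,
    strain (%), and force (nN).
    """
    if times is None:
        times = np.arange(0.0, 601.0, 30.0)
    times = np.asarray(times, dtype=float)
    if params.profile == "saturating":
        s = params.s_max * (1.0 - np.exp(-times / params.tau))
    else:
        s = np.minimum(params.s_max, params.s_max * times / (3.0 * params.tau))
    if params.mode == "widening":
        s = -s
    width_true = width0 * (1.0 - s / 100.0)
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd, times.size) \
        if params.noise_sd > 0 else np.zeros(times.size)
    width = width_true + noise
    # the measured t0 width defines width0 downstream; keep it exact so the
    # noise model perturbs deformation, not the reference state
    width[0] = width0
    trace = DeformationTrace(times=times, width=width, width0=width0)
    truth = {
        "width": width_true,
        "strain_pct": s,
        "force_nN": k * (width0 - width_true),
        "k": k,
    }
    return trace, truth


def make_cohort(params: CohortParams,
                trajectory: TrajectoryParams = TrajectoryParams(),
                width0: float = DEFAULT_WIDTH0,
                times: np.ndarray | None = None, *, k: float = DEFAULT_K):
    """Generate a cohort of traces with lognormal inter-embryo variability.

    Per-embryo s_max and tau are drawn as nominal * LogNormal(mu, sigma)
    with sigma from the requested coefficient of variation and mu = -s^2/2,
    so the multiplier has mean 1 and the cohort mean converges to the
    nominal trajectory.  Noise seeds are spawned deterministically from the
    cohort seed, making the whole cohort reproducible byte-for-byte.
    """
    rng = np.random.default_rng(params.seed)
    sigma = float(np.sqrt(np.log1p(params.variability ** 2)))
    traces, truths = [], []
    for i in range(params.n):
        if sigma > 0:
            mult_s = rng.lognormal(-sigma ** 2 / 2.0, sigma)
            mult_tau = rng.lognormal(-sigma ** 2 / 2.0, sigma)
        else:
            mult_s = mult_tau = 1.0
        child_seed = int(rng.integers(0, 2 ** 31 - 1))
        p = replace(trajectory, s_max=trajectory.s_max * mult_s,
                    tau=trajectory.tau * mult_tau, seed=child_seed)
        trace, truth = make_trajectory(p, width0=width0, times=times, k=k)
        traces.append(trace)
        truths.append(truth)
    return traces, truths


def render_movie(trace: DeformationTrace, *,
                 pixel_size: float = 0.59,
                 frame_shape: tuple[int, int] = (512, 512),
                 ring_thickness: float = 15.0,
                 blur_sigma_px: float = 1.0,
                 photons_peak: float = 200.0,
                 shot_noise: bool = True,
                 read_noise: float = 2.0,
                 drift_per_frame: tuple[float, float] = (0.0, 0.0),
                 bulge: float = 0.3,
                 seed: int | None = None):
    """Render a time-lapse of the deforming sensor annulus.

    Each frame draws an anti-aliased elliptical annulus whose x (mediolateral)
    outer extent equals the trace width; the y extent bulges by
    ``bulge * strain`` to mimic the contralateral elastic expansion of a
    compressed ring.  Frames are blurred (optics), scaled to ``photons_peak``
    and corrupted with Poisson shot noise plus Gaussian read noise; the frame
    center drifts by ``drift_per_frame`` px per frame.

    Returns (stack, truth) with truth holding the scripted widths (um) and
    per-frame drift offsets (px).
    """
    ny, nx = frame_shape
    times = trace.times
    widths = trace.width
    width0 = trace.width0
    if widths.size == 0:
        raise InvalidRenderError("trace has no frames")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    frames = np.empty((times.size, ny, nx), dtype=np.float32)
    offsets = []
    for i, w in enumerate(widths):
        strain = (width0 - w) / width0
        a_x = w / 2.0 / pixel_size                       # outer semi-axis, px
        a_y = width0 * (1.0 + bulge * strain) / 2.0 / pixel_size
        if 2 * a_x > nx - 4 or 2 * a_y > ny - 4:
            raise InvalidRenderError(
                f"sensor (frame {i}) does not fit the {frame_shape} frame")
        off = (drift_per_frame[0] * i, drift_per_frame[1] * i)
        offsets.append(off)
        cx = nx / 2.0 + off[0]
        cy = ny / 2.0 + off[1]
        rho = np.sqrt(((xx - cx) / a_x) ** 2 + ((yy - cy) / a_y) ** 2)
        # radial distance from the wall band edges in px (approximate local
        # scaling by the mean semi-axis keeps the anti-aliasing isotropic)
        scale = 0.5 * (a_x + a_y)
        half_band = ring_thickness / 2.0 / pixel_size
        r_mid = 1.0 - half_band / scale
        band = np.abs(rho - r_mid) * scale - half_band
        img = np.clip(0.5 - band, 0.0, 1.0)              # 1 px soft edge
        if blur_sigma_px > 0:
            img = gaussian_filter(img, blur_sigma_px)
        img *= photons_peak
        noisy = (rng.poisson(img).astype(np.float32) if shot_noise
                 else img.astype(np.float32))
        if read_noise > 0:
            noisy += rng.normal(0.0, read_noise, img.shape).astype(np.float32)
        frames[i] = np.clip(noisy, 0.0, None)
    stack = ImageStack(frames=frames, pixel_size=pixel_size,
                       time_step=float(times[1] - times[0]) if times.size > 1
                       else 30.0)
    truth = {"width": widths.copy(), "offsets_px": np.asarray(offsets),
             "width0": width0}
    return stack, truth


def make_afm_curve(E: float = 80.0, theta: float = 20.0,
                   contact_point: float = 0.0, *,
                   max_depth: float = 2.0, n_points: int = 200,
                   noise: float = 0.0, nu: float = 0.5,
                   spring_constant: float = 0.2,
                   seed: int | None = None):
    """Synthesize one AFM indentation curve from the pyramidal contact model.

    ``noise`` is the multiplicative force noise level (e.g. 0.01 for 1%),
    applied relative to the maximum force, plus the same amount as additive
    baseline noise so the pre-contact segment is realistically non-flat.
    Returns (curve, truth) with truth = {'E': ..., 'contact_point': ...}.
    """
    if E <= 0:
        raise InvalidArgumentError("E must be positive")
    depth = np.linspace(0.0, max_depth, n_points)
    force = hertz_forward(depth, E, theta, contact_point=contact_point, nu=nu)
    rng = np.random.default_rng(seed)
    if noise > 0:
        level = noise * float(force.max())
        force = force + rng.normal(0.0, level, force.shape)
    curve = AFMCurve(depth=depth, force=force, tip_half_angle=theta,
                     spring_constant=spring_constant)
    truth = {"E": E, "contact_point": contact_point, "theta": theta}
    return curve, truth
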