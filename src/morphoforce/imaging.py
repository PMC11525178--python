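"""Width measurement from time-lapse images of the sensor.

The sensor autofluoresces, so a single channel suffices: frames are
registered against the first frame (stage drift), the sensor segmented by
global thresholding, and its mediolateral width read off the bounding
rectangle of the largest connected component — the same bounding-rectangle
measurement an operator would perform, automated.  Convention: image x is
the mediolateral axis, y rostrocaudal; 3D stacks are maximum-projected on
load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate

from .errors import (
    InvalidArgumentError,
    NoDetectionError,
    RegistrationError,
)
from .inference import DeformationTrace


@dataclass
class ImageStack:
    """Time-lapse intensity stack: frames (T, H, W), pixel size (um/px) and
    time step (minutes).  Image x = mediolateral."""

    frames: np.ndarray
    pixel_size: float
    time_step: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidArgumentError("frames must be a (T, H, W) array, T >= 1")
        if not self.pixel_size > 0:
            raise InvalidArgumentError("pixel_size must be positive")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise InvalidArgumentError("intensities must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def load_stack(path, pixel_size: float, time_step: float = 30.0) -> ImageStack:
    """Read a (multi-page) TIFF; z-stacks (T, Z, Y, X) are max-projected."""
    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 4:
        arr = arr.max(axis=1)
    return ImageStack(frames=arr, pixel_size=pixel_size, time_step=time_step)


@dataclass
class SensorMask:
    """Binary sensor mask for one frame with its bounding rectangle
    (x_min, x_max, y_min, y_max) in px, inclusive."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def register_stack(stack: ImageStack, mode: str = "translation",
                   *, upsample: int = 20):
    """Align every frame to the first by intensity cross-correlation.

    ``mode='translation'`` estimates subpixel (dy, dx) shifts by phase
    correlation; ``mode='rigid'`` additionally searches a small rotation
    range by maximizing the correlation peak.  Returns (registered stack,
    offsets) where offsets[i] = (dy, dx[, angle_deg]) found for frame i.
    """
    if mode not in ("translation", "rigid"):
        raise InvalidArgumentError("mode must be translation or rigid")
    if stack.n_frames == 1:
        return stack, []
    ref = stack.frames[0]
    if float(ref.std()) == 0.0:
        raise RegistrationError("reference frame has zero variance")
    out = np.empty_like(stack.frames)
    out[0] = ref
    offsets = []
    for i in range(1, stack.n_frames):
        frame = stack.frames[i]
        if float(frame.std()) == 0.0:
            raise RegistrationError(f"frame {i} has zero variance")
        best_angle = 0.0
        moving = frame
        if mode == "rigid":
            best = -np.inf
            for angle in np.linspace(-5.0, 5.0, 21):
                cand = rotate(frame, angle, preserve_range=True)
                _, err, _ = phase_cross_correlation(ref, cand,
                                                    upsample_factor=4)
                score = -err
                if score > best:
                    best, best_angle = score, angle
            moving = rotate(frame, best_angle, preserve_range=True)
        shift, _, _ = phase_cross_correlation(ref, moving,
                                              upsample_factor=upsample)
        aligned = ndimage.shift(moving, shift, order=1, mode="nearest")
        out[i] = aligned
        if mode == "rigid":
            offsets.append((float(shift[0]), float(shift[1]), best_angle))
        else:
            offsets.append((float(shift[0]), float(shift[1])))
    return ImageStack(frames=out, pixel_size=stack.pixel_size,
                      time_step=stack.time_step), offsets


def segment_sensor(frame: np.ndarray, method: str = "otsu",
                   threshold: float | None = None,
                   *, closing_radius: int = 2) -> SensorMask:
    """Segment the sensor in one frame.

    Global threshold (Otsu by default, or a fixed value), morphological
    closing, largest connected component, hole filling.  Raises
    ``NoDetectionError`` when nothing survives.
    """
    frame = np.asarray(frame, dtype=float)
    if float(frame.std()) == 0.0:
        raise NoDetectionError("frame is constant; nothing to segment")
    if method == "otsu":
        thr = threshold_otsu(frame)
    elif method == "fixed":
        if threshold is None:
            raise InvalidArgumentError("fixed method needs a threshold")
        thr = threshold
    else:
        raise InvalidArgumentError("method must be otsu or fixed")
    binary = frame > thr
    if closing_radius > 0:
        binary = closing(binary, disk(closing_radius))
    labels = label(binary)
    if labels.max() == 0:
        raise NoDetectionError("empty mask after thresholding")
    props = regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    mask = labels == largest.label
    mask = ndimage.binary_fill_holes(mask)
    ys, xs = np.nonzero(mask)
    bbox = (int(xs.min()), int(xs.max()), int(ys.min()), int(ys.max()))
    return SensorMask(mask=mask, bbox=bbox)


def measure_width(mask: SensorMask, pixel_size: float) -> float:
    """Mediolateral width (um): bounding-rectangle x extent times pixel size."""
    if mask.is_empty:
        raise NoDetectionError("empty mask")
    x_min, x_max, _, _ = mask.bbox
    return (x_max - x_min + 1) * pixel_size


def extract_trace(stack: ImageStack, *, register: bool = True,
                  mode: str = "translation",
                  segmentation: str = "otsu") -> DeformationTrace:
    """Image stack -> deformation trace: register, segment and measure each
    frame; width0 is the frame-0 width and times come from the time step.

    Frames without a detection are flagged as gaps (NaN width), never
    interpolated.
    """
    if stack.n_frames == 0:
        raise InvalidArgumentError("empty stack")
    work = stack
    if register and stack.n_frames > 1:
        work, _ = register_stack(stack, mode=mode)
    widths = np.empty(work.n_frames)
    for i in range(work.n_frames):
        try:
            mask = segment_sensor(work.frames[i], method=segmentation)
            widths[i] = measure_width(mask, work.pixel_size)
        except NoDetectionError:
            widths[i] = np.nan
    if not np.isfinite(widths[0]):
        raise NoDetectionError("no detection in the reference frame")
    times = np.arange(work.n_frames) * stack.time_step
    return DeformationTrace(times=times, width=widths, width0=float(widths[0]))
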