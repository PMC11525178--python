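"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`MorphoForceError`
so callers (and the CLI) can distinguish bad input from solver breakdown.
"""


class MorphoForceError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MorphoForceError, ValueError):
    """A scalar argument is outside its physical domain (e.g. E <= 0)."""


class UnsupportedConfigurationError(MorphoForceError):
    """A closed form or mode is requested outside its validity (e.g. nu != 0.5)."""


class InsufficientDataError(MorphoForceError):
    """Too few data points to perform the requested fit or measurement."""


class DegenerateCurveError(MorphoForceError):
    """A curve carries no usable signal (e.g. identically zero force)."""


class ConvergenceError(MorphoForceError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, *, step: int | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.step = step
        self.residual = residual


class ContactResolutionError(MorphoForceError):
    """Penalty contact left penetration beyond tolerance."""


class InvalidGeometryError(MorphoForceError, ValueError):
    """Geometric parameters are inconsistent (e.g. wall thicker than radius)."""


class RegistrationError(MorphoForceError):
    """Image registration cannot proceed (e.g. featureless frames)."""


class NoDetectionError(MorphoForceError):
    """Segmentation produced an empty mask."""


class InvalidTraceError(MorphoForceError, ValueError):
    """A deformation trace violates its invariants."""


class InvalidRenderError(MorphoForceError, ValueError):
    """Synthetic rendering parameters do not fit the frame."""


class ConfigError(MorphoForceError, ValueError):
    """A run configuration file is malformed or has unknown keys."""
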