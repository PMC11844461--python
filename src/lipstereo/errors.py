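"""Exception hierarchy for the lipstereo pipeline.

Every error raised by the package derives from :class:`LipStereoError`, so
callers can catch pipeline failures without masking programming errors.
"""


class LipStereoError(Exception):
    """Base class for all lipstereo errors."""


class InvalidModelError(LipStereoError):
    """A camera model or rig violates its invariants (non-finite parameters,
    non-orthonormal rotation, non-positive focal lengths, ...)."""


class BehindCameraError(LipStereoError):
    """A 3D point has non-positive depth in a camera frame and cannot be
    projected."""


class ConvergenceError(LipStereoError):
    """An iterative routine (distortion inversion) failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateGeometryError(LipStereoError):
    """A geometric estimation problem is rank-deficient: coplanar resection
    correspondences, a zero-baseline rig, or a point at infinity during
    triangulation."""


class NoClapFoundError(LipStereoError):
    """No audio sample reached the clap detection threshold."""

    def __init__(self, message: str, max_amplitude: float | None = None):
        super().__init__(message)
        self.max_amplitude = max_amplitude


class AlignmentError(LipStereoError):
    """Temporal alignment could not be performed (insufficient overlap,
    empty series, too few closure minima)."""


class ParseError(LipStereoError):
    """A pipeline input file is malformed. Carries the file and, where
    meaningful, the 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc += ": "
        super().__init__(loc + message)
        self.path = path
        self.line = line
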