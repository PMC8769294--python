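"""Exception types shared across the package."""


class ViatraceError(Exception):
    """Base class for package errors."""


class InvalidInputError(ViatraceError, ValueError):
    """A contract violation in user-supplied data or parameters."""


class DegenerateReferenceError(ViatraceError):
    """Blank and dark references coincide at one or more pixels.

    A pixel where ``Imax <= Imin`` carries no usable dynamic range and
    indicates a broken reference pair (wrong file, saturated dark frame,
    dead sensor region), so conversion refuses rather than emitting NaN.
    """

    def __init__(self, n_bad_pixels: int):
        self.n_bad_pixels = int(n_bad_pixels)
        super().__init__(
            f"blank reference <= dark reference at {self.n_bad_pixels} pixel(s)"
        )


class UnsupportedFormatError(ViatraceError):
    """Image file is not a single-plane 8/16-bit grayscale TIFF."""


class DegenerateDistributionsError(ViatraceError):
    """Live and dead value distributions are not separable enough to threshold."""


class GenerationError(ViatraceError):
    """Synthetic phantom could not be generated under its constraints."""


class PipelineError(ViatraceError):
    """A pipeline stage failed; the message names the stage."""
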