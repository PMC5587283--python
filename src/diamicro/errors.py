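"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`DiamicroError`
so callers (and the pipeline driver) can distinguish analysis failures from
programming errors.
"""


class DiamicroError(Exception):
    """Base class for all package errors."""


class CalibrationError(DiamicroError):
    """Pixel-size / Nyquist violation (e.g. requested period <= 2 pixels)."""


class DegenerateInputError(DiamicroError):
    """Input carries no usable signal (constant image, empty profile...)."""


class NoEstimateError(DiamicroError):
    """No spectral/autocorrelation peak rises above the noise floor."""


class OutOfBandError(DiamicroError):
    """The dominant periodicity lies outside the physiological band."""


class InsufficientSamplingError(DiamicroError):
    """A reference line crosses too few fibers to measure widths."""


class SegmentationError(DiamicroError):
    """Fiber segmentation found no closed interiors."""


class PackingError(DiamicroError):
    """Requested fibers cannot tile the field at the requested mean area."""


class RegistrationError(DiamicroError):
    """Channel shapes disagree; channels are not pixel-registered."""


class ConfigurationError(DiamicroError):
    """Invalid or incomplete run configuration / cohort specification."""
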