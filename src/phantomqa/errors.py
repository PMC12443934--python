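"""Exception hierarchy.

Exit-code contract used by the CLI: validation/configuration problems exit 2,
detection problems exit 3, file-format and I/O problems exit 4.
"""


class PhantomQAError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(PhantomQAError):
    """Invalid parameter, type invariant violation, or precondition failure."""

    exit_code = 2


class CapacityError(ValidationError):
    """Sample layout exceeds the capacity of the selected plate."""


class GeometryError(ValidationError):
    """Physically impossible geometry (overlap, containment violation)."""


class UsageError(ValidationError):
    """Operation called with an incompatible object (e.g. wrong sequence family)."""


class ConfigurationError(ValidationError):
    """Bad run configuration, e.g. a non-invertible distortion field."""


class InsufficientDataError(ValidationError):
    """Not enough inputs to compute the requested quantity."""


class UndefinedSNRError(ValidationError):
    """Noise standard deviation is zero; the SNR ratio is undefined."""


class DetectionError(PhantomQAError):
    """Vial/ROI detection failure."""

    exit_code = 3


class NoContrastError(DetectionError):
    """Image has no contrast to threshold."""


class DetectionShortfallError(DetectionError):
    """Fewer vial candidates found than expected."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(
            f"detection shortfall: found {found} vial candidate(s), expected {expected}"
        )


class PlacementError(DetectionError):
    """Automatic region placement failed; supply manual regions instead."""


class FormatError(PhantomQAError):
    """Unreadable or underspecified image file."""

    exit_code = 4


class UnsupportedInputError(FormatError):
    """Recognised but unsupported input (e.g. multi-frame DICOM series)."""
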