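"""Typed exceptions shared across the package.

Missing data in a cohort is a fact of life, not a crash: operations that hit
an absent file or value raise :class:`MissingDataError` (or return a flagged
result) so callers can count and skip, while genuine misuse raises one of the
hard error types below.
"""


class BraincohortError(Exception):
    """Base class for all package errors."""


class ValidationError(BraincohortError, ValueError):
    """Input violates an operation precondition (non-finite point, r <= 0...)."""


class SpaceMismatchError(BraincohortError):
    """Objects live in different coordinate spaces, or a transform chain
    cannot be built between the requested spaces."""


class NonInvertibleError(BraincohortError):
    """Affine linear block is singular (|det| below tolerance)."""


class OutOfBoundsError(BraincohortError):
    """A point falls outside a warp grid or image; message names the index."""


class FormatError(BraincohortError):
    """A file exists but cannot be parsed in its declared dialect."""


class UnsupportedFormatError(FormatError):
    """File extension does not select a known dialect."""


class MissingDataError(BraincohortError):
    """Requested per-subject data is absent.

    This is the soft, expected signal of an incomplete cohort: catch it,
    flag the subject, continue.  Distinct from :class:`FormatError` (file
    present but broken) and :class:`ConfigurationError` (project misconfigured).
    """

    def __init__(self, message: str, subject_id: str | None = None,
                 data_type: str | None = None):
        super().__init__(message)
        self.subject_id = subject_id
        self.data_type = data_type


class EmptyRegionError(BraincohortError):
    """A sampling region contains no voxels/points; returned instead of NaN."""


class ConfigurationError(BraincohortError):
    """Project layout or generator configuration is unusable."""


class ParseError(BraincohortError):
    """Bundle-expression text is malformed; carries the failing position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownReferenceError(BraincohortError):
    """A bundle-expression leaf names no structure or ROI in the context."""


class CollinearityError(BraincohortError):
    """Design matrix is rank deficient; message names the aliased terms."""


class DegenerateDesignError(BraincohortError):
    """An exclusion or filter emptied a nominal level / the whole design."""


class NotFoundError(BraincohortError, KeyError):
    """A database id (variable, sample, scenario) does not exist."""
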