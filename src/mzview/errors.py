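"""Exception and warning hierarchy for mzview.

All library errors derive from :class:`MzViewError` so callers can catch one
base class; warnings derive from :class:`MzViewWarning`.
"""

from __future__ import annotations


class MzViewError(Exception):
    """Base class for all mzview errors."""


class MalformedSpectrumError(MzViewError):
    """A spectrum/scan fragment violates structural expectations
    (mismatched array lengths, missing m/z or intensity array, ...)."""


class CodecError(MzViewError):
    """Binary peak-array decoding failed (bad base64, zlib inflate failure)."""


class TruncationError(CodecError):
    """Decoded byte count is not a multiple of the element size."""


class MalformedPeaksError(MzViewError):
    """Interleaved peak array has an odd element count."""


class UnsupportedFormatError(MzViewError):
    """Root element is not mzML/indexedmzML/mzXML.

    Attributes
    ----------
    root : str or None
        Local name of the document root that was found, if any.
    """

    def __init__(self, message: str, root: str | None = None):
        super().__init__(message)
        self.root = root


class FormatParseError(MzViewError):
    """File content is not parseable XML at all."""


class IndexIncompleteError(MzViewError):
    """The streaming index pass hit truncated XML.

    Carries the partial index built so far in ``partial_index``.
    """

    def __init__(self, message: str, partial_index=None, run_metadata=None):
        super().__init__(message)
        self.partial_index = partial_index
        self.run_metadata = run_metadata


class ScanNotFoundError(MzViewError, KeyError):
    """Requested scan id is not in the index.

    ``suggestions`` lists the nearest known scan ids.
    """

    def __init__(self, message: str, suggestions: list[str] | None = None):
        super().__init__(message)
        self.suggestions = suggestions or []

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return self.args[0]


class CorruptScanError(MzViewError):
    """A scan fragment failed to parse or decode.

    Carries the byte span of the offending fragment.
    """

    def __init__(self, message: str, byte_start: int | None = None,
                 byte_end: int | None = None):
        super().__init__(message)
        self.byte_start = byte_start
        self.byte_end = byte_end


class PrecursorCycleError(MzViewError):
    """Precursor references form a cycle; names the repeated scan."""

    def __init__(self, message: str, scan_id: str | None = None):
        super().__init__(message)
        self.scan_id = scan_id


class MalformedChromatogramError(MzViewError):
    """Chromatogram time/intensity arrays have mismatched lengths."""


class MzViewWarning(UserWarning):
    """Base class for mzview warnings."""


class LengthMismatchWarning(MzViewWarning):
    """Decoded array length differs from the file-declared length."""


class DialectWarning(MzViewWarning):
    """The file's embedded offset table disagrees with actual content;
    the streaming index is used instead."""


class ContradictionWarning(MzViewWarning):
    """Filter criteria are self-contradictory (e.g. selected-ion m/z with
    ms_level=1); the result is empty by construction."""


class NonFiniteDataWarning(MzViewWarning):
    """Decoded arrays contain NaN or infinite values (preserved as-is)."""
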