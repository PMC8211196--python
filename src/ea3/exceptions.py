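"""Exception hierarchy.

Everything raised by this package derives from :class:`EA3Error`, so callers
can catch one type at the CLI boundary.  The finer-grained classes distinguish
shape problems (:class:`DimensionError`), inadmissible parameter values
(:class:`ParameterError`), out-of-range or malformed data
(:class:`AppraisalValidationError`), evidence models that assign the observed
evidence probability zero under every hypothesis
(:class:`DegenerateEvidenceError`), and malformed input files
(:class:`FormatError`).
"""


class EA3Error(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(EA3Error):
    """Vector lengths are incompatible or below the minimum of two."""


class ParameterError(EA3Error):
    """A scalar parameter (typically the cautiousness beta) is inadmissible."""


class AppraisalValidationError(EA3Error):
    """An input value is non-finite, out of range, or structurally invalid."""


class DegenerateEvidenceError(EA3Error):
    """The evidence model gives the observed evidence zero probability."""


class FormatError(EA3Error):
    """An input file does not conform to the expected layout."""
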