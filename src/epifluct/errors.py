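"""Exception hierarchy for the epifluct pipeline.

All errors raised by the package derive from :class:`EpifluctError` so callers
can catch pipeline failures without masking programming errors.
"""


class EpifluctError(Exception):
    """Base class for all epifluct errors."""


class InvalidArgumentError(EpifluctError, ValueError):
    """An argument violates a documented precondition."""


class MissingProbeError(EpifluctError, KeyError):
    """Clock or reference CpGs are absent from the probe universe."""

    def __init__(self, missing, context=""):
        self.missing = sorted(missing)
        msg = f"{len(self.missing)} probe(s) missing"
        if context:
            msg += f" ({context})"
        msg += ": " + ", ".join(self.missing[:10])
        if len(self.missing) > 10:
            msg += ", ..."
        super().__init__(msg)


class FormatError(EpifluctError, ValueError):
    """A file does not conform to its expected tabular format."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DataError(EpifluctError, ValueError):
    """Input data contain invalid values (non-finite, out of range)."""


class InsufficientDataError(EpifluctError, ValueError):
    """Too few observations for the requested computation."""


class DegenerateInputError(EpifluctError, ValueError):
    """Input has no usable variation (e.g. all values identical)."""


class AnnotationError(EpifluctError, ValueError):
    """Probe annotations are missing or inconsistent."""


class CoverageError(EpifluctError, ValueError):
    """A reference does not cover enough of the requested probes."""


class OrderingError(EpifluctError, ValueError):
    """Collection days are not strictly increasing within a series."""


class PairingError(EpifluctError, ValueError):
    """Two tables that must match series-by-series do not."""


class ReconciliationError(EpifluctError, ValueError):
    """Sample sheet and beta matrix disagree about the sample set."""
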