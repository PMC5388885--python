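"""Exception hierarchy shared across the toolkit."""


class BarcodekitError(Exception):
    """Base class for all toolkit errors."""


class FastqParseError(BarcodekitError):
    """A FASTQ record could not be parsed (e.g. base/quality length mismatch)."""


class FastaHeaderError(BarcodekitError):
    """A FASTA header does not follow the ``species|specimen_id|locus`` dialect."""


class InsufficientCoverageError(BarcodekitError):
    """Too few reads to build a consensus at the requested minimum coverage."""

    def __init__(self, message: str, direction: str | None = None):
        super().__init__(message)
        self.direction = direction


class MergeError(BarcodekitError):
    """No forward/reverse overlap satisfied the merge criteria."""


class AmbiguousDirectionError(BarcodekitError):
    """A read prefix matches both the forward and the reverse primer."""


class SeedFailureError(BarcodekitError):
    """No read starts with the forward primer; micro-assembly cannot seed."""


class TrimFailureError(BarcodekitError):
    """A primer was not found at the expected terminus of an assembled profile.

    Carries the untrimmed profile so callers can still inspect the assembly.
    """

    def __init__(self, message: str, profile=None):
        super().__init__(message)
        self.profile = profile


class CRBBuildError(BarcodekitError):
    """Invalid input while building a comprehensive reference barcode database."""
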