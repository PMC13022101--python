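"""Exception hierarchy shared across the package."""


class RmsxError(Exception):
    """Base class for all package errors."""


class FormatError(RmsxError):
    """A file could not be read in the expected format."""


class AtomCountMismatchError(RmsxError):
    """Structure and trajectory disagree on the number of atoms."""


class EmptySelectionError(RmsxError):
    """An atom predicate resolved to no atoms where atoms are required."""


class SlicingError(RmsxError):
    """An invalid partition of the frame range was requested."""


class DegenerateInputError(RmsxError):
    """Input geometry or series is too degenerate for the operation."""
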