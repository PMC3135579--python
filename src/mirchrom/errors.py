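"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2, DataError -> 3.
"""


class MirchromError(Exception):
    """Base class for all package errors."""


class ValidationError(MirchromError):
    """Invalid value, coordinate or configuration supplied by the caller."""


class DataError(MirchromError):
    """Malformed or inconsistent input data encountered while parsing."""
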