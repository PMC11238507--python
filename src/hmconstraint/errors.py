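"""Exception hierarchy.

Two broad classes matter to callers: :class:`DataError` (bad or missing
input data; CLI exit code 1) and :class:`ConfigError` (invalid
configuration; CLI exit code 2).
"""


class HmcError(Exception):
    """Base class for all package errors."""


class DataError(HmcError):
    """Input data is malformed, inconsistent or missing."""


class ConfigError(HmcError):
    """Run configuration is invalid."""


class FormatError(DataError):
    """A file does not conform to its declared format (e.g. ragged alignment)."""


class MemberError(DataError):
    """An alignment row has an unparseable or inconsistent member header."""


class EmptyInputError(DataError):
    """A required input is empty."""


class CompletenessError(DataError):
    """A lookup table is missing required entries."""


class CalibrationError(DataError):
    """The neutral-expectation model cannot be calibrated."""


class ModelError(DataError):
    """A transcript model violates its structural invariants."""
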