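"""Exception hierarchy.

Contract violations (bad arguments, shape mismatches, invalid
configuration) raise :class:`ContractError`; unreadable or malformed
files raise :class:`FormatError`.  The CLI maps these to exit codes
2 and 3 respectively.
"""


class CordmapError(Exception):
    """Base class for all package errors."""


class ContractError(CordmapError, ValueError):
    """A precondition on inputs or configuration was violated."""


class ConfigurationError(ContractError):
    """An invalid phantom or run configuration."""


class InsufficientDataError(ContractError):
    """Not enough data to perform the operation (e.g. < 2 cardiac peaks)."""


class EmptySelectionError(CordmapError, RuntimeError):
    """A selection step retained nothing (e.g. no significant frames)."""


class FormatError(CordmapError, RuntimeError):
    """A file could not be parsed as the expected format."""
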