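"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`TargetExpressError`, so callers (and the CLI) can distinguish
expected failures from bugs.
"""


class TargetExpressError(Exception):
    """Base class for all package errors."""


class FormatError(TargetExpressError, ValueError):
    """A file does not conform to the expected tabular/FASTA layout."""


class ValidationError(TargetExpressError, ValueError):
    """Parsed values violate a domain invariant (e.g. FDR outside [0, 1])."""


class DomainError(TargetExpressError, ValueError):
    """Arguments outside the mathematical domain of an operation."""


class EmptyResultError(TargetExpressError, ValueError):
    """A filter or query removed every row; the message names the filter."""


class ConfigError(TargetExpressError, ValueError):
    """An invalid combination of configuration options."""


class ContractError(TargetExpressError, ValueError):
    """Mismatch between fitted-model metadata and the data offered to it."""


class ModelIOError(TargetExpressError, ValueError):
    """A persisted model file is unreadable, truncated or incompatible."""
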