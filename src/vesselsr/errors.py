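"""Exception hierarchy shared across the package.

Distinct classes exist so the command-line layer can map them to distinct
exit codes (config vs I/O vs contract violations).
"""


class VesselSRError(Exception):
    """Base class for all package errors."""


class ContractError(VesselSRError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class ConfigError(VesselSRError, ValueError):
    """A configuration object or file is invalid."""


class IOFailure(VesselSRError, OSError):
    """A file could not be read or written."""
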