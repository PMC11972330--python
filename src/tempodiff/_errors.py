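"""Exception hierarchy.

Exit-code mapping used by the CLI: DataError / DesignError / ParseError /
ConfigError are usage-or-input problems (exit 2); any other failure is a
computational error (exit 1).
"""


class TempodiffError(Exception):
    """Base class for all package errors."""


class DataError(TempodiffError):
    """Input values violate a data contract (negative counts, bad lengths, ...)."""


class DesignError(TempodiffError):
    """Experimental design is unusable (condition/timepoint coverage mismatch)."""


class ParseError(TempodiffError):
    """A file could not be parsed; message carries a 1-based line reference."""


class ConfigError(TempodiffError):
    """Invalid configuration (unknown metric, bad alpha, inconsistent sizes)."""
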