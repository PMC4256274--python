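"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`SlipscanError`,
so the CLI can translate any of them into a one-line diagnostic and a
non-zero exit code.
"""


class SlipscanError(Exception):
    """Base class for all slipscan errors."""


class InputError(SlipscanError, ValueError):
    """Invalid value passed to an operation (bad alphabet, out-of-range edit, ...)."""


class FormatError(SlipscanError, ValueError):
    """Malformed input file (FASTA without headers, empty file, bad table)."""


class ConfigError(SlipscanError, ValueError):
    """Invalid or insufficient configuration (empty ladder, tiny family, ...)."""


class EstimateError(SlipscanError, ValueError):
    """A frequency estimate is undefined for the given measurements."""


class GenerationError(SlipscanError, RuntimeError):
    """The synthetic-gene designer could not satisfy its invariants."""
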