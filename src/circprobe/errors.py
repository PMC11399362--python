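"""Exception hierarchy.

Every error the library raises derives from :class:`CircprobeError` and
carries an ``exit_code`` so the CLI can map failure classes to distinct
process exit statuses (0 success, 2 bad input/config, 3 design failure).
"""


class CircprobeError(Exception):
    """Base class for all circprobe errors."""

    exit_code = 1


class InputError(CircprobeError, ValueError):
    """Malformed or unusable user input (sequences, files, arguments)."""

    exit_code = 2


class AlphabetError(InputError):
    """A sequence contains characters outside the A/C/G/T alphabet."""


class KmerLengthError(InputError):
    """A k-mer string has the wrong length for the fixed k."""


class CodeRangeError(InputError):
    """An integer k-mer code lies outside [0, 4**k)."""


class ConfigError(CircprobeError, ValueError):
    """Invalid configuration: bad thresholds, unknown keys, bad backend."""

    exit_code = 2


class IndexFormatError(CircprobeError):
    """An index file does not carry the expected magic/version header."""

    exit_code = 2


class IndexCorruptionError(IndexFormatError):
    """An index file header parses but the bitmap body is truncated."""


class FixtureSpecError(ConfigError):
    """A synthetic-fixture request is infeasible (e.g. too many plants)."""


class DesignFailure(CircprobeError):
    """No probe satisfying all constraints exists for the given input."""

    exit_code = 3
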