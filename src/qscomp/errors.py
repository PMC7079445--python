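"""Exception hierarchy shared by all qscomp modules.

Exit-code mapping used by the CLI: usage errors -> 1, format/validation
errors -> 2, corruption errors -> 3.
"""


class QscompError(Exception):
    """Base class for all qscomp errors."""


class ValidationError(QscompError):
    """Input bytes violate the quality-score contract (ASCII 33..104)."""


class FormatError(QscompError):
    """Structurally malformed input file (FASTQ structure, bad container)."""


class CorruptionError(QscompError):
    """A container section failed an integrity check during decode."""


class RangeError(QscompError):
    """A requested line range lies outside the stored line count."""


class ParameterError(QscompError):
    """Invalid configuration or algorithm parameter."""
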