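"""Exception hierarchy.

``ValidationError`` marks bad user input (missing files, malformed
annotations, grid mismatches) and maps to exit code 2 in the CLI;
every other :class:`ReplichipError` maps to exit code 1.
"""


class ReplichipError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ReplichipError):
    """Invalid input data or configuration."""
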