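"""Exception hierarchy.

``ValidationError`` covers invalid parameters or data contents (CLI exit
code 2); ``InputError`` covers unreadable or malformed files (exit code 3).
"""


class StonectError(Exception):
    """Base class for all package errors."""


class ValidationError(StonectError, ValueError):
    """Invalid argument, configuration, or data content."""


class InputError(StonectError, OSError):
    """Missing, unreadable, or malformed input file."""
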