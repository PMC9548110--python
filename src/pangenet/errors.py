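"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/format/usage problems exit
with 1, anything unexpected exits with 2.
"""


class PangenetError(Exception):
    """Base class for all errors raised deliberately by pangenet."""


class ValidationError(PangenetError):
    """Input data violates a documented invariant."""


class FormatError(PangenetError):
    """A file could not be parsed under the requested dialect."""


class UsageError(PangenetError):
    """An argument value is outside the supported domain."""
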