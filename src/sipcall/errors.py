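"""Exception hierarchy shared by all pipeline stages.

Two failure families are distinguished because the CLI maps them to
different exit codes: malformed input (exit 2) versus inputs that are
well-formed but make the labeling statistic undefined (exit 3).
"""


class SipcallError(Exception):
    """Base class for all package errors."""


class ValidationError(SipcallError):
    """Input violates a format or invariant contract (CLI exit code 2)."""


class UndefinedStatisticError(SipcallError):
    """A required statistic cannot be formed, e.g. a bottle with no heavy
    fractions, so no odds ratio exists (CLI exit code 3)."""
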