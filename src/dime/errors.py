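"""Exception hierarchy shared across the package."""


class DimeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DimeError, ValueError):
    """An input artifact violates its format contract (bad value, missing
    column, duplicate identifier, ...). The message names the offending
    symbol / coordinate where possible."""


class UsageError(DimeError, ValueError):
    """The caller asked for something unsupported (unknown dialect, k out of
    range, infeasible configuration)."""
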