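"""Exception hierarchy for pvdispro.

Every error raised on purpose by the package derives from
:class:`PvDisproError`, so callers (including the CLI) can catch one type.
"""


class PvDisproError(Exception):
    """Base class for all pvdispro errors."""


class InputError(PvDisproError, ValueError):
    """An argument violated a precondition (empty identifier, bad value)."""


class FormatError(PvDisproError, ValueError):
    """A file did not match the declared schema (missing column, bad row)."""


class ConsistencyError(PvDisproError, ValueError):
    """Counts violate an aggregate invariant (e.g. n_adrs < sum of parts)."""


class LookupError_(PvDisproError, KeyError):
    """A requested drug is absent from the dataset or aggregate collection."""


class UndefinedRatioError(PvDisproError, ZeroDivisionError):
    """A descriptive ratio was requested with a zero denominator."""


class SpecError(PvDisproError, ValueError):
    """A synthetic-data specification is infeasible or inconsistent."""


class UsageError(PvDisproError, ValueError):
    """An operation was invoked in a way that makes no sense (e.g. a drug
    compared against itself)."""
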