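"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`MlcpsError`,
so callers (and the CLI) can catch one type. Subclasses also derive from the
closest builtin (`ValueError`) so untargeted handling stays idiomatic.
"""


class MlcpsError(Exception):
    """Base class for all errors raised by mlcps."""


class InvalidMetricsError(MlcpsError, ValueError):
    """A metric vector, weight vector or argument violates its contract."""


class DegenerateGeometryError(MlcpsError, ValueError):
    """Fewer than three effective metrics: no polygon can be formed."""


class UndefinedMetricError(MlcpsError, ValueError):
    """A requested metric has an undefined value (e.g. zero denominator)."""


class TableFormatError(MlcpsError, ValueError):
    """A delimited-text table violates the expected layout."""
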