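"""Exception hierarchy for rizmap.

Every error raised deliberately by the package derives from :class:`RizmapError`
so callers (and the CLI) can distinguish validation failures from bugs.
"""


class RizmapError(Exception):
    """Base class for all rizmap errors."""


class InvalidConfigurationError(RizmapError, ValueError):
    """A configuration value violates its documented constraints."""


class InfeasibleGeometryError(RizmapError):
    """Lesion placement could not satisfy the geometric constraints.

    The message names the violated constraint (bounding box or minimum
    separation) so the caller can relax it.
    """


class DegenerateGeometryError(RizmapError):
    """A geometric operation has no defined answer (e.g. no boundary exists)."""


class MissingMarkersError(RizmapError, KeyError):
    """A marker gene set is empty after matching against the expression matrix."""


class EmptyMatrixError(RizmapError):
    """The expression matrix contains no usable spots."""


class UndefinedAgreementError(RizmapError):
    """No spot has an expected zone, so the agreement ratio is undefined."""


class IncomparableRunsError(RizmapError):
    """Two results were produced under incompatible configurations."""


class InputFormatError(RizmapError):
    """An on-disk input file could not be parsed."""
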