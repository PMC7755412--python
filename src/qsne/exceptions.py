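"""Named exceptions raised across the package.

Every contract violation raises a subclass of :class:`QsneError`, so callers
can catch the package's failures without masking unrelated bugs.
"""


class QsneError(Exception):
    """Base class for all qsne errors."""


class NotFiniteError(QsneError, ValueError):
    """Input contains NaN or infinite values where finite values are required."""


class DimensionMismatchError(QsneError, ValueError):
    """Shapes of related arrays are incompatible."""


class PerplexityRangeError(QsneError, ValueError):
    """A perplexity (or perplexity window) falls outside the valid (1, m-1) range."""


class BracketingError(QsneError, RuntimeError):
    """The bandwidth search failed to bracket the target perplexity."""


class NormalizationError(QsneError, ValueError):
    """Probability rows do not sum to one within tolerance."""


class DegenerateDataError(QsneError, ValueError):
    """The data carry no usable distance information (e.g. all points identical)."""


class InsufficientDataError(QsneError, ValueError):
    """Too few observations for the requested computation."""


class DisjointTraceError(QsneError, ValueError):
    """Two optimizer traces share no common objective range."""


class MatrixParseError(QsneError, ValueError):
    """A delimited text matrix could not be parsed."""
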