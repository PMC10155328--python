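"""Exception hierarchy for the eigenratio package.

Every error raised by the library derives from :class:`EigenratioError`, so
callers (including the CLI) can catch one base class and map it to a
non-zero exit status with a one-line remedy.
"""


class EigenratioError(Exception):
    """Base class for all package errors."""


class DimensionError(EigenratioError):
    """Input matrices disagree on the number of individuals (rows)."""


class DomainError(EigenratioError):
    """A non-missing genotype entry lies outside {0, 1, 2}."""


class ResourceError(EigenratioError):
    """The memory budget cannot hold even one column plus the accumulator."""


class ParameterError(EigenratioError):
    """An estimator or simulation parameter is out of its valid range."""


class NumericError(EigenratioError):
    """Non-finite accumulation or a non-positive denominator in the null."""


class RankDeficiencyError(EigenratioError):
    """The sample covariance is numerically rank deficient.

    Typically caused by duplicated individuals or highly correlated
    (multicollinear) markers; the remedy is to remove them upstream.
    """


class EstimationFailureError(EigenratioError):
    """No index satisfies the sequential decision rule.

    This can happen when the data exhibit serious multicollinearity;
    pre-process the genetic data to remove highly correlated markers.
    """


class EmptySpectrumError(EigenratioError):
    """Every marker was dropped (monomorphic / all-missing / MAF filter)."""


class EmptyOutputError(EigenratioError):
    """A conversion produced no usable variants."""


class GenotypeIOError(EigenratioError):
    """A genotype file could not be read or is truncated."""
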