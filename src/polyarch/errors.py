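"""Exception hierarchy shared across modules."""


class PolyarchError(Exception):
    """Base class for package errors."""


class DialectError(PolyarchError, ValueError):
    """A file does not conform to its declared text dialect."""


class LayoutError(PolyarchError):
    """Variant layout violates ordering constraints."""


class DomainError(PolyarchError):
    """An input value is outside its documented domain."""


class EmptyEligibleError(PolyarchError):
    """No variant passes the causal-eligibility filter."""


class DegenerateSignalError(PolyarchError):
    """All effects are zero but positive heritability was requested."""


class LDProfileError(PolyarchError):
    """Block LD description is invalid (e.g. non-positive-definite)."""


class PackingError(PolyarchError):
    """Requested gene span does not fit in the genome."""


class CollinearityError(PolyarchError):
    """Design matrix is rank deficient where full rank is required."""


class ConfigurationError(PolyarchError):
    """Inconsistent or incomplete configuration."""


class InsufficientDataError(PolyarchError):
    """Too few observations for the requested fit."""


class InsufficientSampleError(PolyarchError):
    """Too few individuals for the requested computation."""


class DegenerateDesignError(PolyarchError):
    """Regression design has no variation."""


class PartitionError(PolyarchError):
    """Requested partition is impossible."""


class NormalizationError(PolyarchError):
    """A normalizing total is zero."""


class MalformedIntervalError(PolyarchError):
    """Interval with start >= end."""


class AnnotationError(PolyarchError):
    """Gene annotation references an unknown chromosome."""


class AlignmentError(PolyarchError):
    """Two inputs that must share structure do not."""


class HarmonizationError(PolyarchError):
    """Allele mismatch between two summary-statistic tables."""


class MonomorphicError(PolyarchError):
    """Fewer than two genotype classes present."""


class FitFailureError(PolyarchError):
    """Nonlinear fit failed to converge after bounded restarts."""
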