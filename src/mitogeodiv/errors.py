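"""Exception hierarchy shared across the pipeline stages."""


class MitogeodivError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(MitogeodivError):
    """Sequences in one alignment differ in length."""


class AlphabetError(MitogeodivError):
    """A character outside {A, C, G, T, -, N} was encountered."""


class DuplicateIdentifierError(MitogeodivError):
    """Two records in one alignment share an identifier."""


class EmptyAlignmentError(MitogeodivError):
    """An operation produced or received an alignment with no columns."""


class LinkageError(MitogeodivError):
    """A sample's seq_name has no matching row in the companion alignment."""


class CoordinateError(MitogeodivError):
    """Latitude/longitude outside the valid WGS84 domain."""


class InsufficientSampleError(MitogeodivError):
    """Fewer sequences than the estimator requires."""


class UndefinedDistanceError(MitogeodivError):
    """A pair of sequences shares no comparable (both-ACGT) site."""


class SaturationError(MitogeodivError):
    """Observed divergence exceeds the domain of the distance correction."""


class MissingLabelError(MitogeodivError):
    """A sample used as a window center has no phylogroup label."""


class DegenerateGroupingError(MitogeodivError):
    """Grouping factor has fewer than two non-empty groups."""


class ParameterError(MitogeodivError):
    """A parameter outside its stated domain, or an infeasible configuration."""


class UndefinedCorrelationError(MitogeodivError):
    """Pearson correlation undefined because a variable has zero variance."""


class UndefinedPercentageError(MitogeodivError):
    """Percent variation undefined because both variance components are zero."""


class GridMismatchError(MitogeodivError):
    """Rasters in one operation do not share shape and georeferencing."""
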