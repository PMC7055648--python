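"""Exception types shared across the pipeline stages."""


class MesoconnError(ValueError):
    """Base class for all package-specific errors."""


class InvalidSpecError(MesoconnError):
    """A generator or pipeline specification violates its invariants."""


class UnknownConditionError(MesoconnError):
    """A stimulus condition is missing from the planted remap table."""


class InfeasibleClusteringError(MesoconnError):
    """Fewer data points than requested clusters."""


class DegenerateInputError(MesoconnError):
    """An input set is empty or otherwise degenerate."""


class IllPosedRegressionError(MesoconnError):
    """The global signal has zero variance; the regression is ill posed."""


class UndefinedCorrelationError(MesoconnError):
    """A correlation is undefined (constant trace or vector)."""


class IncompatibleNetworksError(MesoconnError):
    """Networks disagree in size or node coordinates."""


class InvalidPartitionError(MesoconnError):
    """A partition does not cover every node."""


class DegenerateBoundsError(MesoconnError):
    """Resolution-parameter bounds are undefined (constant weight matrix)."""


class SamplingError(MesoconnError):
    """The admissible sampling set is empty."""


class UndefinedFlexibilityError(MesoconnError):
    """Flexibility requires at least two layers."""


class EmptySummaryError(MesoconnError):
    """No profiles satisfy the summary filter."""


class UndefinedVarianceError(MesoconnError):
    """The z-Rand variance is undefined for a degenerate partition."""


class SchemaError(MesoconnError):
    """A file does not conform to the expected on-disk schema."""


class MissingPartnerError(MesoconnError):
    """A parcel lacks a homotopic partner."""
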