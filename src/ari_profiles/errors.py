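"""Exception hierarchy shared across the package."""


class AriProfilesError(Exception):
    """Base class for package errors."""


class ConfigurationError(AriProfilesError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(AriProfilesError, ValueError):
    """Invalid argument to an analysis operation."""


class FormatError(AriProfilesError, ValueError):
    """Malformed input table."""


class ModelError(AriProfilesError, ValueError):
    """Design matrix unusable (e.g. aliased cells)."""


class EstimationError(AriProfilesError, ValueError):
    """A statistical estimate cannot be formed from the data given."""


class DegenerateVarianceError(EstimationError):
    """All residual variances are zero; moderation is undefined."""


class DecompositionError(AriProfilesError, ValueError):
    """Principal component decomposition impossible (degenerate input)."""


class DegenerateTestError(AriProfilesError, ValueError):
    """Test statistic undefined (zero variance)."""


class UndefinedCorrelationError(DegenerateTestError):
    """Correlation undefined because an input vector is constant."""


class InsufficientDataError(AriProfilesError, ValueError):
    """Too few observations for the requested computation."""


class UnknownSubjectError(AriProfilesError, KeyError):
    """A subject identifier does not occur in the annotation."""


class FetchError(AriProfilesError, RuntimeError):
    """Network retrieval or remote-format parsing failed."""
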