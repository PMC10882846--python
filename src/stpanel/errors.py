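"""Exception hierarchy shared across the package."""


class StpanelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StpanelError):
    """An input file does not conform to the expected schema."""


class DomainError(StpanelError):
    """A value lies outside its mathematically valid domain."""


class ParameterError(StpanelError):
    """A user-supplied parameter is invalid or out of range."""


class AlignmentError(StpanelError):
    """Two aligned structures (field vs. weights) do not match."""


class DegenerateFieldError(StpanelError):
    """An attribute field has zero variance (statistic undefined)."""


class DegenerateGeometryError(StpanelError):
    """Geometry is degenerate (e.g. coincident centroids)."""


class SingularDesignError(StpanelError):
    """A (weighted) design matrix is rank deficient."""


class ConfigurationError(StpanelError):
    """The requested operation is incompatible with the inputs."""
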