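"""Exception hierarchy shared across the package."""


class NeuromodesError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(NeuromodesError, ValueError):
    """Operands have incompatible shapes."""


class DomainError(NeuromodesError, ValueError):
    """A parameter lies outside its admissible domain."""


class SingularDataError(NeuromodesError, ValueError):
    """A regression design is numerically rank deficient."""


class DegenerateDesignError(NeuromodesError, ValueError):
    """An estimation subproblem has no informative data (e.g. all-zero inputs)."""


class OptimizationFailureError(NeuromodesError, RuntimeError):
    """An iterative optimiser produced a non-finite or invalid result."""


class InternalConsistencyError(NeuromodesError, RuntimeError):
    """An invariant that the algorithm guarantees by construction was violated."""


class FormatError(NeuromodesError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ConfigError(NeuromodesError, ValueError):
    """A configuration document is invalid."""


class DataError(NeuromodesError, ValueError):
    """Input data are structurally valid but unusable for the requested operation."""
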