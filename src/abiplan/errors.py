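"""Exception hierarchy shared across the package."""


class AbiplanError(Exception):
    """Base class for all abiplan errors."""


class InvalidSpecError(AbiplanError):
    """A phantom/beam specification violates its invariants."""


class GeometryError(AbiplanError):
    """A geometric operation is impossible (empty projection, point outside body, ...)."""


class ConfigurationError(AbiplanError):
    """Objective/goal configuration does not cover the data it is applied to."""


class DegenerateSystemError(AbiplanError):
    """The weighted least-squares system cannot be assembled (e.g. all penalties zero)."""


class SingularSystemError(AbiplanError):
    """Gaussian elimination hit a pivot below the singularity threshold."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ValidationError(AbiplanError):
    """Input files are inconsistent with each other."""
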