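"""Exception hierarchy for the toothmor package."""


class ToothmorError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ToothmorError):
    """An input object violates one of its documented invariants."""


class GeometryError(ValidationError):
    """Infeasible geometry specification or malformed mesh."""


class MaterialError(ValidationError):
    """Constitutive parameters outside their admissible range."""


class SolverError(ToothmorError):
    """Static solve failed to converge.

    Attributes
    ----------
    last_residual : float or None
        Relative residual norm at the point of failure.
    """

    def __init__(self, message, last_residual=None):
        super().__init__(message)
        self.last_residual = last_residual


class InvertedElementError(SolverError):
    """An element's deformation gradient lost positive determinant.

    Attributes
    ----------
    element_id : int or None
        Index of the first offending element.
    """

    def __init__(self, message, element_id=None):
        super().__init__(message)
        self.element_id = element_id


class ZeroResidualError(ToothmorError):
    """The residual tensor is identically zero: no rank-one correction exists."""


class ExtrapolationError(ToothmorError):
    """A parametric query fell outside the training grid's bounding box."""


class ZeroNormError(ToothmorError):
    """Relative error is undefined because the reference field has zero norm."""


class ContainerError(ToothmorError):
    """An array container file is unreadable, truncated or fails its digest check."""


class ConfigError(ValidationError):
    """Pipeline configuration is malformed (unknown keys, bad types, bad values)."""


class PipelineError(ToothmorError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
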