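"""Exception hierarchy for orthomove."""


class OrthomoveError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(OrthomoveError):
    """A geometric construction has no well-defined answer.

    Raised for collinear/duplicated point sets, a vanishing projected ray,
    or a skeletal landmark falling onto the occlusal plane.
    """


class DegenerateTestError(OrthomoveError):
    """A statistical test is undefined for the given data (e.g. zero variance)."""


class SchemaError(OrthomoveError):
    """Input data violates the landmark file schema."""


class MissingLandmarkError(SchemaError):
    """A landmark required by an operation is absent from the set."""


class ConfigError(OrthomoveError):
    """Invalid simulation or run configuration."""
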