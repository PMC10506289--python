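"""Exception types shared across the registration pipeline."""


class KneeRegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KneeRegError, ValueError):
    """An argument is outside its documented domain."""


class InvalidTransformError(ParameterError):
    """A rigid-transform parameter is non-finite."""


class DegenerateRigError(ParameterError):
    """The two requested view directions coincide (modulo 180 degrees)."""


class ProjectionOutOfBoundsError(KneeRegError):
    """The mesh projects behind the source or entirely off the detector."""


class NoEdgesError(KneeRegError):
    """An edge map is empty; the edge potential field is undefined."""


class UndefinedSpecificityError(KneeRegError):
    """The projected interior is empty; object specificity is undefined."""
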