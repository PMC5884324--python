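"""Exception hierarchy for agelimb."""


class AgelimbError(Exception):
    """Base class for all agelimb computation errors."""


class DomainError(AgelimbError):
    """An input lies outside the validated domain of a regression or law."""


class GeometryError(AgelimbError):
    """A cross-section or mesh is geometrically invalid (e.g. no cortex)."""


class ClassificationError(AgelimbError):
    """A mesh node could not be assigned to the periosteal or endosteal layer."""


class CalibrationError(AgelimbError):
    """Inverse parameter identification failed or received degenerate input."""


class SolverError(AgelimbError):
    """The explicit integrator detected an instability or invalid state."""


class ConfigError(AgelimbError):
    """A run configuration failed schema validation."""
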