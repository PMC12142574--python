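"""Exception hierarchy shared by all pipeline stages."""


class FibtemplateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FibtemplateError):
    """A structure/trajectory file could not be parsed."""


class EmptyInputError(FibtemplateError):
    """An operation received zero atoms, frames or samples."""


class StructureMismatchError(FibtemplateError):
    """Atom counts or shapes are inconsistent between two structures."""


class ParameterError(FibtemplateError):
    """A numeric parameter is outside its valid domain."""


class ConfigError(FibtemplateError):
    """The YAML configuration is missing or invalid."""


class DataError(FibtemplateError):
    """Required observables or coordinates are absent from a trajectory."""


class SingularityError(FibtemplateError):
    """Two atoms coincide where a pairwise energy is being evaluated."""


class InfeasibleGeometryError(FibtemplateError):
    """Pose rejection sampling stalled; the requested geometry admits
    essentially no clash-free placements."""
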