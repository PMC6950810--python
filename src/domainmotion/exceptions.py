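"""Exception hierarchy used across the package."""


class DomainMotionError(Exception):
    """Base class for all package errors."""


class ParseError(DomainMotionError):
    """A file could not be parsed (message names the offending line/frame)."""


class SelectionError(DomainMotionError):
    """An atom selection is empty or refers to missing atoms."""


class DegenerateFitError(DomainMotionError):
    """Too few or collinear atoms for a rigid-body fit."""


class ParameterError(DomainMotionError):
    """A required per-atom parameter (radius, charge, LJ) is missing."""


class ConvergenceError(DomainMotionError):
    """An iterative solver did not converge within its iteration budget."""


class ConfigError(DomainMotionError):
    """A pipeline/CLI configuration is invalid."""
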