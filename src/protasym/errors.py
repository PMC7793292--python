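"""Exception hierarchy shared by all analysis modules."""


class ProtasymError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(ProtasymError):
    """A PDB record could not be parsed; message carries the line number."""


class EmptyStructureError(ProtasymError):
    """A structure or model contained zero atoms where atoms are required."""


class NoMatchError(ProtasymError):
    """An atom selection matched nothing where a match is required."""


class AmbiguousSelectionError(ProtasymError):
    """A selection required to resolve to exactly one atom matched several."""


class DegenerateGeometryError(ProtasymError):
    """Point configuration has too few points or insufficient rank."""


class InsufficientFramesError(ProtasymError):
    """An ensemble operation was asked to run on too few frames."""


class InsufficientDataError(ProtasymError):
    """Too few observations for the requested statistic or fit."""


class ParameterError(ProtasymError, ValueError):
    """A generator or analysis parameter is out of its allowed domain."""


class PairingError(ProtasymError):
    """Two series that must be frame-paired have different lengths."""


class NormalizationError(ProtasymError):
    """A normalizing quantity (mean, integral) is zero or invalid."""


class SupportError(ProtasymError):
    """Two profiles share no common q support."""


class ConvergenceError(ProtasymError):
    """An iterative procedure failed to converge within its budget."""


class InvalidRegionError(ProtasymError):
    """A fit region is invalid (e.g. Guinier slope of the wrong sign)."""


class RadiusAssignmentError(ProtasymError):
    """No van der Waals radius is known for an atom's element."""


class ConfigurationError(ProtasymError):
    """A pipeline configuration is missing or inconsistent."""
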