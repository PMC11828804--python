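"""Exception hierarchy shared across the package."""


class ZoneChipError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ZoneChipError):
    """Invalid configuration value or file."""


class ResolutionError(ConfigurationError):
    """Grid resolution too coarse to resolve a geometric feature."""


class DomainError(ZoneChipError, ValueError):
    """Input outside the physical/mathematical domain of an operation."""


class SolverError(ZoneChipError):
    """Iterative solver failed to converge."""


class CalibrationError(ZoneChipError):
    """Sensor calibration is unidentifiable or missing required points."""


class DataError(ZoneChipError):
    """Inconsistent measured data (e.g. dead cells exceed total cells)."""


class FormatError(ZoneChipError):
    """Unsupported or malformed file format."""


class RenderingError(ZoneChipError):
    """Synthetic rendering would exceed the image dtype range."""


class PlacementError(ZoneChipError):
    """Could not place non-overlapping synthetic objects at the requested density."""
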