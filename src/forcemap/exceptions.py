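"""Exception hierarchy for the force-map pipeline."""


class ForcemapError(Exception):
    """Base class for all package errors."""


class DomainError(ForcemapError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ConvergenceError(ForcemapError, ArithmeticError):
    """A numerical solver failed to converge; message carries diagnostics."""


class CalibrationError(ForcemapError):
    """Sensitivity or spring-constant calibration failed."""


class ContactPointError(ForcemapError):
    """No usable contact point could be estimated for a curve."""


class FitError(ForcemapError):
    """Young's-modulus fit failed (too few contact samples, E <= 0, ...)."""


class MapError(ForcemapError):
    """Map assembly / plane removal failed."""


class PartitionError(ForcemapError):
    """Region partition failed (e.g. empty cell mask)."""


class StatsError(ForcemapError):
    """Too few points for the requested statistic."""


class ArchiveError(ForcemapError):
    """Malformed force-map exchange archive."""
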