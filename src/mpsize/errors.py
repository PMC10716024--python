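"""Exception hierarchy for mpsize."""

from __future__ import annotations


class MPSizeError(Exception):
    """Base class for all mpsize errors."""


class FormatError(MPSizeError):
    """An input file violates the expected tabular/JSON format."""


class ValidationError(MPSizeError):
    """A domain object or parameter violates an invariant."""


class PeakFitError(MPSizeError):
    """A Gaussian peak fit failed to converge inside its window."""


class AmbiguousPeaksError(MPSizeError):
    """Too many candidate peaks inside one classification band."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates) if candidates is not None else []


class MissingPeakError(MPSizeError):
    """A required population (empty/filled/reference/released) was not found."""


class IncompleteDisassemblyError(MPSizeError):
    """Intact AAVs detected in a genome-release measurement; sizing refused."""


class DegenerateCurveError(MPSizeError):
    """A calibration line cannot be inverted (zero slope, degenerate x)."""


class FamilyMisuseError(MPSizeError):
    """A calibration family was used for a conversion it does not support."""


class NoRouteError(MPSizeError):
    """No sizing approach is possible with the declared materials."""


class ConfigError(MPSizeError):
    """A run configuration file is invalid."""
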