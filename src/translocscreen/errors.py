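"""Exception hierarchy for the screening pipeline.

Validation errors (bad inputs, impossible layouts) are distinguished from
computation errors so the CLI can map them to distinct exit codes.
"""


class TranslocScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(TranslocScreenError):
    """Invalid configuration, layout or input data (CLI exit code 2)."""


class CapacityError(ValidationError):
    """Plate layout cannot hold the requested wells."""


class PlacementError(TranslocScreenError):
    """Cells could not be placed without overlap at the requested density."""


class ShapeError(ValidationError):
    """Mismatched raster shapes between channels or label maps."""


class NormalizationError(TranslocScreenError):
    """No usable vehicle wells; the plate cannot be normalized."""


class GateError(TranslocScreenError):
    """Too few groups remain for the ANOVA gate."""


class CurveError(ValidationError):
    """A qPCR standard curve is invalid (e.g. non-negative slope)."""


class PrecisionError(TranslocScreenError):
    """Numerical routine failed to reach its requested tolerance."""
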