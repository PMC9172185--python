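"""Typed exceptions raised across the pipeline."""


class TilquantError(Exception):
    """Base class for all package errors."""


class ParameterError(TilquantError, ValueError):
    """A configuration or function parameter is outside its documented range."""


class PlacementError(TilquantError):
    """Synthetic objects cannot be placed without exceeding the tile area."""


class DegenerateInputError(TilquantError, ValueError):
    """Input has no usable variation (constant channel, equal densities...)."""


class EmptyTumourError(TilquantError):
    """Tumour segmentation produced an empty mask."""


class AlignmentError(TilquantError, ValueError):
    """Mask and image grids do not align."""


class StainMatrixError(TilquantError, ValueError):
    """Stain matrix is singular or malformed."""


class AggregationError(TilquantError, ValueError):
    """Density records cannot be aggregated (empty list, mixed markers)."""


class FitError(TilquantError):
    """A statistical model could not be fitted."""


class CutoffError(TilquantError):
    """No admissible candidate cutoff exists."""
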