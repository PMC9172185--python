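"""Core raster containers shared by the segmentation and quantification stages.

A whole slide (or a tile cut from one) is carried as a :class:`RasterImage`:
an 8-bit RGB pixel grid plus the physical scale it was scanned at.  The scale
is expressed as microns per pixel at pyramid level 0 together with the integer
downsample factor of the stored grid, so densities computed downstream are
always in physical units (cells per mm^2 of tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Scanner resolution the workflow was designed around (40x magnification).
DEFAULT_MPP = 0.252


@dataclass
class RasterImage:
    """An 8-bit RGB image with physical scale metadata.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        The RGB pixel grid.
    mpp : float
        Microns per pixel at pyramid level 0.
    level_downsample : int
        Downsample factor of ``pixels`` relative to level 0 (>= 1), so the
        effective scale of the stored grid is ``mpp * level_downsample``.
    """

    pixels: np.ndarray
    mpp: float = DEFAULT_MPP
    level_downsample: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ParameterError(
                f"pixels must be H x W x 3, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ParameterError(f"pixels must be uint8, got {self.pixels.dtype}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ParameterError("image must have at least one pixel")
        if not self.mpp > 0:
            raise ParameterError(f"mpp must be positive, got {self.mpp}")
        if int(self.level_downsample) != self.level_downsample or self.level_downsample < 1:
            raise ParameterError(
                f"level_downsample must be an integer >= 1, got {self.level_downsample}"
            )
        self.level_downsample = int(self.level_downsample)

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the stored grid."""
        return self.pixels.shape[:2]

    @property
    def effective_mpp(self) -> float:
        """Microns per pixel of the stored grid."""
        return self.mpp * self.level_downsample


@dataclass
class TumourMask:
    """Binary tumour mask aligned to a stated downsample level.

    ``provenance`` records the parameter set that produced the mask so every
    downstream artefact can state how its tumour region was obtained.
    """

    mask: np.ndarray
    level_downsample: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ParameterError(f"mask must be 2-D, got shape {self.mask.shape}")


@dataclass
class TilePatch:
    """A 1024x1024 (by default) tile cut from the tumour region.

    ``origin`` is the (row, col) of the tile's top-left corner in level-0
    pixels; tiles live on a regular non-overlapping grid anchored at (0, 0).
    ``tumour_fraction`` is the fraction of the tile covered by the tumour
    mask; only tiles with at least half tumour are admitted to analysis.
    """

    origin: tuple[int, int]
    size: int
    tumour_fraction: float
    image: RasterImage
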