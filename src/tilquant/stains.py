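"""H-DAB stain model: Beer-Lambert optical density and colour deconvolution.

Brightfield IHC colour formation is modelled as Beer-Lambert absorbance: a
pixel transmitting intensity ``I`` on [0, 255] has optical density

    OD = -log10((I + eps) / 255)

per RGB channel, and the OD vector is a non-negative mixture of per-stain
unit absorbance vectors.  Unmixing (colour deconvolution) inverts that linear
system with the stain-matrix inverse, yielding per-stain concentration maps —
here the hematoxylin (blue nuclear counterstain) and DAB (brown chromogen)
channels, with the third residual channel discarded.

The default stain vectors are the classical Ruifrok & Johnston H-DAB values;
they are configurable because real scanners and staining batches deviate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StainMatrixError
from .image import RasterImage

#: Ruifrok & Johnston H-DAB absorbance vectors (rows: hematoxylin, DAB).
HEMATOXYLIN_VECTOR = np.array([0.650, 0.704, 0.286])
DAB_VECTOR = np.array([0.268, 0.570, 0.776])

_EPS = 1e-6


def hdab_stain_matrix(
    hematoxylin: np.ndarray = HEMATOXYLIN_VECTOR,
    dab: np.ndarray = DAB_VECTOR,
) -> np.ndarray:
    """Build a 3x3 unit-row stain matrix [hematoxylin; DAB; residual].

    The residual vector is the unit cross product of the two stains, so the
    matrix is always invertible for non-collinear stain vectors.
    """
    h = np.asarray(hematoxylin, dtype=float)
    d = np.asarray(dab, dtype=float)
    h = h / np.linalg.norm(h)
    d = d / np.linalg.norm(d)
    resid = np.cross(h, d)
    norm = np.linalg.norm(resid)
    if norm < 1e-8:
        raise StainMatrixError("stain vectors are collinear; matrix is singular")
    return np.vstack([h, d, resid / norm])


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB array (clipped at 0)."""
    od = -np.log10((pixels.astype(float) + _EPS) / 255.0)
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`, returning uint8 RGB."""
    rgb = 255.0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def stain_rgb(stain_vector: np.ndarray, od: float = 1.0) -> np.ndarray:
    """RGB colour of a pure stain at the given optical density (uint8)."""
    v = np.asarray(stain_vector, dtype=float)
    return od_to_rgb(od * v / np.linalg.norm(v))


@dataclass
class StainChannels:
    """Unmixed per-stain optical-density images (same shape as the tile)."""

    hematoxylin_od: np.ndarray
    dab_od: np.ndarray


def colour_deconvolve(
    tile: RasterImage | np.ndarray, stain_matrix: np.ndarray | None = None
) -> StainChannels:
    """Unmix an RGB tile into hematoxylin and DAB optical-density channels.

    Parameters
    ----------
    tile : RasterImage or uint8 ndarray (H, W, 3)
    stain_matrix : 3x3 array, optional
        Rows are unit absorbance vectors (hematoxylin, DAB, residual).
        Defaults to the Ruifrok & Johnston H-DAB matrix.

    Returns
    -------
    StainChannels
        Non-negative OD images; the residual channel is discarded.
    """
    pixels = tile.pixels if isinstance(tile, RasterImage) else np.asarray(tile)
    if stain_matrix is None:
        stain_matrix = hdab_stain_matrix()
    stain_matrix = np.asarray(stain_matrix, dtype=float)
    if stain_matrix.shape != (3, 3):
        raise StainMatrixError(f"stain matrix must be 3x3, got {stain_matrix.shape}")
    if abs(np.linalg.det(stain_matrix)) < 1e-8:
        raise StainMatrixError("stain matrix is singular")
    od = rgb_to_od(pixels)
    conc = od.reshape(-1, 3) @ np.linalg.inv(stain_matrix)
    conc = np.clip(conc, 0.0, None).reshape(pixels.shape)
    return StainChannels(hematoxylin_od=conc[..., 0], dab_od=conc[..., 1])


def remix(channels: StainChannels, stain_matrix: np.ndarray | None = None) -> np.ndarray:
    """Re-render unmixed channels to RGB (residual assumed zero)."""
    if stain_matrix is None:
        stain_matrix = hdab_stain_matrix()
    conc = np.stack(
        [
            channels.hematoxylin_od,
            channels.dab_od,
            np.zeros_like(channels.dab_od),
        ],
        axis=-1,
    )
    od = conc.reshape(-1, 3) @ np.asarray(stain_matrix, dtype=float)
    return od_to_rgb(od.reshape(conc.shape))
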