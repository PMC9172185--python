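"""Tumour-region segmentation on downsampled slides and full-resolution tiling.

The slide is reduced by block-mean downsampling (factor 16 by default),
converted to HSV, and thresholded on the saturation channel with Otsu's
method: unstained background and blank alveolar cavities are near-white
(saturation ~ 0) while tissue is stained (saturation high), so saturation is
the discriminative channel.  An optional hue-range gate can further restrict
the mask to tumour-tissue hues.  Morphological closing and small-object
removal stand in for the interactive fine-tuning step a pathologist would
perform; their radii are configuration, not fact.

The resulting binary mask is upsampled (nearest neighbour) to level 0 and
the tumour region cut into non-overlapping square tiles on a regular grid;
a tile enters analysis only if at least half of it is tumour.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv
from skimage.morphology import closing, disk, remove_small_objects

from .errors import AlignmentError, DegenerateInputError, EmptyTumourError, ParameterError
from .image import RasterImage, TilePatch, TumourMask


def downsample(img: RasterImage, factor: int) -> RasterImage:
    """Block-mean reduce an image by an integer factor.

    Output dimensions are ``ceil(H/factor) x ceil(W/factor)``; partial edge
    blocks are averaged over the pixels they actually contain.  The physical
    scale bookkeeping follows: ``level_downsample`` is multiplied by
    ``factor``.
    """
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    h, w = img.shape
    if factor > min(h, w):
        raise ParameterError(f"factor {factor} exceeds image dimensions {h}x{w}")
    if factor == 1:
        return RasterImage(img.pixels.copy(), img.mpp, img.level_downsample)
    acc = np.add.reduceat(img.pixels.astype(np.float64), np.arange(0, h, factor), axis=0)
    acc = np.add.reduceat(acc, np.arange(0, w, factor), axis=1)
    rows = np.minimum(np.arange(0, h, factor) + factor, h) - np.arange(0, h, factor)
    cols = np.minimum(np.arange(0, w, factor) + factor, w) - np.arange(0, w, factor)
    acc /= rows[:, None, None] * cols[None, :, None]
    return RasterImage(
        np.clip(np.rint(acc), 0, 255).astype(np.uint8),
        img.mpp,
        img.level_downsample * factor,
    )


def rgb_to_hsv_channels(img: RasterImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard hexcone HSV transform; all three channels on [0, 1]."""
    hsv = rgb2hsv(img.pixels)
    return hsv[..., 0], hsv[..., 1], hsv[..., 2]


def otsu_threshold(channel: np.ndarray, nbins: int = 256) -> float:
    """Otsu's automatic threshold over a fixed-bin histogram.

    The returned value is the upper edge of the last low-class bin of the
    variance-maximizing split, so "value <= threshold" reproduces that
    split exactly; ties are broken by the smallest maximizing threshold.

    Raises
    ------
    DegenerateInputError
        If the channel is constant (no threshold separates anything).
    """
    values = np.asarray(channel, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise DegenerateInputError("constant channel has no Otsu threshold")
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centres = (edges[:-1] + edges[1:]) / 2.0
    p = hist.astype(float) / hist.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centres)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        # between-class variance for splitting after each bin t (low: <= t)
        num = (mu_total * w0 - mu) ** 2
        den = w0 * (1.0 - w0)
        sigma_b = np.where(den > 0, num / den, 0.0)
    best = int(np.argmax(sigma_b[:-1]))  # argmax takes the first (smallest) tie
    return float(edges[best + 1])


def segment_tumour_region(
    img: RasterImage,
    hue_range: tuple[float, float] | None = None,
    closing_radius: int = 2,
    min_object_px: int = 64,
) -> TumourMask:
    """Segment stained tissue from background/blank on a downsampled slide.

    The mask keeps pixels whose saturation is at or above the Otsu threshold
    of the saturation channel (white background and blank cavities have
    saturation ~ 0), optionally intersected with a hue-range gate, then
    cleaned by morphological closing and small-object removal.

    Raises
    ------
    EmptyTumourError
        If nothing survives (e.g. an all-white slide).
    """
    hue, sat, _ = rgb_to_hsv_channels(img)
    try:
        t = otsu_threshold(sat)
    except DegenerateInputError:
        raise EmptyTumourError("slide has constant saturation; no tissue found")
    mask = sat >= t
    if hue_range is not None:
        lo, hi = hue_range
        gate = (hue >= lo) & (hue <= hi) if lo <= hi else (hue >= lo) | (hue <= hi)
        mask &= gate
    if closing_radius > 0:
        mask = closing(mask, disk(closing_radius))
    if min_object_px > 0:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    if not mask.any():
        raise EmptyTumourError("tumour mask is empty after cleanup")
    return TumourMask(
        mask=mask,
        level_downsample=img.level_downsample,
        provenance={
            "saturation_threshold": t,
            "hue_range": hue_range,
            "closing_radius": closing_radius,
            "min_object_px": min_object_px,
        },
    )


def mask_to_geojson(mask: TumourMask) -> dict:
    """Boundary polygons of a tumour mask as a GeoJSON FeatureCollection.

    Contours are traced at the 0.5 level on the stored (downsampled) grid;
    coordinates are [col, row] in level-0 pixels (scaled by the mask's
    ``level_downsample``).
    """
    from skimage.measure import find_contours

    f = mask.level_downsample
    features = []
    padded = np.pad(mask.mask.astype(float), 1)
    for contour in find_contours(padded, 0.5):
        coords = [
            [float((c - 1) * f), float((r - 1) * f)] for r, c in contour
        ]
        if coords[0] != coords[-1]:
            coords.append(coords[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [coords]},
                "properties": {"level_downsample": f},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def upsample_mask(mask: TumourMask, shape_level0: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample of a downsampled mask to the level-0 grid."""
    f = mask.level_downsample
    up = np.repeat(np.repeat(mask.mask, f, axis=0), f, axis=1)
    h, w = shape_level0
    if up.shape[0] < h or up.shape[1] < w:
        raise AlignmentError(
            f"mask at downsample {f} covers {up.shape}, smaller than image {shape_level0}"
        )
    return up[:h, :w]


def tile_tumour_region(
    img: RasterImage,
    mask: TumourMask,
    tile_size: int = 1024,
    min_tumour_fraction: float = 0.5,
) -> list[TilePatch]:
    """Cut the tumour region into non-overlapping level-0 tiles.

    Tiles live on a regular grid anchored at (0, 0) with half-open extents
    ``[r, r + tile_size)``; partial edge tiles are discarded.  A tile is
    admitted iff its tumour-mask fraction is at least ``min_tumour_fraction``
    (inclusive — exactly 50% tumour is kept under the default).
    """
    if img.level_downsample != 1:
        raise AlignmentError("tiling requires the level-0 image")
    h, w = img.shape
    mask0 = upsample_mask(mask, (h, w))
    tiles = []
    for r in range(0, h - tile_size + 1, tile_size):
        for c in range(0, w - tile_size + 1, tile_size):
            frac = float(mask0[r : r + tile_size, c : c + tile_size].mean())
            if frac >= min_tumour_fraction:
                tiles.append(
                    TilePatch(
                        origin=(r, c),
                        size=tile_size,
                        tumour_fraction=frac,
                        image=RasterImage(
                            img.pixels[r : r + tile_size, c : c + tile_size].copy(),
                            img.mpp,
                            1,
                        ),
                    )
                )
    return tiles
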