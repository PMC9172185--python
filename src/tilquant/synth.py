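"""Synthetic IHC tiles and survival cohorts with exact ground truth.

This module is the package's test-bed generator.  It renders brightfield
H-DAB tiles that reproduce the visual classes the quantification pipeline
must tell apart — DAB-brown positive (lymphocyte) nuclei, hematoxylin-blue
negative nuclei, near-black dust macules (a lung-tissue artefact), white
blank alveolar cavities, and a faint eosin-pink tissue wash — with every
object's centroid and class recorded exactly by construction.  Stained
objects are rendered with the same Beer-Lambert stain vectors the
deconvolution stage inverts, so stain-separation tests have closed-form
expected values.

It also simulates survival cohorts in which a 0-100 marker score carries a
step hazard effect at a known cutoff, which is what the cutoff-selection and
Cox-regression stages must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import ParameterError, PlacementError
from .image import DEFAULT_MPP, RasterImage
from .stains import DAB_VECTOR, HEMATOXYLIN_VECTOR, stain_rgb

#: Faint tissue wash: eosin absorbance at OD 0.15 (pink, clearly saturated
#: against blank white, and projecting only ~0.02 onto the DAB channel).
TISSUE_WASH_RGB = (249, 181, 246)
#: Lymphocyte nuclear radius range in microns (5-10 um diameter).
DEFAULT_NUCLEUS_RADIUS_UM = (2.5, 5.0)


@dataclass
class SyntheticTileSpec:
    """Parameters of one synthetic IHC tile.

    The defaults are the package's reference tile conditions: a 512x512 px
    desk-scale tile at scanner resolution, 20 DAB-positive and 20
    hematoxylin-only nuclei (~1500 positive cells per mm^2 of tissue, a
    realistic infiltration density), 3 dust macules, one fifth of the tile
    blank alveolar cavity, and two deliberately touching positive pairs so
    the adhesive-cell splitting stage is exercised.
    """

    width: int = 512
    height: int = 512
    n_positive: int = 20
    n_negative: int = 20
    n_dust: int = 3
    blank_fraction: float = 0.2
    nucleus_radius_um: tuple[float, float] = DEFAULT_NUCLEUS_RADIUS_UM
    mpp: float = DEFAULT_MPP
    n_overlap_pairs: int = 2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_positive, self.n_negative, self.n_dust, self.n_overlap_pairs) < 0:
            raise ParameterError("object counts must be >= 0")
        if not 0 <= self.blank_fraction < 1:
            raise ParameterError(
                f"blank_fraction must be in [0, 1), got {self.blank_fraction}"
            )
        lo, hi = self.nucleus_radius_um
        if not (0 < lo <= hi):
            raise ParameterError(f"bad nucleus radius range {self.nucleus_radius_um}")
        if self.mpp <= 0:
            raise ParameterError("mpp must be positive")
        if self.width < 8 or self.height < 8:
            raise ParameterError("tile must be at least 8x8 px")
        if 2 * self.n_overlap_pairs > self.n_positive:
            raise ParameterError("overlap pairs cannot exceed half of n_positive")


@dataclass
class TileTruth:
    """A rendered tile plus its exact ground truth."""

    image: RasterImage
    positive_centroids: list[tuple[int, int]]
    negative_centroids: list[tuple[int, int]]
    dust_centroids: list[tuple[int, int]]
    tissue_area_px: int

    @property
    def positive_count(self) -> int:
        return len(self.positive_centroids)


def _place_one(
    rng: np.random.Generator,
    row_range: tuple[float, float],
    col_range: tuple[float, float],
    eff_radius: float,
    occupied: list[tuple[float, float, float]],
    what: str,
    max_tries: int = 4000,
) -> tuple[float, float]:
    """Rejection-sample one centre whose effective radius clears ``occupied``.

    ``occupied`` holds (row, col, effective radius) of already-placed
    objects; the new centre must be at least the sum of effective radii from
    each.  Raises :class:`PlacementError` naming the offending object class
    when the tile is too crowded.
    """
    for _ in range(max_tries):
        r = rng.uniform(*row_range)
        c = rng.uniform(*col_range)
        if all(
            (r - ro) ** 2 + (c - co) ** 2 >= (eff_radius + rad) ** 2
            for ro, co, rad in occupied
        ):
            occupied.append((r, c, eff_radius))
            return r, c
    raise PlacementError(f"could not place {what} in the available tissue area")


def _draw_nucleus(canvas, rng, centre, radius_px, colour) -> None:
    """Filled ellipse with mild axis jitter and random orientation."""
    jitter = rng.uniform(0.0, 0.25)
    rr, cc = draw_ellipse(
        centre[0],
        centre[1],
        radius_px * (1 + jitter),
        radius_px * (1 - jitter),
        rotation=rng.uniform(0, np.pi),
        shape=canvas.shape[:2],
    )
    canvas[rr, cc] = colour


def _draw_dust(canvas, rng, centre, r_px: float) -> None:
    """Irregular near-black blob: a union of offset ellipses within r_px."""
    grey = int(rng.uniform(15, 35))
    for _ in range(rng.integers(3, 7)):
        dr, dc = rng.uniform(-0.4 * r_px, 0.4 * r_px, size=2)
        rr, cc = draw_ellipse(
            centre[0] + dr,
            centre[1] + dc,
            r_px * rng.uniform(0.5, 1.0),
            r_px * rng.uniform(0.5, 1.0),
            rotation=rng.uniform(0, np.pi),
            shape=canvas.shape[:2],
        )
        canvas[rr, cc] = (grey, grey, grey)


def generate_ihc_tile(spec: SyntheticTileSpec) -> TileTruth:
    """Render one synthetic H-DAB tile with exact ground truth.

    Layout: a white blank strip (alveolar cavity) occupies the leftmost
    ``blank_fraction`` of the tile; the remainder is tissue (eosin-pink wash
    with mild noise).  DAB-positive nuclei are rendered at the pure DAB
    colour at optical density 1.0, negative nuclei at the pure hematoxylin
    colour at OD 1.0; dust macules are near-black irregular blobs.  The same
    spec (including seed) always yields a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    blank_w = int(round(spec.blank_fraction * w))

    canvas = np.empty((h, w, 3), dtype=np.uint8)
    canvas[:, :blank_w] = 255
    wash = np.array(TISSUE_WASH_RGB, dtype=float)
    noise = rng.normal(scale=1.5, size=(h, w - blank_w, 3))
    canvas[:, blank_w:] = np.clip(wash + noise, 0, 255).astype(np.uint8)
    tissue_area_px = h * (w - blank_w)

    r_lo, r_hi = (r / spec.mpp for r in spec.nucleus_radius_um)
    margin = int(np.ceil(r_hi)) + 2
    if w - blank_w <= 2 * margin or h <= 2 * margin:
        raise PlacementError("tissue region too small for any nucleus")
    row_range = (margin, h - margin)
    col_range = (blank_w + margin, w - margin)

    occupied: list[tuple[float, float, float]] = []
    pos_colour = stain_rgb(DAB_VECTOR, od=1.0)
    neg_colour = stain_rgb(HEMATOXYLIN_VECTOR, od=1.0)

    # Effective radius clears the 1.25x jitter on the major axis plus a
    # 1-px gap so independently placed nuclei never touch.
    def eff(radius: float) -> float:
        return 1.3 * radius + 1.0

    # Dust macules are the largest objects: place them first so the
    # remaining nuclei pack around them.  Blob diameter 2-12 um.
    dust: list[tuple[int, int]] = []
    dust_jobs: list[tuple[tuple[float, float], float]] = []
    for _ in range(spec.n_dust):
        d_um = rng.uniform(2.0, 12.0)
        r_px = max(1.5, d_um / 2.0 / spec.mpp)
        dm = int(np.ceil(1.4 * r_px)) + 2
        rows = (float(dm), float(h - dm))
        cols = (float(blank_w + dm), float(w - dm))
        if rows[0] >= rows[1] or cols[0] >= cols[1]:
            raise PlacementError(f"could not place {spec.n_dust} x dust macule")
        r, c = _place_one(
            rng, rows, cols, 1.4 * r_px + 2, occupied, f"{spec.n_dust} x dust macule"
        )
        dust_jobs.append(((r, c), r_px))
        dust.append((int(round(r)), int(round(c))))

    # Touching positive pairs are placed next: the two ellipses of a pair
    # overlap deliberately and must be split by watershed downstream.
    positive: list[tuple[int, int]] = []
    for _ in range(spec.n_overlap_pairs):
        radius = rng.uniform(r_lo, r_hi)
        gap = 1.8 * radius
        ar, ac = _place_one(
            rng, row_range, col_range, eff(radius) + gap / 2, occupied,
            f"{spec.n_overlap_pairs} x overlap pair",
        )
        theta = rng.uniform(0, 2 * np.pi)
        for k in (-0.5, 0.5):
            cr = ar + k * gap * np.sin(theta)
            cc = ac + k * gap * np.cos(theta)
            _draw_nucleus(canvas, rng, (cr, cc), radius, pos_colour)
            positive.append((int(round(cr)), int(round(cc))))

    n_single = spec.n_positive - 2 * spec.n_overlap_pairs
    for _ in range(n_single):
        radius = rng.uniform(r_lo, r_hi)
        r, c = _place_one(
            rng, row_range, col_range, eff(radius), occupied,
            f"{spec.n_positive} x positive nucleus",
        )
        _draw_nucleus(canvas, rng, (r, c), radius, pos_colour)
        positive.append((int(round(r)), int(round(c))))

    negative: list[tuple[int, int]] = []
    for _ in range(spec.n_negative):
        radius = rng.uniform(r_lo, r_hi)
        r, c = _place_one(
            rng, row_range, col_range, eff(radius), occupied,
            f"{spec.n_negative} x negative nucleus",
        )
        _draw_nucleus(canvas, rng, (r, c), radius, neg_colour)
        negative.append((int(round(r)), int(round(c))))

    for centre, r_px in dust_jobs:
        _draw_dust(canvas, rng, centre, r_px)

    return TileTruth(
        image=RasterImage(canvas, mpp=spec.mpp),
        positive_centroids=positive,
        negative_centroids=negative,
        dust_centroids=dust,
        tissue_area_px=tissue_area_px,
    )


@dataclass
class SlideTruth:
    """A synthetic desk-scale 'slide': pink tissue disc on a white background."""

    image: RasterImage
    tissue_mask: np.ndarray
    positive_centroids: list[tuple[int, int]]


def generate_tissue_slide(
    width: int = 2048,
    height: int = 2048,
    disc_fraction: float = 0.42,
    n_positive: int = 0,
    nucleus_radius_um: tuple[float, float] = DEFAULT_NUCLEUS_RADIUS_UM,
    mpp: float = DEFAULT_MPP,
    seed: int = 0,
) -> SlideTruth:
    """Render a slide-like image for tumour-segmentation and end-to-end tests.

    A single tissue disc (radius ``disc_fraction`` x min dimension) of
    eosin-pink wash is drawn on a white slide background; ``n_positive``
    DAB-positive nuclei are scattered inside it.
    """
    rng = np.random.default_rng(seed)
    canvas = np.full((height, width, 3), 255, dtype=np.uint8)
    radius = disc_fraction * min(height, width)
    cr, cc = height / 2, width / 2
    rr, cols = draw_ellipse(cr, cc, radius, radius, shape=(height, width))
    wash = np.array(TISSUE_WASH_RGB, dtype=float)
    canvas[rr, cols] = np.clip(
        wash + rng.normal(scale=1.5, size=(rr.size, 3)), 0, 255
    ).astype(np.uint8)
    mask = np.zeros((height, width), dtype=bool)
    mask[rr, cols] = True

    r_lo, r_hi = (r / mpp for r in nucleus_radius_um)
    inner = radius - 2 * r_hi
    occupied: list[tuple[float, float, float]] = []
    pos_colour = stain_rgb(DAB_VECTOR, od=1.0)
    positive = []
    for _ in range(n_positive):
        for _ in range(2000):
            ang = rng.uniform(0, 2 * np.pi)
            rad = inner * np.sqrt(rng.uniform())
            r, c = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
            if all(
                (r - ro) ** 2 + (c - co) ** 2 >= (2 * r_hi + 2 + rad2) ** 2
                for ro, co, rad2 in occupied
            ):
                occupied.append((r, c, 2 * r_hi + 2))
                break
        else:
            raise PlacementError(f"could not place {n_positive} x positive nucleus")
        _draw_nucleus(canvas, rng, (r, c), rng.uniform(r_lo, r_hi), pos_colour)
        positive.append((int(round(r)), int(round(c))))
    return SlideTruth(
        image=RasterImage(canvas, mpp=mpp), tissue_mask=mask, positive_centroids=positive
    )


# ---------------------------------------------------------------------------
# Survival cohorts


@dataclass
class CohortSpec:
    """Parameters of a simulated survival cohort.

    Each subject receives a marker score ~ Uniform(0, 100); crossing
    ``true_cutoff`` multiplies the event hazard by
    ``hazard_ratio_high_vs_low`` (values < 1 mean high scores are
    protective, as for immune infiltration).  Event times are exponential,
    censoring is exponential truncated at ``max_followup_months``.  Binary
    Bernoulli(1/2) covariates with the given log-hazard effects emulate
    clinical factors.  Defaults approximate a resected-NSCLC cohort:
    ~0.01 events/month baseline and ten years of follow-up.
    """

    n_subjects: int = 200
    true_cutoff: float = 50.0
    hazard_ratio_high_vs_low: float = 0.5
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.008
    max_followup_months: float = 120.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be >= 2")
        if self.hazard_ratio_high_vs_low <= 0:
            raise ParameterError("hazard ratio must be positive")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ParameterError("censoring_rate must be >= 0")
        if not self.max_followup_months > 0:
            raise ParameterError("max_followup_months must be positive")


def generate_survival_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a subject table: score, covariates, observed time, event.

    Columns: ``subject_id``, ``score``, one column per covariate, ``time``
    (months), ``event`` (1 = DFS event observed, 0 = censored).  The same
    spec (including seed) always yields an identical table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    score = rng.uniform(0.0, 100.0, size=n)
    covs = {
        name: rng.integers(0, 2, size=n).astype(float)
        for name in spec.covariate_effects
    }
    log_h = np.log(spec.baseline_hazard) + np.log(
        spec.hazard_ratio_high_vs_low
    ) * (score > spec.true_cutoff)
    for name, beta in spec.covariate_effects.items():
        log_h = log_h + beta * covs[name]
    event_time = rng.exponential(1.0, size=n) / np.exp(log_h)
    if spec.censoring_rate > 0:
        cens_time = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)
    cens_time = np.minimum(cens_time, spec.max_followup_months)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    out = pd.DataFrame({"subject_id": np.arange(n), "score": score})
    for name, vals in covs.items():
        out[name] = vals
    out["time"] = np.maximum(time, 1e-9)
    out["event"] = event
    return out


# ---------------------------------------------------------------------------
# On-disk fixture export (PNG/TIFF tile + CSV/JSON truth)


def save_tile_truth(truth: TileTruth, out_dir: str | Path, stem: str) -> dict:
    """Write the tile image (PNG) and its ground truth (CSV + JSON summary)."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(truth.image.pixels).save(out_dir / f"{stem}.png")
    rows = (
        [("positive", r, c) for r, c in truth.positive_centroids]
        + [("negative", r, c) for r, c in truth.negative_centroids]
        + [("dust", r, c) for r, c in truth.dust_centroids]
    )
    pd.DataFrame(rows, columns=["klass", "row", "col"]).to_csv(
        out_dir / f"{stem}_truth.csv", index=False
    )
    summary = {
        "positive_count": truth.positive_count,
        "negative_count": len(truth.negative_centroids),
        "dust_count": len(truth.dust_centroids),
        "tissue_area_px": int(truth.tissue_area_px),
        "mpp": truth.image.mpp,
    }
    (out_dir / f"{stem}_truth.json").write_text(json.dumps(summary, indent=2))
    return summary
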