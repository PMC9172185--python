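"""Slide-to-report orchestration.

``run_slide`` takes a subject's adjacent CD3- and CD8-stained slides through
tumour segmentation, tiling and cell quantification, producing per-tile and
slide-aggregated densities.  ``run_cohort`` takes per-subject densities plus
a survival table through score normalization, maxstat cutoffs (fit on the
cohort or imported from a discovery run), I-score assignment, and the
survival/model-comparison report.  Batch processing records per-slide errors
and continues; missing-data subjects are excluded complete-case (no
imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import DensityRecord, aggregate_slide_density, quantify_tile
from .config import PipelineConfig
from .errors import ParameterError, TilquantError
from .image import RasterImage
from .scoring import ScoreNormalizer, assign_iscore_table, maxstat_cutoff
from .stains import hdab_stain_matrix
from .survival import (
    CoxFit,
    cox_fit,
    harrell_cindex,
    integrated_auc,
    kaplan_meier,
    likelihood_ratio_test,
    logrank_test,
    screen_candidates,
    stepwise_aic,
)
from .tissue import downsample, segment_tumour_region, tile_tumour_region


@dataclass
class SlideResult:
    """Quantification output of one subject's pair of stained slides."""

    slide_id: str
    config_hash: str
    per_tile: pd.DataFrame
    aggregated: dict[str, DensityRecord]
    qc: dict = field(default_factory=dict)


def run_slide(
    slide_id: str,
    cd3_image: RasterImage,
    cd8_image: RasterImage,
    config: PipelineConfig | None = None,
) -> SlideResult:
    """Segment, tile and quantify a subject's CD3 and CD8 slides.

    The two slides are adjacent sections, so a tumour mask is computed for
    each independently.  Returns per-tile density rows and the area-weighted
    slide aggregate per marker.
    """
    config = config or PipelineConfig()
    config.validate()
    if cd3_image.mpp != cd8_image.mpp:
        raise ParameterError("CD3 and CD8 slides must share mpp")
    stain_matrix = hdab_stain_matrix(
        np.array(config.stain_hematoxylin), np.array(config.stain_dab)
    )
    rows = []
    aggregated: dict[str, DensityRecord] = {}
    qc: dict = {"config_hash": config.config_hash}
    for marker, image in (("CD3", cd3_image), ("CD8", cd8_image)):
        small = downsample(image, config.downsample_factor)
        mask = segment_tumour_region(
            small,
            hue_range=config.hue_range,
            closing_radius=config.closing_radius,
            min_object_px=config.min_object_px,
        )
        tiles = tile_tumour_region(
            image, mask, tile_size=config.tile_size,
            min_tumour_fraction=config.tumour_fraction_min,
        )
        qc[f"{marker}_n_tiles"] = len(tiles)
        records = []
        for tile in tiles:
            record, _, _ = quantify_tile(
                tile.image,
                marker=marker,
                stain_matrix=stain_matrix,
                n_superpixels=config.n_superpixels,
                dust_threshold=config.dust_threshold,
                bernsen_window_radius=config.bernsen_window_radius,
                bernsen_contrast_min=config.bernsen_contrast_min,
                bernsen_mid_fixed=config.bernsen_mid_fixed,
                min_peak_separation=config.min_peak_separation,
                min_area_px=config.min_cell_area_px,
                max_area_px=config.max_cell_area_px,
                kmeans_seed=config.seed,
            )
            records.append(record)
            rows.append(
                {
                    "slide_id": slide_id,
                    "marker": marker,
                    "tile_row": tile.origin[0],
                    "tile_col": tile.origin[1],
                    "tumour_fraction": tile.tumour_fraction,
                    "cell_count": record.cell_count,
                    "tissue_area_px": record.tissue_area_px,
                    "density": record.density,
                }
            )
        if records:
            aggregated[marker] = aggregate_slide_density(records)
    per_tile = pd.DataFrame(
        rows,
        columns=[
            "slide_id", "marker", "tile_row", "tile_col", "tumour_fraction",
            "cell_count", "tissue_area_px", "density",
        ],
    )
    return SlideResult(
        slide_id=slide_id, config_hash=config.config_hash,
        per_tile=per_tile, aggregated=aggregated, qc=qc,
    )


def run_batch(slides, config: PipelineConfig | None = None):
    """Process (slide_id, cd3_image, cd8_image) triples; collect errors.

    Returns ``(results, errors)`` where ``errors`` maps slide_id to the
    error message; processing continues across failures.
    """
    results, errors = [], {}
    for slide_id, cd3, cd8 in slides:
        try:
            results.append(run_slide(slide_id, cd3, cd8, config))
        except TilquantError as exc:
            errors[slide_id] = f"{type(exc).__name__}: {exc}"
    return results, errors


@dataclass
class CohortReport:
    """Scored cohort plus the survival and model-comparison summaries."""

    subjects: pd.DataFrame
    cd3_cutoff: float
    cd8_cutoff: float
    normalizers: dict[str, ScoreNormalizer]
    excluded: list
    config_hash: str
    logrank: dict = field(default_factory=dict)
    iscore_fit: CoxFit | None = None
    final_fit: CoxFit | None = None
    screened: list[str] = field(default_factory=list)
    model_metrics: dict = field(default_factory=dict)


def run_cohort(
    densities: pd.DataFrame,
    survival: pd.DataFrame,
    config: PipelineConfig | None = None,
    covariates: list[str] | None = None,
    cutoffs: tuple[float, float] | None = None,
    normalizers: dict[str, ScoreNormalizer] | None = None,
) -> CohortReport:
    """Score a cohort and report the prognostic value of the I-score.

    Parameters
    ----------
    densities : DataFrame with columns subject_id, cd3_density, cd8_density.
    survival : DataFrame with columns subject_id, time, event (+ covariates).
    covariates : clinical covariate columns to screen at p < 0.10 and feed
        to stepwise AIC selection together with the two-category I-score.
    cutoffs : (cd3_cutoff, cd8_cutoff) from a discovery run; fitted on this
        cohort by maximally selected rank statistics when None.
    normalizers : score normalizers from a discovery run; fitted on this
        cohort when None (each cohort is normalized on its own scale by
        default).

    Subjects missing either marker density or survival data are excluded
    (complete-case) and listed in the report.
    """
    config = config or PipelineConfig()
    config.validate()
    merged = survival.merge(densities, on="subject_id", how="outer", indicator=True)
    complete = (
        (merged["_merge"] == "both")
        & merged["cd3_density"].notna()
        & merged["cd8_density"].notna()
        & merged["time"].notna()
        & merged["event"].notna()
    )
    excluded = merged.loc[~complete, "subject_id"].tolist()
    data = merged.loc[complete].drop(columns="_merge").reset_index(drop=True).copy()
    if len(data) < 10:
        raise ParameterError(f"only {len(data)} complete-case subjects; need >= 10")

    if normalizers is None:
        normalizers = {
            "CD3": ScoreNormalizer.fit(data["cd3_density"]),
            "CD8": ScoreNormalizer.fit(data["cd8_density"]),
        }
    data["cd3_score"] = normalizers["CD3"].transform(data["cd3_density"])
    data["cd8_score"] = normalizers["CD8"].transform(data["cd8_density"])

    if cutoffs is None:
        cd3_cut = maxstat_cutoff(
            data["cd3_score"], data["time"], data["event"],
            minprop=config.maxstat_minprop, maxprop=config.maxstat_maxprop,
            marker="CD3",
        ).cutoff
        cd8_cut = maxstat_cutoff(
            data["cd8_score"], data["time"], data["event"],
            minprop=config.maxstat_minprop, maxprop=config.maxstat_maxprop,
            marker="CD8",
        ).cutoff
    else:
        cd3_cut, cd8_cut = cutoffs

    data = assign_iscore_table(data, cd3_cut, cd8_cut)
    data["iscore2_high"] = (data["iscore2"] == "high").astype(float)

    report = CohortReport(
        subjects=data,
        cd3_cutoff=float(cd3_cut),
        cd8_cutoff=float(cd8_cut),
        normalizers=normalizers,
        excluded=excluded,
        config_hash=config.config_hash,
    )

    km_by_group = {}
    for name, grp in data.groupby("iscore2"):
        km_by_group[name] = kaplan_meier(grp["time"], grp["event"])
    report.logrank["km_iscore2"] = km_by_group
    if data["iscore2"].nunique() > 1:
        stat, p, df = logrank_test(data["iscore2"], data["time"], data["event"])
        report.logrank["iscore2"] = {"statistic": stat, "p": p, "df": df}
        report.iscore_fit = cox_fit(data, ["iscore2_high"])

    if covariates:
        candidates = screen_candidates(data, list(covariates) + ["iscore2_high"])
        report.screened = candidates
        if candidates:
            final = stepwise_aic(data, candidates)
            report.final_fit = final
            risk = final.risk_score()
            c, c_ci = harrell_cindex(
                risk, data["time"], data["event"], seed=config.seed
            )
            iauc, iauc_ci = integrated_auc(
                risk, data["time"], data["event"],
                n_boot=config.n_boot, seed=config.seed,
            )
            report.model_metrics["full"] = {
                "covariates": final.covariates,
                "c_index": c, "c_index_ci": c_ci,
                "iauc": iauc, "iauc_ci": iauc_ci,
                "aic": final.aic,
            }
            base_covs = [c_ for c_ in final.covariates if c_ != "iscore2_high"]
            if "iscore2_high" in final.covariates and base_covs:
                base = cox_fit(data, base_covs)
                lam, df, p = likelihood_ratio_test(base, final)
                report.model_metrics["lrt_vs_no_iscore"] = {
                    "statistic": lam, "df": df, "p": p, "aic_base": base.aic,
                }
    return report
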