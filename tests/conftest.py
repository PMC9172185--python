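import numpy as np
import pytest

from tilquant.cells import quantify_tile
from tilquant.synth import (
    CohortSpec,
    SyntheticTileSpec,
    generate_ihc_tile,
    generate_survival_cohort,
)


@pytest.fixture(scope="session")
def default_tile():
    """Reference synthetic tile (seed 7) with exact ground truth."""
    return generate_ihc_tile(SyntheticTileSpec(seed=7))


@pytest.fixture(scope="session")
def quantified_default_tile(default_tile):
    """(DensityRecord, LabelledCells, tissue mask) of the reference tile."""
    return quantify_tile(default_tile.image)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with a strong protective effect above score 50 (HR 0.25)."""
    return generate_survival_cohort(
        CohortSpec(n_subjects=300, hazard_ratio_high_vs_low=0.25, true_cutoff=50.0, seed=11)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no score effect (HR = 1)."""
    return generate_survival_cohort(
        CohortSpec(n_subjects=200, hazard_ratio_high_vs_low=1.0, seed=13)
    )


def brute_force_otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive-search Otsu oracle: try every split of a fixed-bin histogram.

    Independent of the cumulative-sum implementation: loops candidates and
    computes the between-class variance of each split directly.
    """
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centres = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_v = None, -1.0
    total = hist.sum()
    for t in range(nbins - 1):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            v = 0.0
        else:
            mu0 = (hist[: t + 1] * centres[: t + 1]).sum() / hist[: t + 1].sum()
            mu1 = (hist[t + 1 :] * centres[t + 1 :]).sum() / hist[t + 1 :].sum()
            v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-15:
            # upper edge of the last low bin: "value <= t" realizes the split
            best_v, best_t = v, edges[t + 1]
    return float(best_t)
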