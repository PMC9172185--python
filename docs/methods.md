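# Methods

This note documents the models and procedures `tilquant` implements, the
choices made where the design was open, and what the synthetic test-bed does
and does not establish about real data.

## Image model and stain separation

Brightfield IHC colour formation is modelled by Beer–Lambert absorbance:
a pixel with transmitted 8-bit intensity I has per-channel optical density
OD = −log₁₀((I + ε)/255), and the OD vector is a non-negative combination of
unit stain-absorbance vectors. The default stain matrix uses the classical
Ruifrok–Johnston H-DAB vectors (hematoxylin (0.650, 0.704, 0.286), DAB
(0.268, 0.570, 0.776)), with the residual channel as their unit cross
product; the matrix is configurable because scanners and staining batches
deviate. Unmixing is the linear inversion of that system with negative
concentrations clipped at zero; the residual channel is discarded.

## Tumour-region segmentation

Slides are block-mean downsampled by 16 (partial edge blocks averaged over
the pixels they contain), converted to HSV, and thresholded on saturation
with Otsu's method over a 256-bin histogram. Saturation is the
discriminative channel because unstained background and blank alveolar
cavities are near-white (S ≈ 0) while any stained tissue — even a faint
eosin wash — keeps measurable saturation. The threshold returned is the
upper edge of the last low-class bin, so "S ≤ t" reproduces the
variance-maximizing split exactly; ties break toward the smaller threshold.
An optional hue-range gate (off by default) can restrict the mask to
specific tissue hues. Morphological closing (disk radius 2 at the ×16
level) and small-object removal (< 64 px) stand in for the interactive
proofreading a pathologist would perform on real slides; both are
configuration, and the package makes no attempt to discriminate atelectasis
from tumour-associated stroma — on real material that judgement belongs to
a pathologist.

Tiling is a regular non-overlapping grid anchored at (0, 0) with half-open
1024-px extents; partial edge tiles are discarded, and a tile enters
analysis iff its tumour-mask fraction (nearest-neighbour-upsampled mask) is
at least 0.5, inclusive.

## Tile-level cell quantification

* **Background/blank removal.** SLIC superpixels (≈200 per tile,
  compactness 10) are clustered by k-means on mean RGB + mean saturation.
  Three clusters by default: stained nuclei form their own
  strongly-saturated cluster, so a two-way split would contrast nuclei
  against everything else rather than blank against tissue. A cluster is
  labelled background/blank iff it is bright and unsaturated (mean V > 0.88
  and mean S < 0.10); the absolute gate lets all-tissue and all-blank tiles
  resolve correctly instead of being force-split. k-means runs with a fixed
  seed, so masks are reproducible.
* **Dust macules.** Carbonaceous lung-tissue particles are dark and
  essentially grey; pixels with grayscale < 50/255 *and* RGB chroma
  (max − min) < 35 are masked out. The chroma gate keeps heavily DAB-stained
  brown pixels (strongly non-neutral) out of the dust mask. The threshold is
  configuration — the value used on the original slides is unpublished.
  Dust pixels are excluded from both the cell masks and the density
  denominator (an explicit choice; excluding them from the numerator only
  would inflate densities on dusty tiles).
* **Bernsen local thresholding** on the DAB OD channel: per pixel the local
  threshold is (local max + local min)/2 over a square window of half-width
  15 px; where the local contrast is below 0.08 OD the region counts as
  homogeneous and pixels are classified against a fixed mid-grey of
  0.15 OD. Foreground is *above* threshold (stain is bright in OD).
* **Watershed splitting.** Seeds are local maxima of the Euclidean distance
  transform at least 8 px apart (≈2 µm at 0.252 µm/px); watershed lines
  divide merged blobs; unseeded components keep a plain connected label.
* **Counting.** Objects of 100–5000 px² count as positive cells; the lower
  bound matches lymphocyte size at scanner resolution (5–10 µm diameter
  ≥ ~300 px² in-plane, so 100 px² also tolerates partially clipped nuclei)
  and the upper bound discards stain blotches. Density is
  count / (tissue_area_px · (mpp/1000)²) in cells/mm², where the tissue
  area is the tissue mask minus dust. Slide-level density re-divides the
  summed counts by the summed areas (area-weighted, not a mean of tiles).

## Scores, cutoffs, I-score

Densities are min–max scaled to [0, 100] within a cohort (the alternative,
percentile ranks, was rejected to keep density differences metric); new
subjects are scaled against the stored bounds and clamped. Normalization is
per cohort by default, mirroring a discovery→validation design in which the
validation cohort can instead be scored with the discovery normalizer and
cutoffs passed explicitly.

Cutoffs are maximally selected rank statistics: every observed score whose
empirical quantile lies in [0.1, 0.9] is a candidate split (score ≤ c vs
score > c); for each, the standardized log-rank statistic is computed with
hypergeometric variance (ties handled per event time); the cutoff
maximizing |S(c)| is returned, ties broken by the smaller cutoff. "High" is
strictly greater than the cutoff. No p-value correction is applied to the
selected cutoff. The estimator is unbiased but its argmax has sampling
spread of a few subject ranks around a step-effect threshold; simulations
here locate the median recovered cutoff on target at n = 300, while
exact-to-the-observation recovery occurs in roughly a third of replicates.

I-score: high iff CD3-high and CD8-high; low iff both low; intermediate
otherwise. The two-category score merges low + intermediate.

## Survival statistics

Cox models maximize the partial likelihood by Newton–Raphson with Efron tie
handling (lifelines); Wald 95 % CIs; AIC = −2·loglik + 2k. Candidate
covariates are screened univariably at P < 0.10, capped at
floor(events/10) predictors, and selected by bidirectional stepwise search
minimizing AIC from the full candidate model (deterministic given the
data). Discrimination: Harrell's C (concordant usable pairs over usable
pairs, risk ties 0.5; an event/censored tie in time counts the event as the
earlier failure) and the incident/dynamic AUC(t) at each event time,
integrated with Kaplan–Meier weights w(t) = 2·f(t)·S(t) over [0, max event
time]. Both carry subject-level bootstrap percentile CIs with fixed seeds;
the bootstrap resamples the integrated quantity itself (1000 replicates by
default). The likelihood-ratio test compares nested fits on identical
subjects. The proportional-hazards diagnostic is the Grambsch–Therneau
score test on scaled Schoenfeld residuals against the rank of event time,
per covariate and globally (df = number of covariates); per-covariate
statistics were verified to match lifelines' `proportional_hazard_test`
exactly.

Cohort-comparison and agreement statistics: Pearson chi-square without
continuity correction by default (Yates available for 2×2);
Mann–Whitney U two-sided (exact for small tie-free samples); linear-by-linear
association M² = (N−1)r² with default scores 1..r/1..c; Bland–Altman bias
± 1.96·SD of paired differences; ICC(2,1) (two-way random effects, absolute
agreement, single rater) with its F-based CI via pingouin. No
multiple-testing adjustment is applied anywhere.

## The synthetic test-bed

`tilquant.synth` renders the visual classes the pipeline must separate, at
desk scale (512×512 px, 0.252 µm/px): a white blank strip covering 20 % of
the tile (alveolar cavity), an eosin wash at OD 0.15 elsewhere (pink,
clearly saturated against blank, projecting only ≈0.02 onto the DAB
channel), 20 DAB-positive and 20 hematoxylin-only nuclei drawn as jittered
ellipses with radii 2.5–5 µm at exactly OD 1.0 of the matching stain
vector, two deliberately touching positive pairs (centre gap 1.8 r) to
exercise watershed, and 3 near-black irregular dust blobs 2–12 µm across.
Twenty positives per tile is ≈1500 cells/mm², a realistic infiltration
density, and close to the most that non-overlapping placement admits at
these nucleus sizes. Placement is rejection sampling with per-object
effective radii; overcrowded specs raise an error naming the offending
class. Survival cohorts draw scores U(0, 100), exponential event times with
a step hazard at the true cutoff (hazard ratio configurable, protective
defaults), exponential censoring truncated at 120 months, and Bernoulli(½)
binary covariates with specified log-hazard effects — event rates and
follow-up approximating a resected-NSCLC cohort (~0.01 events/month
baseline, ten-year horizon).

What passing tests show — and do not. The tiles have ideal stain
colorimetry (rendered with the very vectors the deconvolution inverts),
no uneven illumination, no focus blur, no folds, no overlapping
positive/negative nuclei, and nucleus-free wash texture. Perfect or
near-perfect counting here demonstrates the pipeline's logic (channel
separation, masking, splitting, unit conversion) is correct, not that the
default thresholds transfer to any particular scanner or stain batch; on
real material the stain vectors, Bernsen parameters and dust threshold are
the knobs to calibrate, and tumour masks need pathologist review.

## Numerical and degenerate-input conventions

Constant channels raise a degenerate-input error from Otsu (an all-white
slide reports "empty tumour"); equal densities cannot be scaled to 0–100;
zero tissue area is a division error, not a NaN; empty masks yield zero
labels; an all-censored cohort has no log-rank or Cox fit; reverse-KM
cohorts with no censoring signal an undefined median as `inf`. All
stochastic steps (k-means init, bootstraps, simulations) take explicit
seeds and are bit-reproducible. Problem sizes in the test suite and
acceptance script (60 tiles, cohorts of 150–500, 400 null replicates, 2048²
synthetic slides) were chosen so the whole battery runs in minutes on one
CPU while leaving Monte-Carlo margins well away from the assertion bounds.

## Known limitations

* The tumour/stroma distinction and slide-level quality control are out of
  scope; the segmentation is the thresholding stage of a semi-automated
  process.
* Nuclei are classified positive/non-positive only; no membrane vs nuclear
  localization.
* The 2×3 chi-square "with continuity correction" variant used for one
  published table (with a zero cell) is ambiguous and not implemented.
* iAUC follows the incident/dynamic definition with KM-derived weights;
  other weightings (e.g. cumulative/dynamic) give different absolute
  values.
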