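"""Marker scores, survival-optimal cutoffs, and the I-score categories.

Raw CD3+/CD8+ densities (cells/mm^2) are min-max normalized within a cohort
to 0-100 "scores".  Each score is dichotomized at the cutoff maximizing the
standardized two-sample log-rank statistic over all admissible candidate
splits (maximally selected rank statistics).  The I-score integrates the two
dichotomies: high iff both markers are high, low iff both are low,
intermediate otherwise; the two-category version merges low + intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CutoffError, DegenerateInputError, ParameterError


@dataclass
class ScoreNormalizer:
    """Min-max scaling of densities to [0, 100], frozen on a reference cohort.

    New subjects (e.g. a validation cohort scored against discovery bounds)
    are scaled with the stored (d_min, d_max) and clamped to [0, 100].
    """

    d_min: float
    d_max: float

    @classmethod
    def fit(cls, densities) -> "ScoreNormalizer":
        d = np.asarray(densities, dtype=float)
        if d.size < 2:
            raise ParameterError("need at least 2 subjects to normalize")
        if np.any(d < 0):
            raise ParameterError("densities must be non-negative")
        lo, hi = float(d.min()), float(d.max())
        if hi <= lo:
            raise DegenerateInputError("all densities equal; 0-100 scale is degenerate")
        return cls(d_min=lo, d_max=hi)

    def transform(self, densities) -> np.ndarray:
        d = np.asarray(densities, dtype=float)
        score = 100.0 * (d - self.d_min) / (self.d_max - self.d_min)
        return np.clip(score, 0.0, 100.0)


def normalize_scores(densities) -> np.ndarray:
    """Convenience: fit + transform on the same cohort."""
    return ScoreNormalizer.fit(densities).transform(densities)


@dataclass
class CutoffResult:
    """Output of the maximally-selected-rank-statistic scan."""

    marker: str
    cutoff: float
    max_statistic: float
    candidate_range: tuple[float, float]
    #: candidate scan trace: one row per candidate (cutoff, abs standardized stat)
    trace: pd.DataFrame = field(repr=False, default=None)


def logrank_z_at_split(scores, times, events, cutoff: float) -> float:
    """Standardized log-rank statistic for groups score <= cutoff vs > cutoff.

    Positive sign means the high-score group has fewer events than expected.
    Uses the hypergeometric variance with ties handled per event time.
    """
    z = _scan_statistics(
        np.asarray(scores, float),
        np.asarray(times, float),
        np.asarray(events, int),
        np.array([cutoff], dtype=float),
    )[0]
    return float(z)


def _scan_statistics(scores, times, events, cutoffs) -> np.ndarray:
    """Signed standardized log-rank statistic at each candidate cutoff.

    Vectorized over candidates: for each event time with d events and n at
    risk, the high group (score > c) contributes observed events o1 against
    expectation d*n1/n and hypergeometric variance; the statistic is
    (E - O)/sqrt(V) for the high group, so protective high groups score
    positive.  Candidates with zero variance return 0.
    """
    order = np.argsort(times, kind="stable")
    t, e, s = times[order], events[order], scores[order]
    n = len(t)
    high = s[None, :] > cutoffs[:, None]  # (n_cand, n) membership
    uniq = np.unique(t)
    U = np.zeros(len(cutoffs))
    V = np.zeros(len(cutoffs))
    for k, tk in enumerate(uniq):
        in_time = t == tk
        d = int(e[in_time].sum())
        if d == 0:
            continue
        at_risk = t >= tk
        n_risk = int(at_risk.sum())
        n1 = high[:, at_risk].sum(axis=1).astype(float)
        o1 = high[:, in_time & (e == 1)].sum(axis=1).astype(float)
        exp1 = d * n1 / n_risk
        if n_risk > 1:
            var = d * (n1 / n_risk) * (1 - n1 / n_risk) * (n_risk - d) / (n_risk - 1)
        else:
            var = np.zeros_like(n1)
        U += exp1 - o1
        V += var
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(V > 0, U / np.sqrt(V), 0.0)
    return z


def maxstat_cutoff(
    scores,
    times,
    events,
    minprop: float = 0.1,
    maxprop: float = 0.9,
    marker: str = "",
) -> CutoffResult:
    """Survival-optimal cutoff by maximally selected rank statistics.

    Every observed score value whose empirical quantile lies in
    [``minprop``, ``maxprop``] (and which leaves both groups non-empty) is a
    candidate split ``score <= c`` vs ``score > c``; the cutoff maximizing
    the absolute standardized log-rank statistic is returned, ties broken by
    the smaller cutoff.

    Raises
    ------
    CutoffError
        If fewer than 10 subjects, no admissible candidate, or no events.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (0 <= minprop < maxprop <= 1):
        raise ParameterError("need 0 <= minprop < maxprop <= 1")
    if len(scores) < 10:
        raise CutoffError("maximally selected rank statistics needs >= 10 subjects")
    if events.sum() < 1:
        raise CutoffError("no events; log-rank statistics are undefined")
    sorted_scores = np.sort(scores)
    n = len(scores)
    lo = sorted_scores[int(np.floor(minprop * (n - 1)))]
    hi = sorted_scores[int(np.ceil(maxprop * (n - 1)))]
    uniq = np.unique(scores)
    cand = uniq[(uniq >= lo) & (uniq <= hi) & (uniq < uniq.max())]
    if cand.size == 0:
        raise CutoffError(
            f"no admissible candidate cutoff in quantile range [{minprop}, {maxprop}]"
        )
    z = _scan_statistics(scores, times, events, cand)
    absz = np.abs(z)
    best = int(np.argmax(absz))  # first max = smallest cutoff on ties
    trace = pd.DataFrame({"cutoff": cand, "abs_statistic": absz, "statistic": z})
    return CutoffResult(
        marker=marker,
        cutoff=float(cand[best]),
        max_statistic=float(absz[best]),
        candidate_range=(float(lo), float(hi)),
        trace=trace,
    )


def classify_marker(score, cutoff: float):
    """High iff score is strictly greater than the cutoff."""
    return np.asarray(score, dtype=float) > cutoff


@dataclass
class IScoreCategory:
    """Per-subject I-score assignment from the two marker dichotomies."""

    subject_id: object
    cd3_high: bool
    cd8_high: bool
    three_cat: str
    two_cat: str


def assign_iscore(cd3_high: bool, cd8_high: bool, subject_id=None) -> IScoreCategory:
    """Integrate CD3/CD8 dichotomies into three- and two-category I-scores."""
    if cd3_high and cd8_high:
        three = "high"
    elif cd3_high or cd8_high:
        three = "intermediate"
    else:
        three = "low"
    return IScoreCategory(
        subject_id=subject_id,
        cd3_high=bool(cd3_high),
        cd8_high=bool(cd8_high),
        three_cat=three,
        two_cat="high" if three == "high" else "low",
    )


def assign_iscore_table(
    subjects: pd.DataFrame,
    cd3_cutoff: float,
    cd8_cutoff: float,
    cd3_col: str = "cd3_score",
    cd8_col: str = "cd8_score",
) -> pd.DataFrame:
    """Vectorized I-score assignment over a subject table.

    Adds ``cd3_high``, ``cd8_high``, ``iscore3`` and ``iscore2`` columns.
    """
    out = subjects.copy()
    out["cd3_high"] = classify_marker(out[cd3_col].to_numpy(), cd3_cutoff)
    out["cd8_high"] = classify_marker(out[cd8_col].to_numpy(), cd8_cutoff)
    both = out["cd3_high"] & out["cd8_high"]
    either = out["cd3_high"] | out["cd8_high"]
    out["iscore3"] = np.where(both, "high", np.where(either, "intermediate", "low"))
    out["iscore2"] = np.where(both, "high", "low")
    return out
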