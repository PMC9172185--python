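"""Survival analysis and model-comparison statistics.

Kaplan-Meier estimation, the reverse Kaplan-Meier median follow-up, log-rank
tests, Cox proportional-hazards regression (Newton-Raphson partial
likelihood with Efron tie handling, via lifelines) with univariable
candidate screening and bidirectional stepwise selection on AIC,
discrimination metrics (Harrell's C-index, incident/dynamic time-dependent
AUC integrated over follow-up), the likelihood-ratio test between nested
models, the Schoenfeld-residual proportional-hazards test, and the
cohort-comparison and agreement statistics (Pearson chi-square,
Mann-Whitney U, linear-by-linear association, Bland-Altman limits of
agreement, intraclass correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import DegenerateInputError, FitError, ParameterError

# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def kaplan_meier(times, events) -> KaplanMeierFitter:
    """Product-limit survival estimator (censored subjects leave the risk set)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size < 1:
        raise ParameterError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return kmf


def reverse_km_median_followup(times, events) -> tuple[float, tuple[float, float]]:
    """Median follow-up by the reverse Kaplan-Meier method.

    The event indicator is flipped (censoring becomes the "event") and the
    median of the resulting curve — the first time it drops to <= 0.5 — is
    the median follow-up.  Returns ``(median, (ci_low, ci_high))``; all three
    are ``inf`` when the curve never reaches 0.5 (the undefined-median
    signal, e.g. a cohort with no censoring).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1 - events)
    median = float(kmf.median_survival_time_)
    from lifelines.utils import median_survival_times

    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return median, (lo, hi)


def logrank_test(groups, times, events) -> tuple[float, float, int]:
    """Log-rank chi-square test across two or more groups.

    Returns ``(statistic, p, df)``.
    """
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise ParameterError("log-rank test needs at least 2 groups")
    if events.sum() < 1:
        raise ParameterError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value), n_groups - 1


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """A fitted Cox model: estimates, uncertainty, and model-fit summaries.

    ``summary`` has one row per covariate with columns ``coef``, ``se``,
    ``hr``, ``hr_ci_low``, ``hr_ci_high`` and ``p`` (Wald).  ``aic`` is
    ``-2 loglik + 2 k`` on the partial likelihood.
    """

    covariates: list[str]
    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    model: CoxPHFitter = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    time_col: str = "time"
    event_col: str = "event"

    @property
    def k(self) -> int:
        return len(self.covariates)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.k

    def risk_score(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Linear predictor x'beta (higher = higher hazard)."""
        df = self.data if data is None else data
        beta = self.summary["coef"].to_numpy()
        return df[self.covariates].to_numpy(dtype=float) @ beta

    def coefficient(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hazard_ratio(self, name: str) -> tuple[float, tuple[float, float], float]:
        row = self.summary.loc[name]
        return float(row["hr"]), (float(row["hr_ci_low"]), float(row["hr_ci_high"])), float(row["p"])


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    The partial likelihood is maximized by Newton-Raphson with Efron
    handling of tied event times; confidence intervals and p-values are
    Wald-based at the 95% level.

    Raises
    ------
    FitError
        No events, a constant covariate, or failed convergence.
    """
    if not covariates:
        raise ParameterError("need at least one covariate")
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ParameterError(f"covariates not in data: {missing}")
    events = data[event_col].to_numpy()
    if events.sum() < 1:
        raise FitError("no events in the data; the partial likelihood is flat")
    for c in covariates:
        if data[c].nunique() < 2:
            raise FitError(f"covariate {c!r} is constant; its effect is not identifiable")
    cph = CoxPHFitter()
    try:
        cph.fit(
            data[covariates + [time_col, event_col]],
            duration_col=time_col,
            event_col=event_col,
        )
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise FitError(f"Cox model failed to converge: {exc}") from exc
    summ = pd.DataFrame(
        {
            "coef": cph.params_,
            "se": cph.standard_errors_,
            "hr": np.exp(cph.params_),
            "hr_ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "hr_ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "p": cph.summary["p"],
        }
    )
    summ.index.name = "covariate"
    return CoxFit(
        covariates=list(covariates),
        summary=summ,
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(events.sum()),
        model=cph,
        data=data,
        time_col=time_col,
        event_col=event_col,
    )


def screen_candidates(
    data: pd.DataFrame,
    covariates: list[str],
    alpha: float = 0.10,
    time_col: str = "time",
    event_col: str = "event",
) -> list[str]:
    """Univariable screening: keep covariates with Wald p < ``alpha``.

    Covariates whose univariable model cannot be fitted are dropped.
    """
    kept = []
    for c in covariates:
        try:
            fit = cox_fit(data, [c], time_col=time_col, event_col=event_col)
        except FitError:
            continue
        if float(fit.summary.loc[c, "p"]) < alpha:
            kept.append(c)
    return kept


def stepwise_aic(
    data: pd.DataFrame,
    candidates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Bidirectional stepwise Cox selection minimizing AIC.

    Starts from the full candidate model; at each step considers dropping
    any current covariate or adding back any excluded candidate, takes the
    single move with the lowest AIC, and stops when no move improves it.
    Deterministic given the data and candidate order.  The AIC of every
    model visited is recorded on the returned fit as ``search_trace``.
    """
    if not candidates:
        raise ParameterError("stepwise selection needs a non-empty candidate set")

    cache: dict[tuple[str, ...], CoxFit | None] = {}

    def fit_subset(subset: tuple[str, ...]) -> CoxFit | None:
        if subset not in cache:
            try:
                cache[subset] = cox_fit(data, list(subset), time_col, event_col)
            except (FitError, ParameterError):
                cache[subset] = None
        return cache[subset]

    current = tuple(candidates)
    best = fit_subset(current)
    if best is None:
        raise FitError("the full candidate model could not be fitted")
    improved = True
    while improved:
        improved = False
        moves: list[tuple[str, ...]] = []
        for c in current:
            rem = tuple(x for x in current if x != c)
            if rem:
                moves.append(rem)
        for c in candidates:
            if c not in current:
                moves.append(current + (c,))
        for subset in moves:
            fit = fit_subset(subset)
            if fit is not None and fit.aic < best.aic - 1e-10:
                best, current, improved = fit, subset, True
        # greedy: accept the best single move, then rescan
    trace = pd.DataFrame(
        [
            {"covariates": ", ".join(k), "aic": v.aic}
            for k, v in cache.items()
            if v is not None
        ]
    )
    best.search_trace = trace  # type: ignore[attr-defined]
    return best


def max_candidate_predictors(n_events: int, epp: int = 10) -> int:
    """Events-per-predictor cap: at most floor(n_events / epp) candidates."""
    if epp <= 0:
        raise ParameterError("epp must be positive")
    if n_events < 0:
        raise ParameterError("n_events must be >= 0")
    return n_events // epp


# ---------------------------------------------------------------------------
# Discrimination: Harrell's C and integrated time-dependent AUC


def _concordance_pairs(risk, times, events):
    """(concordant + 0.5*ties, usable) over Harrell-usable pairs.

    A pair is usable when the shorter observed time is an event (an
    event/censored tie in time counts the event as the earlier failure);
    pairs tied in time with both events are not comparable.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(risk)
    num = 0.0
    usable = 0
    for i in range(n):
        if events[i] != 1:
            continue
        # i is an observed event: compare with everyone surviving past t_i
        later = (times > times[i]) | ((times == times[i]) & (events == 0))
        usable += int(later.sum())
        num += float((risk[i] > risk[later]).sum()) + 0.5 * float(
            (risk[i] == risk[later]).sum()
        )
    return num, usable


def harrell_cindex(
    risk,
    times,
    events,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance index with a bootstrap percentile 95% CI.

    Concordant usable pairs (higher risk fails earlier) over all usable
    pairs, ties in risk counted 0.5.  The CI resamples subjects with
    replacement ``n_boot`` times (seeded).
    """
    num, usable = _concordance_pairs(risk, times, events)
    if usable == 0:
        raise DegenerateInputError("no usable pairs for the concordance index")
    c = num / usable
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(risk)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bn, bu = _concordance_pairs(risk[idx], times[idx], events[idx])
        if bu > 0:
            boots.append(bn / bu)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = c
    return float(c), (float(lo), float(hi))


def _incident_dynamic_iauc(risk, times, events) -> float | None:
    """Incident/dynamic AUC(t) at each event time, KM-weight integrated.

    AUC(t): probability a subject failing at t out-ranks a subject still at
    risk beyond t (ties 0.5).  Weights follow Heagerty & Zheng:
    w(t) = 2 f(t) S(t) from the Kaplan-Meier estimate, normalized over the
    observed event times.  Returns None when degenerate (< 2 distinct event
    times or no weight).
    """
    event_times = np.unique(times[events == 1])
    if event_times.size < 2:
        return None
    kmf = KaplanMeierFitter().fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    s_at = surv.reindex(surv.index.union(event_times)).ffill().fillna(1.0)
    aucs, weights = [], []
    s_prev = 1.0
    for t in event_times:
        cases = (times == t) & (events == 1)
        controls = times > t
        s_t = float(s_at.loc[t])
        if controls.sum() > 0:
            rc = risk[cases][:, None]
            rk = risk[controls][None, :]
            auc = float((rc > rk).mean() + 0.5 * (rc == rk).mean())
            f_t = s_prev - s_t
            aucs.append(auc)
            weights.append(2.0 * f_t * s_t)
        s_prev = s_t
    weights = np.asarray(weights)
    if len(aucs) < 2 or weights.sum() <= 0:
        return None
    return float(np.average(aucs, weights=weights))


def integrated_auc(
    risk,
    times,
    events,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Integrated incident/dynamic AUC with a subject-bootstrap 95% CI.

    Raises
    ------
    DegenerateInputError
        Fewer than 2 distinct event times in the data.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    point = _incident_dynamic_iauc(risk, times, events)
    if point is None:
        raise DegenerateInputError("integrated AUC needs >= 2 distinct event times")
    rng = np.random.default_rng(seed)
    n = len(risk)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        b = _incident_dynamic_iauc(risk[idx], times[idx], events[idx])
        if b is not None:
            boots.append(b)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = point
    return float(point), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Model comparison and diagnostics


def likelihood_ratio_test(nested: CoxFit, full: CoxFit) -> tuple[float, int, float]:
    """LRT between nested Cox models: 2*(loglik_full - loglik_nested).

    Returns ``(statistic, df, p)`` with p from chi-square at df = parameter
    difference; identical models give (0, 0, 1).
    """
    if nested.n != full.n or nested.n_events != full.n_events:
        raise ParameterError("models were not fitted on identical subjects")
    if not set(nested.covariates) <= set(full.covariates):
        raise ParameterError("first model is not nested in the second")
    df = full.k - nested.k
    lam = max(0.0, 2.0 * (full.log_likelihood - nested.log_likelihood))
    if df == 0:
        return lam, 0, 1.0
    return float(lam), int(df), float(stats.chi2.sf(lam, df))


def schoenfeld_ph_test(fit: CoxFit) -> tuple[pd.DataFrame, float]:
    """Proportional-hazards test on scaled Schoenfeld residuals.

    Each covariate's scaled residuals are regressed on the rank of the event
    time (Grambsch-Therneau score test); returns a per-covariate table
    (columns ``chi2``, ``p``) and the global chi-square p-value (df = number
    of covariates).
    """
    if fit.n_events < 2:
        raise ParameterError("Schoenfeld test needs at least 2 events")
    cph: CoxPHFitter = fit.model
    resid = cph.compute_residuals(
        fit.data[fit.covariates + [fit.time_col, fit.event_col]],
        kind="schoenfeld",
    )
    # rows: event subjects, ordered by event time
    event_data = fit.data.loc[resid.index]
    t = event_data[fit.time_col].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    r = resid[fit.covariates].to_numpy(dtype=float)[order]
    g = stats.rankdata(t[order])
    g = g - g.mean()
    d = len(g)
    var_mat = cph.variance_matrix_.loc[fit.covariates, fit.covariates].to_numpy()
    # scaled residuals s* = d * V^{-1}_bar r = d * (information)^{-1} r * d
    s_star = d * (r @ var_mat)
    u = g @ s_star  # p-vector
    gss = float((g**2).sum())
    info = np.linalg.inv(var_mat)
    per = {}
    for j, name in enumerate(fit.covariates):
        # Var(u_j) = gss * [Vbar^{-1}]_jj with Vbar^{-1} = d * (information)^{-1}
        chi2 = u[j] ** 2 / (d * var_mat[j, j] * gss)
        per[name] = {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1))}
    global_chi2 = float(u @ info @ u) / (d * gss)
    global_p = float(stats.chi2.sf(global_chi2, fit.k))
    return pd.DataFrame(per).T, global_p


# ---------------------------------------------------------------------------
# Contingency-table and agreement statistics


def pearson_chi_square(
    table, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns ``(chi2, df, p)``; Yates continuity correction is available for
    2x2 tables.

    Raises
    ------
    DegenerateInputError
        If any row or column margin is zero.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ParameterError("need an r x c table with r, c >= 2")
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ParameterError("counts must be non-negative with a positive total")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise DegenerateInputError("a zero margin makes expected counts undefined")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=continuity_correction)
    return float(chi2), int(df), float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def linear_by_linear(
    table, row_scores=None, col_scores=None
) -> tuple[float, float]:
    """Linear-by-linear association (Mantel-Haenszel trend) test.

    ``M^2 = (N - 1) r^2`` where r is the count-weighted Pearson correlation
    of the ordinal row/column scores (defaults 1..r, 1..c); p from
    chi-square with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ParameterError("need an r x c table")
    r_sc = np.arange(1, obs.shape[0] + 1) if row_scores is None else np.asarray(row_scores, float)
    c_sc = np.arange(1, obs.shape[1] + 1) if col_scores is None else np.asarray(col_scores, float)
    n = obs.sum()
    if n <= 1:
        raise ParameterError("need a table total > 1")
    pr = obs.sum(axis=1) / n
    pc = obs.sum(axis=0) / n
    mr = float(r_sc @ pr)
    mc = float(c_sc @ pc)
    vr = float(((r_sc - mr) ** 2) @ pr)
    vc = float(((c_sc - mc) ** 2) @ pc)
    if vr <= 0 or vc <= 0:
        raise DegenerateInputError("zero variance in row or column scores")
    cov = float((r_sc - mr) @ (obs / n) @ (c_sc - mc))
    r = cov / math.sqrt(vr * vc)
    m2 = (n - 1) * r * r
    return float(m2), float(stats.chi2.sf(m2, 1))


@dataclass
class AgreementResult:
    """Bland-Altman limits of agreement plus the intraclass correlation."""

    bias: float
    loa_low: float
    loa_high: float
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None


def bland_altman(manual, automated) -> AgreementResult:
    """Bland-Altman agreement: bias = mean(manual - automated), LoA = +-1.96 SD."""
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.shape != automated.shape:
        raise ParameterError("paired vectors must have equal length")
    if manual.size < 2:
        raise ParameterError("Bland-Altman needs n >= 2 pairs")
    diff = manual - automated
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def icc(manual, automated) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Returns the coefficient and its F-based 95% CI.
    """
    import pingouin as pg

    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.shape != automated.shape or manual.size < 3:
        raise ParameterError("ICC needs paired vectors with n >= 3")
    if np.var(manual) + np.var(automated) == 0:
        raise DegenerateInputError("zero between-subject variance; ICC undefined")
    if np.array_equal(manual, automated):
        # perfect agreement: the F-based interval collapses
        return 1.0, (1.0, 1.0)
    n = manual.size
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["manual", "automated"], n),
            "value": np.concatenate([manual, automated]),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="value"
    ).set_index("Type")
    # single-rater absolute agreement, two-way random effects
    row = res.loc["ICC(A,1)"] if "ICC(A,1)" in res.index else res.loc["ICC2"]
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))


def agreement(manual, automated) -> AgreementResult:
    """Bland-Altman bias/LoA together with ICC(2,1) and its CI."""
    res = bland_altman(manual, automated)
    res.icc, res.icc_ci = icc(manual, automated)
    return res
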