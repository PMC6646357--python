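"""Survival and group-comparison statistics.

Kaplan-Meier estimation and the K-sample log-rank test delegate to lifelines;
univariate Cox regression maximizes the partial likelihood by Newton's method
with Breslow tie handling (Efron optional) and reports the hazard ratio with
a normal-approximation 95% CI. One-way ANOVA with Tukey's HSD post hoc test
is provided for group comparisons of continuous quantities (e.g. prognosis
score across tumor grades).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import EstimationError, UndefinedCorrelationError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times.

    Censored subjects sharing an event time remain at risk at that time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored_before: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value of the KM estimate at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest event time with survival <= 0.5 (inf if never reached)."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Univariate Cox fit: hr = exp(beta), ci95 = exp(beta -/+ 1.96 se)."""

    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    n: int
    n_events: int
    n_iter: int
    log_likelihood: float


@dataclass
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    #: (group_i, group_j, mean_diff, adjusted_p) for every unordered pair
    pairwise: list[tuple]


def kaplan_meier(os_months, event) -> KMCurve:
    """Kaplan-Meier curve from survival times and 0/1 event indicators."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise EstimationError("empty survival input")
    if np.any(t < 0):
        raise EstimationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    event_times = np.unique(t[e == 1])
    surv = np.array([float(kmf.predict(x)) for x in event_times])
    at_risk = np.array([int((t >= x).sum()) for x in event_times])
    n_events = np.array([int(((t == x) & (e == 1)).sum()) for x in event_times])
    cens_before = np.array([int(((t < x) & (e == 0)).sum()) for x in event_times])
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        n_censored_before=cens_before,
    )


def logrank_test(os_months, event, group) -> LogRankResult:
    """K-sample log-rank test (chi-square with K-1 degrees of freedom)."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise EstimationError("log-rank needs at least two groups")
    if e.sum() == 0:
        raise EstimationError("log-rank undefined with zero events")
    res = multivariate_logrank_test(t, g, e)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(levels) - 1,
        p_value=float(res.p_value),
    )


def _cox_loglik(beta: float, t, e, x, ties: str):
    """Breslow/Efron partial log-likelihood, score and information.

    Subjects sorted by descending time so the risk set at each event time is a
    prefix; cumulative sums give sum(w), sum(w x), sum(w x^2) over risk sets.
    """
    w = np.exp(beta * x)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    cwx2 = np.cumsum(w * x * x)
    ll = 0.0
    score = 0.0
    info = 0.0
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.arange(i, j)[e[i:j] == 1]
        d = ev.size
        if d:
            s = float(x[ev].sum())
            W, WX, WX2 = cw[j - 1], cwx[j - 1], cwx2[j - 1]
            ll += beta * s
            if ties == "breslow" or d == 1:
                mu = WX / W
                ll -= d * np.log(W)
                score += s - d * mu
                info += d * (WX2 / W - mu * mu)
            else:  # efron
                We = float(np.exp(beta * x[ev]).sum())
                WXe = float((np.exp(beta * x[ev]) * x[ev]).sum())
                WX2e = float((np.exp(beta * x[ev]) * x[ev] ** 2).sum())
                for k in range(d):
                    f = k / d
                    denom = W - f * We
                    num1 = WX - f * WXe
                    num2 = WX2 - f * WX2e
                    ll -= np.log(denom)
                    score += s / d - num1 / denom
                    info += num2 / denom - (num1 / denom) ** 2
        i = j
    return ll, score, info


def cox_univariate(
    os_months, event, covariate, ties: str = "breslow", max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Univariate Cox proportional-hazards regression.

    Newton iteration on the partial likelihood with step-halving; Breslow tie
    handling by default, Efron via ``ties="efron"``. Raises
    :class:`EstimationError` on < 2 events, a constant covariate,
    non-convergence, or runaway estimates (monotone likelihood / separation).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if int(e.sum()) < 2:
        raise EstimationError("Cox regression needs >= 2 events")
    if np.ptp(x) == 0:
        raise EstimationError("constant covariate")
    order = np.argsort(-t, kind="stable")
    t, e, xs = t[order], e[order], x[order]
    x_center = xs.mean()
    xs = xs - x_center  # centering stabilizes exp() without changing beta

    beta = 0.0
    ll, score, info = _cox_loglik(beta, t, e, xs, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if info <= 0:
            raise EstimationError("non-positive information (degenerate risk sets)")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_loglik(new_beta, t, e, xs, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:  # keep likelihood non-decreasing
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_loglik(new_beta, t, e, xs, ties)
            halvings += 1
        delta = new_beta - beta
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(beta) > 50:
            raise EstimationError("estimate diverged; possible perfect separation")
        if abs(delta) < tol:
            break
    else:
        raise EstimationError(f"no convergence in {max_iter} Newton iterations")
    if info <= 0:
        raise EstimationError("non-positive information at optimum")
    se = float(1.0 / np.sqrt(info))
    hr = float(np.exp(beta))
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=hr,
        ci95=(float(np.exp(beta - Z_95 * se)), float(np.exp(beta + Z_95 * se))),
        n=int(t.size),
        n_events=int(e.sum()),
        n_iter=n_iter,
        log_likelihood=float(ll),
    )


def score_os_association(scores, os_months) -> tuple[float, float, float, float]:
    """Pearson r, least-squares slope/intercept, and two-sided p for r.

    Quantifies how strongly the prognosis score tracks overall survival
    within a cohort.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(os_months, dtype=float)
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept), float(fit.pvalue)


def anova_tukey(values, group) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's HSD post hoc pairwise comparisons."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    v = np.asarray(values, dtype=float)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise EstimationError("ANOVA needs at least two groups")
    groups = [v[g == lv] for lv in levels]
    if any(len(arr) < 2 for arr in groups):
        raise EstimationError("every group needs at least two values")

    grand = v.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in groups)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in groups)
    pairs = [
        (levels[i], levels[j])
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
    ]
    if ss_within == 0 and ss_between == 0:
        # all observations identical: no variability to test
        pairwise = [(a, b, 0.0, 1.0) for a, b in pairs]
        return AnovaTukeyResult(f_stat=0.0, p_value=1.0, pairwise=pairwise)

    f_stat, p_value = stats.f_oneway(*groups)
    hsd = pairwise_tukeyhsd(v, g)
    uniq = list(hsd.groupsunique)
    pairwise = []
    idx = 0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            pairwise.append(
                (
                    uniq[i],
                    uniq[j],
                    float(hsd.meandiffs[idx]),
                    float(hsd.pvalues[idx]),
                )
            )
            idx += 1
    return AnovaTukeyResult(
        f_stat=float(f_stat), p_value=float(p_value), pairwise=pairwise
    )


def km_by_group(os_months, event, group) -> dict:
    """One :class:`KMCurve` per group level (insertion-ordered)."""
    t = np.asarray(os_months, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    return {
        lv: kaplan_meier(t[g == lv], e[g == lv])
        for lv in pd.unique(g)
        if (g == lv).sum() > 0
    }
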