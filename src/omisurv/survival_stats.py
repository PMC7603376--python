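"""Self-contained survival and association statistics.

The univariate Cox proportional-hazards screen, the Kaplan-Meier
product-limit estimator and the K-group log-rank test are implemented here
directly (Breslow convention for tied event times throughout, so that the
Cox score test at beta = 0 coincides with the log-rank statistic for a
binary covariate when event times are untied). Chi-square independence,
Pearson / point-biserial correlation, Welch's t and ROC AUC delegate to
scipy / scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score


@dataclass
class FeatureSurvivalAssoc:
    """Univariate Cox-PH association of one feature with survival."""

    category: str
    feature_id: str
    coef: float
    p_value: float
    n_used: int
    chi2: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.coef):
            raise ValueError(f"non-finite Cox coefficient for {self.feature_id}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1] for {self.feature_id}")


@dataclass
class SurvivalComparison:
    """Per-group Kaplan-Meier curves with the log-rank comparison."""

    group_sizes: dict
    km_curves: dict  # group -> (times, survival) arrays
    logrank_chi2: float
    p_value: float
    medians: dict = field(default_factory=dict)


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event indicators must be 0 or 1")
    return times, events


def _risk_set_sums(order_times, weights):
    """Reverse cumulative sums of `weights` over the risk set t_j >= t_i.

    `order_times` must be ascending; returns for each position i the sum of
    weights over every j whose time ties with or exceeds time at i.
    """
    rev = np.cumsum(weights[::-1])[::-1]
    first = np.searchsorted(order_times, order_times, side="left")
    return rev[first]


def coxph_univariate(
    feature,
    times,
    events,
    *,
    category: str = "",
    feature_id: str = "",
    test: str = "score",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> FeatureSurvivalAssoc:
    """Fit h(t) = h0(t) exp(beta x) by Breslow partial likelihood.

    The coefficient is estimated by Newton-Raphson; the reported p-value is
    by default the partial-likelihood SCORE test at beta = 0, which
    generalizes the log-rank test to continuous covariates and coincides
    with it for a binary one (in the absence of tied event times). Set
    ``test="wald"`` for the Wald test at the fitted coefficient.
    """
    x = np.asarray(feature, dtype=float)
    times, events = _check_surv(times, events)
    if x.shape != times.shape:
        raise ValueError("feature and survival vectors must have equal length")
    if np.std(x) == 0:
        raise ValueError(f"zero-variance feature {feature_id!r}")
    if events.sum() < 2:
        raise ValueError("need at least 2 events for Cox regression")
    if test not in ("score", "wald"):
        raise ValueError(f"unknown test {test!r}")

    order = np.argsort(times, kind="stable")
    t, d, xv = times[order], events[order], x[order]
    xv = xv - xv.mean()  # centring for numerical stability; beta invariant
    ev = d == 1

    def derivatives(beta):
        w = np.exp(beta * xv)
        s0 = _risk_set_sums(t, w)
        s1 = _risk_set_sums(t, w * xv)
        s2 = _risk_set_sums(t, w * xv * xv)
        m = s1 / s0
        loglik = np.sum(beta * xv[ev] - np.log(s0[ev]))
        score = np.sum(xv[ev] - m[ev])
        info = np.sum(s2[ev] / s0[ev] - m[ev] ** 2)
        return loglik, score, info

    # score test at beta = 0
    _, u0, i0 = derivatives(0.0)
    chi2_score = u0 * u0 / i0

    beta = 0.0
    loglik, score, info = derivatives(beta)
    for _ in range(max_iter):
        step = score / info
        # step-halving keeps the partial likelihood monotone
        for _ in range(30):
            cand = beta + step
            ll_new, sc_new, in_new = derivatives(cand)
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                break
            step /= 2.0
        beta, loglik, score, info = cand, ll_new, sc_new, in_new
        if abs(step) < tol:
            break

    if test == "score":
        chi2 = chi2_score
    else:
        chi2 = beta * beta * info  # Wald: (beta / se)^2
    p = float(sps.chi2.sf(chi2, df=1))
    return FeatureSurvivalAssoc(
        category=category,
        feature_id=feature_id,
        coef=float(beta),
        p_value=p,
        n_used=int(times.size),
        chi2=float(chi2),
    )


def km_estimate(times, events):
    """Kaplan-Meier product-limit estimator.

    Returns ``(grid, survival)`` where ``grid`` starts at 0 (S = 1) and then
    holds every distinct event time; ``survival`` is the right-continuous
    step value at each grid point. Samples censored exactly at an event time
    remain at risk for that event (censoring tie-broken after events).
    """
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, d = times[order], events[order]
    event_times = np.unique(t[d == 1])
    n = t.size
    grid = [0.0]
    surv = [1.0]
    s = 1.0
    for et in event_times:
        at_risk = np.sum(t >= et)
        deaths = np.sum((t == et) & (d == 1))
        s *= 1.0 - deaths / at_risk
        grid.append(float(et))
        surv.append(float(s))
    return np.array(grid), np.array(surv)


def km_median(times, events) -> float:
    """Smallest time at which the KM curve drops to 0.5 or below (inf if never)."""
    grid, surv = km_estimate(times, events)
    below = np.flatnonzero(surv <= 0.5)
    return float(grid[below[0]]) if below.size else float("inf")


def logrank_test(times_by_group, events_by_group):
    """K-group log-rank test.

    Standard observed-minus-expected chi-square with the hypergeometric
    variance (tie factor (n_j - d_j)/(n_j - 1)), K - 1 degrees of freedom.
    Returns ``(chi2, p_value)``.
    """
    groups = list(times_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ts, ds, gs = [], [], []
    for g, tg in enumerate(times_by_group):
        tg, eg = _check_surv(tg, events_by_group[g])
        if tg.size == 0:
            raise ValueError(f"group {g} is empty")
        ts.append(tg)
        ds.append(eg)
        gs.append(np.full(tg.size, g))
    t = np.concatenate(ts)
    d = np.concatenate(ds)
    g = np.concatenate(gs)
    if d.sum() == 0:
        raise ValueError("no events in any group")
    K = len(groups)
    event_times = np.unique(t[d == 1])
    oe = np.zeros(K)
    V = np.zeros((K, K))
    for et in event_times:
        at_risk = t >= et
        nj = at_risk.sum()
        dj = np.sum((t == et) & (d == 1))
        ngj = np.array([(at_risk & (g == k)).sum() for k in range(K)], dtype=float)
        ogj = np.array(
            [((t == et) & (d == 1) & (g == k)).sum() for k in range(K)], dtype=float
        )
        egj = dj * ngj / nj
        oe += ogj - egj
        if nj > 1:
            frac = ngj / nj
            tie = dj * (nj - dj) / (nj - 1.0)
            V += tie * (np.diag(frac) - np.outer(frac, frac))
    sub = slice(0, K - 1)
    chi2 = float(oe[sub] @ np.linalg.solve(V[sub, sub], oe[sub]))
    p = float(sps.chi2.sf(chi2, df=K - 1))
    return chi2, p


def compare_survival(times, events, labels) -> SurvivalComparison:
    """KM curves, medians and log-rank comparison across label groups."""
    times, events = _check_surv(times, events)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two groups to compare survival")
    curves, sizes, medians, tg, eg = {}, {}, {}, [], []
    for u in uniq:
        m = labels == u
        curves[u] = km_estimate(times[m], events[m])
        medians[u] = km_median(times[m], events[m])
        sizes[u] = int(m.sum())
        tg.append(times[m])
        eg.append(events[m])
    chi2, p = logrank_test(tg, eg)
    return SurvivalComparison(
        group_sizes=sizes, km_curves=curves, logrank_chi2=chi2, p_value=p,
        medians=medians,
    )


def chi2_independence(table):
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction; (r-1)(c-1) degrees of freedom. Returns
    ``(chi2, p_value)``.
    """
    tab = np.asarray(table)
    if tab.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("every row and column marginal must be positive")
    res = sps.chi2_contingency(tab, correction=False)
    return float(res.statistic), float(res.pvalue)


def assoc_stats(x, y, kind: str = "pearson"):
    """Association between two vectors: ``(statistic, p_value)``.

    kind = "pearson" (continuous-continuous), "point_biserial" (continuous x
    vs binary y; algebraically Pearson on the 0/1 coding) or "welch"
    (Welch's unequal-variance t comparing x between the two classes of y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if kind == "pearson":
        r, p = sps.pearsonr(x, y)
    elif kind == "point_biserial":
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("point-biserial needs binary y with both classes")
        r, p = sps.pointbiserialr(y.astype(int), x)
    elif kind == "welch":
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("welch needs a binary grouping with both classes")
        r, p = sps.ttest_ind(x[y == classes[0]], x[y == classes[1]], equal_var=False)
    else:
        raise ValueError(f"unknown association kind {kind!r}")
    return float(r), float(p)


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
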