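"""Patient-level scoring and the survival-analysis battery.

Per-patient scores are medians over the 10 per-ROI values (so even-count
medians are midpoints of the two central counts, which is why data-driven
thresholds such as 32.5 or 16.25 cells/HPF are half- or quarter-integers).
Ratio scores report the less abundant marker over the more abundant one,
scaled by 100.  Prognostic thresholds are found by a maximally selected
log-rank scan (the single-split reading of recursive partitioning), and
group differences / survival associations use the standard battery:
Mann-Whitney U, Kruskal-Wallis with Dunn's post hoc, Kaplan-Meier with
Greenwood confidence intervals, the log-rank test, and Cox proportional
hazards (Efron or Breslow ties, via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientScore",
    "Cutpoint",
    "KMCurve",
    "CoxFit",
    "patient_median_score",
    "marker_ratio",
    "classify_high_low",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "find_cutpoint",
    "cox_fit",
    "group_tests",
    "dunn_posthoc",
]


# ---------------------------------------------------------------------------
# scores

@dataclass
class PatientScore:
    patient_id: str
    name: str  # marker or "num/den" ratio name
    compartment: str
    value: float
    n_rois: int


def patient_median_score(count_table: pd.DataFrame, marker: str,
                         compartment: str) -> pd.DataFrame:
    """Median per-ROI count per patient (even count -> midpoint)."""
    sel = count_table[(count_table["marker"] == marker)
                      & (count_table["compartment"] == compartment)]
    if sel.empty:
        raise ValueError(f"no counts for {marker}/{compartment}")
    g = sel.groupby("patient_id")["count"]
    out = g.median().rename("value").reset_index()
    out["name"] = marker
    out["compartment"] = compartment
    out["n_rois"] = g.size().to_numpy()
    return out[["patient_id", "name", "compartment", "value", "n_rois"]]


def marker_ratio(count_table: pd.DataFrame, num_marker: str, den_marker: str,
                 compartment: str) -> pd.DataFrame:
    """Per-patient median of the per-ROI ratio 100 * num / den.

    The study convention puts the less abundant marker in the numerator;
    the caller chooses the orientation.  ROIs whose denominator count is 0
    are excluded and flagged; a patient with no usable ROI raises.
    """
    def pick(m):
        s = count_table[(count_table["marker"] == m)
                        & (count_table["compartment"] == compartment)]
        return s.set_index(["patient_id", "roi_id"])["count"]

    num, den = pick(num_marker), pick(den_marker)
    joined = pd.DataFrame({"num": num, "den": den}).dropna()
    if joined.empty:
        raise ValueError("markers share no ROIs")
    usable = joined[joined["den"] > 0]
    excluded = joined[joined["den"] == 0]
    rows = []
    for pid, grp in usable.groupby(level="patient_id"):
        ratio = 100.0 * grp["num"] / grp["den"]
        n_exc = len(excluded.loc[pid]) if pid in excluded.index.get_level_values(0) else 0
        rows.append({"patient_id": pid,
                     "name": f"{num_marker}/{den_marker}",
                     "compartment": compartment,
                     "value": float(np.median(ratio)),
                     "n_rois": len(grp),
                     "n_excluded": n_exc})
    missing = set(joined.index.get_level_values(0)) - {r["patient_id"] for r in rows}
    if missing:
        raise ValueError(
            f"denominator {den_marker} is zero in every ROI for {sorted(missing)}")
    return pd.DataFrame(rows)


def classify_high_low(value, cutpoint: float):
    """'high' iff value >= cutpoint (the study's ">=" convention)."""
    arr = np.asarray(value, float)
    out = np.where(arr >= cutpoint, "high", "low")
    return out.item() if np.isscalar(value) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood variance and log-log CI."""
    event_times: np.ndarray   # unique event times, ascending
    survival: np.ndarray      # S(t) just after each event time
    variance: np.ndarray      # Greenwood Var[S(t)]
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier estimate of the survival function.

    The 95% CI is computed on the log(-log S) scale (and therefore stays
    inside [0, 1]); Greenwood's formula supplies the variance.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.shape != e.shape:
        raise ValueError("times and events differ in length")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = len(t)
    uniq = np.unique(t[e == 1])
    surv, var, lo, hi = [], [], [], []
    s = 1.0
    green = 0.0
    z = stats.norm.ppf(1 - alpha / 2)
    for u in uniq:
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (e == 1))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            green += d / (at_risk * (at_risk - d))
        v = s**2 * green
        surv.append(s)
        var.append(v)
        if 0.0 < s < 1.0:
            # exponential Greenwood ("log-log") interval
            se_cll = np.sqrt(green) / abs(np.log(s))
            lo.append(s ** np.exp(z * se_cll))
            hi.append(s ** np.exp(-z * se_cll))
        else:
            lo.append(s)
            hi.append(s)
    return KMCurve(event_times=uniq, survival=np.array(surv),
                   variance=np.array(var), ci_low=np.array(lo),
                   ci_high=np.array(hi), n=n)


def survival_at(curve: KMCurve, t: float):
    """S(t) and its CI from the step function (right-continuous)."""
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0, (1.0, 1.0)
    return (float(curve.survival[idx]),
            (float(curve.ci_low[idx]), float(curve.ci_high[idx])))


# ---------------------------------------------------------------------------
# log-rank

def _logrank_stat(times, events, group):
    """O-E and hypergeometric variance for group 1 (vectorized)."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(group, int)
    uniq = np.unique(t[e == 1])
    # at-risk counts per unique event time, overall and in group 1
    n_at = (t[None, :] >= uniq[:, None]).sum(axis=1)
    n1_at = ((t[None, :] >= uniq[:, None]) & (g[None, :] == 1)).sum(axis=1)
    d = ((t[None, :] == uniq[:, None]) & (e[None, :] == 1)).sum(axis=1)
    d1 = ((t[None, :] == uniq[:, None]) & (e[None, :] == 1)
          & (g[None, :] == 1)).sum(axis=1)
    exp1 = d * n1_at / n_at
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = np.where(n_at > 1,
                        d * (n1_at / n_at) * (1 - n1_at / n_at)
                        * (n_at - d) / (n_at - 1), 0.0)
    return float((d1 - exp1).sum()), float(var1.sum())


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test; returns (chi2, p).

    Degenerate comparisons (no events, or zero hypergeometric variance)
    return chi2 = 0, p = 1.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])
    o_minus_e, v = _logrank_stat(times, events, group)
    if v <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# maximally selected cutpoint

@dataclass
class Cutpoint:
    threshold: float
    chi2: float
    p: float
    n_high: int
    n_low: int


def find_cutpoint(scores, times, events,
                  min_group_frac: float = 0.15) -> Cutpoint:
    """Maximally selected log-rank split of a continuous score.

    Scans the midpoints between consecutive sorted unique score values,
    keeps splits where both groups hold at least ``min_group_frac`` of the
    cohort, and returns the threshold maximizing the log-rank statistic
    (ties broken toward the lowest threshold).  "High" means
    score >= threshold.  The reported p is the naive log-rank p at the
    selected split, not adjusted for the scan.
    """
    s = np.asarray(scores, float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct score values")
    mids = (uniq[:-1] + uniq[1:]) / 2
    n = len(s)
    best = None
    for thr in mids:
        high = s >= thr
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group_frac * n:
            continue
        o_minus_e, v = _logrank_stat(t, e, high.astype(int))
        if v <= 0:
            continue
        chi2 = o_minus_e**2 / v
        if best is None or chi2 > best[1]:
            best = (thr, chi2, n_high)
    if best is None:
        raise ValueError("no admissible split satisfies the group-size "
                         "constraint")
    thr, chi2, n_high = best
    return Cutpoint(threshold=float(thr), chi2=float(chi2),
                    p=float(stats.chi2.sf(chi2, df=1)),
                    n_high=n_high, n_low=n - n_high)


# ---------------------------------------------------------------------------
# Cox regression

@dataclass
class CoxFit:
    """Wald summary of a Cox proportional-hazards fit."""
    variables: list
    coef: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    ties: str
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.variables, "coef": self.coef,
                             "HR": self.hr, "ci_low": self.ci_low,
                             "ci_high": self.ci_high, "p": self.p})


def cox_fit(covariates: pd.DataFrame, times, events,
            ties: str = "efron") -> CoxFit:
    """Cox PH maximum partial likelihood (statsmodels PHReg).

    ``covariates`` is a numeric DataFrame (one column per variable; encode
    categorical levels as indicators, which makes re-coding the reference
    level equivalent to negating the coefficient).  Monotone likelihood
    (complete separation) is flagged via ``converged=False`` rather than
    raised.
    """
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X = covariates.to_numpy(float)
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    model = PHReg(t, X, status=e, ties=ties)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        res = model.fit(disp=False)
    coef = np.asarray(res.params, float)
    se = np.asarray(res.bse, float)
    converged = bool(np.all(np.isfinite(coef)) and np.all(np.isfinite(se))
                     and np.all(np.abs(coef) < 50) and np.all(se < 1e3))
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        return CoxFit(variables=list(covariates.columns), coef=coef,
                      hr=np.exp(coef), ci_low=np.exp(coef - z * se),
                      ci_high=np.exp(coef + z * se),
                      p=2 * stats.norm.sf(np.abs(coef) / se), ties=ties,
                      converged=converged)


# ---------------------------------------------------------------------------
# group comparisons

def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt(S2 * (1/n_i + 1/n_j)) with the
    tie-corrected S2 = (N(N+1)/12) - sum(t^3 - t) / (12 (N - 1)); two-sided
    normal p-values, Bonferroni-adjusted over the pairs by default.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    ranks = stats.rankdata(v)
    n_total = len(v)
    _, tie_counts = np.unique(v, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term
    mean_rank = {lv: ranks[g == lv].mean() for lv in levels}
    sizes = {lv: int((g == lv).sum()) for lv in levels}
    rows = []
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        se = np.sqrt(s2 * (1 / sizes[a] + 1 / sizes[b]))
        zstat = (mean_rank[a] - mean_rank[b]) / se
        p = 2 * stats.norm.sf(abs(zstat))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": zstat, "p": p,
                     "p_adj": p_adj})
    return pd.DataFrame(rows)


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None


def group_tests(values, groups) -> GroupTestResult:
    """Two groups -> Mann-Whitney U; three or more -> Kruskal-Wallis with
    Dunn's multiple-comparison post hoc.

    Mann-Whitney uses scipy's exact null distribution where feasible
    (small samples, no ties), otherwise the tie-corrected normal
    approximation.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [v[g == lv] for lv in levels]
    if len(levels) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided", method="auto")
        return GroupTestResult("mann-whitney", float(res.statistic),
                               float(res.pvalue))
    stat, p = stats.kruskal(*samples)
    return GroupTestResult("kruskal-wallis", float(stat), float(p),
                           posthoc=dunn_posthoc(values, groups))
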