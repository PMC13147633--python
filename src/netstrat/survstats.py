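"""Survival estimation and cluster-characterisation statistics.

Kaplan-Meier curves, the two-group log-rank test and Cox proportional
hazards (Efron tie handling) are delegated to lifelines; the
cluster-vs-response statistics (hypergeometric composition, majority-mapping
accuracy, Mann-Whitney per-variable comparisons, Fisher/Wilcoxon baseline
balance) are implemented here.  Times are in months; event = 1 marks death,
0 censoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .corrnet import bh_adjust
from .enrich import hypergeom_upper

__all__ = [
    "KMEstimate",
    "CoxFit",
    "km_curve",
    "logrank_test",
    "cox_ph",
    "cluster_enrichment",
    "cluster_accuracy",
    "compare_clusters",
    "baseline_balance",
    "fisher_exact_2xk",
]


@dataclass
class KMEstimate:
    times: np.ndarray           # distinct observed times, sorted
    survival: np.ndarray        # S(t) immediately after each time
    n_risk: np.ndarray
    n_events: np.ndarray
    median: float | None        # first t with S(t) <= 0.5; None if never

    def step_function(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "n_risk": self.n_risk, "n_events": self.n_events}
        )


@dataclass
class CoxFit:
    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    converged: bool
    flagged: str | None = None   # non-None explains a suspect fit
    n: int = 0
    n_events: int = 0


# ---------------------------------------------------------------------------
# estimation


def _check_times(times):
    times = np.asarray(times, float)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times <= 0) or np.any(~np.isfinite(times)):
        raise ValueError("survival times must be positive and finite")
    return times


def km_curve(times, events) -> KMEstimate:
    """Product-limit (Kaplan-Meier) estimate of the survival function.

    The median is the smallest observed time with S(t) <= 0.5 and is None
    when the curve never reaches 0.5 (heavy censoring).
    """
    times = _check_times(times)
    events = np.asarray(events, int)
    if events.shape != times.shape:
        raise ValueError("times and events must have equal length")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    uniq = np.unique(times)
    n = len(times)
    at_risk, deaths, surv = [], [], []
    s = 1.0
    for t in uniq:
        r = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / r
        at_risk.append(r)
        deaths.append(d)
        surv.append(s)
    surv = np.asarray(surv)
    median = None
    below = np.where(surv <= 0.5 + 1e-12)[0]
    if below.size:
        median = float(uniq[below[0]])
    return KMEstimate(
        times=uniq,
        survival=surv,
        n_risk=np.asarray(at_risk),
        n_events=np.asarray(deaths),
        median=median,
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p, 1 df)."""
    times = _check_times(times)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {list(labels)}")
    if any(np.sum(groups == l) == 0 for l in labels):
        raise ValueError("both groups must be non-empty")
    from lifelines.statistics import logrank_test as _lr

    mask = groups == labels[0]
    res = _lr(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    table: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_months",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling and Wald CIs.

    Categorical covariates are expanded to reference-level dummies (first
    level alphabetically is the reference).  Non-convergence or complete
    separation flags the fit instead of failing silently.
    """
    if table[event_col].sum() < 1:
        raise ValueError("need at least one event")
    df = table[[time_col, event_col]].copy()
    for c in covariates:
        col = table[c]
        if col.dtype.kind in "ifu":
            df[c] = col.astype(float)
        else:
            dummies = pd.get_dummies(
                col.astype("category"), prefix=c, drop_first=True, dtype=float
            )
            df = pd.concat([df, dummies], axis=1)
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    flagged = None
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col=time_col, event_col=event_col)
        for w in caught:
            msg = str(w.message).lower()
            if "convergence" in msg or "separation" in msg or "collinear" in msg:
                flagged = str(w.message)
    except ConvergenceError as err:
        raise_df = df.drop(columns=[time_col, event_col])
        return CoxFit(
            coefficients=pd.Series(np.nan, index=raise_df.columns),
            hazard_ratios=pd.Series(np.nan, index=raise_df.columns),
            ci_lower=pd.Series(np.nan, index=raise_df.columns),
            ci_upper=pd.Series(np.nan, index=raise_df.columns),
            p=pd.Series(np.nan, index=raise_df.columns),
            converged=False,
            flagged=str(err),
            n=len(df),
            n_events=int(table[event_col].sum()),
        )
    summ = cph.summary
    return CoxFit(
        coefficients=summ["coef"],
        hazard_ratios=summ["exp(coef)"],
        ci_lower=summ["exp(coef) lower 95%"],
        ci_upper=summ["exp(coef) upper 95%"],
        p=summ["p"],
        converged=converged,
        flagged=flagged,
        n=len(df),
        n_events=int(table[event_col].sum()),
    )


# ---------------------------------------------------------------------------
# cluster characterisation


def _two_cluster_tables(assignment, labels):
    """Align a patient->cluster mapping with a patient->binary-label mapping."""
    assignment = pd.Series(assignment)
    labels = pd.Series(labels)
    common = assignment.index.intersection(labels.index)
    if len(common) != len(assignment) or len(common) != len(labels):
        raise ValueError("assignment and labels must cover the same patients")
    return assignment.loc[common], labels.loc[common]


def cluster_enrichment(
    assignment, response_labels, convention: str = "ge"
) -> pd.DataFrame:
    """Per-cluster hypergeometric over-representation of its majority label.

    For each cluster (n members, k of its majority label; K carriers of that
    label among all N patients) the one-sided upper tail P(X >= k) is
    reported.  ``convention='gt'`` uses the strict tail P(X > k) instead;
    both conventions appear in the literature for composition tests.
    """
    if convention not in ("ge", "gt"):
        raise ValueError("convention must be 'ge' or 'gt'")
    assignment, labels = _two_cluster_tables(assignment, response_labels)
    label_values = sorted(labels.unique())
    if len(label_values) != 2:
        raise ValueError(f"labels must be binary, got {label_values}")
    N = len(labels)
    rows = []
    for cl in sorted(assignment.unique()):
        members = labels[assignment == cl]
        n = len(members)
        counts = members.value_counts()
        majority = counts.idxmax()
        k = int(counts.max())
        K = int((labels == majority).sum())
        if convention == "ge":
            p = hypergeom_upper(k, K, n, N)
        else:
            p = hypergeom_upper(k + 1, K, n, N) if k < min(n, K) else 0.0
        rows.append(
            {"cluster": cl, "n": n, "majority_label": majority,
             "n_majority": k, "n_other": int(n - k),
             "K_majority_total": K, "N": N, "p": p}
        )
    return pd.DataFrame(rows)


def cluster_accuracy(assignment, response_labels):
    """Accuracy of a 2-cluster assignment against binary labels under the
    better of the two cluster->label mappings (majority mapping).

    Returns (accuracy, confusion 2x2 DataFrame, mapping dict).
    """
    assignment, labels = _two_cluster_tables(assignment, response_labels)
    clusters = sorted(assignment.unique())
    label_values = sorted(pd.unique(labels))
    if len(clusters) != 2:
        raise ValueError(f"exactly 2 clusters required, got {len(clusters)}")
    if len(label_values) != 2:
        raise ValueError(f"labels must be binary, got {label_values}")
    best = None
    for mapping in (
        {clusters[0]: label_values[0], clusters[1]: label_values[1]},
        {clusters[0]: label_values[1], clusters[1]: label_values[0]},
    ):
        pred = assignment.map(mapping)
        acc = float((pred == labels).mean())
        if best is None or acc > best[0]:
            best = (acc, mapping)
    acc, mapping = best
    pred = assignment.map(mapping)
    confusion = pd.crosstab(
        pred.rename("predicted"), labels.rename("actual")
    ).reindex(index=label_values, columns=label_values, fill_value=0)
    return acc, confusion, mapping


def compare_clusters(variables: pd.DataFrame, assignment) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per variable between two clusters, BH over
    the variable family.

    Exact enumeration is used when both groups have <= 10 samples and there
    are no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    assignment = pd.Series(assignment)
    variables = variables.loc[assignment.index]
    clusters = sorted(assignment.unique())
    if len(clusters) != 2:
        raise ValueError(f"exactly 2 clusters required, got {len(clusters)}")
    a_idx = assignment[assignment == clusters[0]].index
    b_idx = assignment[assignment == clusters[1]].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each cluster needs at least 2 samples")
    rows = []
    for var in variables.columns:
        x = variables.loc[a_idx, var].to_numpy(float)
        y = variables.loc[b_idx, var].to_numpy(float)
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if len(x) <= 10 and len(y) <= 10 and not ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            )
        rows.append({"variable": var, "U": float(res.statistic),
                     "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2 x k contingency table, k <= 3, by
    full enumeration of tables with the observed margins (probability-based
    two-sided rule: sum P over tables no more probable than the observed)."""
    table = np.asarray(table, int)
    if table.shape[0] != 2 or table.shape[1] > 3:
        raise ValueError("table must be 2 x k with k <= 3")
    if table.shape[1] == 2:
        return float(stats.fisher_exact(table)[1])
    row = table.sum(axis=1)
    col = table.sum(axis=0)

    def log_prob(first_row):
        # multivariate hypergeometric mass of the table with this first row
        lp = 0.0
        for j, c in enumerate(col):
            lp += math.lgamma(c + 1) - math.lgamma(first_row[j] + 1) \
                  - math.lgamma(c - first_row[j] + 1)
        lp += math.lgamma(row[0] + 1) + math.lgamma(row[1] + 1) \
              - math.lgamma(row.sum() + 1)
        return lp

    obs = log_prob(table[0])
    total = 0.0
    p = 0.0
    r0 = row[0]
    for a in range(min(r0, col[0]) + 1):
        for b in range(min(r0 - a, col[1]) + 1):
            c = r0 - a - b
            if c > col[2]:
                continue
            lp = log_prob((a, b, c))
            pr = math.exp(lp)
            total += pr
            if lp <= obs + 1e-9:
                p += pr
    return float(min(p / total, 1.0))


def baseline_balance(
    clinical: pd.DataFrame,
    assignment,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Between-cluster balance tests for baseline covariates.

    Categorical covariates use the two-sided Fisher exact test (full
    enumeration for 2 and 3 levels, chi-square fallback flagged beyond);
    continuous ones use the Wilcoxon rank-sum test.  Levels absent from the
    data are dropped with a warning.
    """
    assignment = pd.Series(assignment)
    clinical = clinical.loc[assignment.index]
    clusters = sorted(assignment.unique())
    if len(clusters) != 2:
        raise ValueError("exactly 2 clusters required")
    if categorical is None and continuous is None:
        categorical = [
            c for c in clinical.columns
            if clinical[c].dtype == object or clinical[c].nunique() <= 4
        ]
        continuous = [c for c in clinical.columns if c not in categorical]
    categorical = categorical or []
    continuous = continuous or []
    rows = []
    mask = (assignment == clusters[0]).to_numpy()
    for c in categorical:
        col = clinical[c]
        levels = [l for l in pd.unique(col) if pd.notna(l)]
        counts = np.array(
            [
                [(col[mask] == l).sum() for l in levels],
                [(col[~mask] == l).sum() for l in levels],
            ],
            int,
        )
        keep = counts.sum(axis=0) > 0
        if not keep.all():
            warnings.warn(f"{c}: dropping empty level(s)", stacklevel=2)
            counts = counts[:, keep]
        if counts.shape[1] < 2:
            rows.append({"covariate": c, "test": "fisher", "statistic": np.nan,
                         "p": 1.0, "note": "single level"})
            continue
        if counts.shape[1] <= 3:
            p = fisher_exact_2xk(counts)
            rows.append({"covariate": c, "test": "fisher",
                         "statistic": np.nan, "p": p, "note": ""})
        else:
            chi2, p, _, _ = stats.chi2_contingency(counts)
            rows.append({"covariate": c, "test": "chi2-fallback",
                         "statistic": float(chi2), "p": float(p),
                         "note": ">3 levels: chi-square approximation"})
    for c in continuous:
        x = clinical.loc[mask, c].astype(float)
        y = clinical.loc[~mask, c].astype(float)
        stat, p = stats.ranksums(x, y)
        rows.append({"covariate": c, "test": "wilcoxon",
                     "statistic": float(stat), "p": float(p), "note": ""})
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p", "note"])
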