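"""Cohort-level statistics: group comparisons and correlations.

Lesion CBV/FA observations arrive as many slices or lesions per
subject, so the headline group comparison is a population-average
("marginal") regression: ordinary least squares of the measurement on
group membership with cluster-robust (subject-clustered sandwich)
standard errors, referenced against a t distribution with
(clusters - 2) degrees of freedom to respect the small number of
subjects.  A plain two-sample t-test is reported alongside.  Normality
is screened with Shapiro-Wilk; a rank-based (Mann-Whitney) comparison
is computed as the nonparametric fallback.  Associations between
per-subject quantities (lesion load, ventricle volumes, EDSS) use the
Pearson correlation with its two-sided test and the fitted line for
plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "compare_groups",
    "correlate",
    "summarize_relations",
    "holm_adjust",
]


def _inv_sqrt_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 1e-12, None)
    return (v / np.sqrt(w)) @ v.T


def _cr2_se(x: np.ndarray, resid: np.ndarray, clusters: np.ndarray) -> float:
    """Bias-reduced (CR2) cluster-robust standard error of the group
    coefficient: each cluster's residuals are rescaled by
    ``(I - H_gg)^{-1/2}`` before entering the sandwich, which removes
    the downward bias of the plain estimator with few clusters.
    """
    xtxi = np.linalg.inv(x.T @ x)
    meat = np.zeros((x.shape[1], x.shape[1]))
    for g in np.unique(clusters):
        m = clusters == g
        xg = x[m]
        hg = xg @ xtxi @ xg.T
        ag = _inv_sqrt_psd(np.eye(int(m.sum())) - hg)
        u = xg.T @ (ag @ resid[m])
        meat += np.outer(u, u)
    cov = xtxi @ meat @ xtxi
    return float(np.sqrt(cov[1, 1]))


@dataclass
class ComparisonResult:
    group_means: dict[str, float]
    group_se: dict[str, float]
    difference: float  # second group minus first (alphabetical)
    se_clustered: float
    p_clustered: float
    p_naive: float
    n_obs: int
    n_clusters: int
    df_clustered: int
    degenerate: bool = False
    shapiro_p: dict[str, float] = field(default_factory=dict)
    p_rank: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_clustered <= 0.05


def compare_groups(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    subjects: np.ndarray | pd.Series,
    reference: str | None = None,
) -> ComparisonResult:
    """Two-group comparison with subject clustering.

    ``values`` are the per-slice / per-lesion measurements, ``groups``
    the two-level group labels, ``subjects`` the subject identifiers
    used as clusters.  ``difference`` is the non-reference group mean
    minus the ``reference`` group mean (first sorted level when not
    given).  The clustered sandwich test is the headline result; the
    naive t-test and a Mann-Whitney fallback are attached.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float),
         "g": np.asarray(groups),
         "s": np.asarray(subjects)}
    ).dropna(subset=["y"])
    levels = sorted(pd.unique(df["g"]))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    for lev in levels:
        if df.loc[df["g"] == lev, "s"].nunique() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 subject clusters")

    if reference is None:
        g0, g1 = levels
    else:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not among groups {levels}")
        g0 = reference
        g1 = levels[1] if levels[0] == reference else levels[0]
    y0 = df.loc[df["g"] == g0, "y"].to_numpy()
    y1 = df.loc[df["g"] == g1, "y"].to_numpy()
    means = {g0: float(y0.mean()), g1: float(y1.mean())}
    ses = {g0: float(y0.std(ddof=1) / np.sqrt(len(y0))) if len(y0) > 1 else 0.0,
           g1: float(y1.std(ddof=1) / np.sqrt(len(y1))) if len(y1) > 1 else 0.0}
    n_clusters = int(df["s"].nunique())
    diff = means[g1] - means[g0]

    if np.allclose(df["y"].to_numpy(), df["y"].iloc[0]):
        return ComparisonResult(
            group_means=means, group_se=ses, difference=0.0,
            se_clustered=0.0, p_clustered=1.0, p_naive=1.0,
            n_obs=len(df), n_clusters=n_clusters,
            df_clustered=max(n_clusters - 2, 1), degenerate=True,
        )

    x = sm.add_constant((df["g"] == g1).astype(float).to_numpy())
    fit = sm.OLS(df["y"].to_numpy(), x).fit()
    se_cl = _cr2_se(x, fit.resid, df["s"].to_numpy())
    dof = max(n_clusters - 2, 1)
    tval = float(fit.params[1] / se_cl) if se_cl > 0 else 0.0
    p_cl = float(2.0 * sps.t.sf(abs(tval), dof))

    p_naive = float(sps.ttest_ind(y1, y0, equal_var=False).pvalue)
    shapiro = {}
    for lev, y in ((g0, y0), (g1, y1)):
        if 3 <= len(y) <= 5000 and np.ptp(y) > 0:
            shapiro[lev] = float(sps.shapiro(y).pvalue)
    try:
        p_rank = float(sps.mannwhitneyu(y1, y0, alternative="two-sided").pvalue)
    except ValueError:
        p_rank = float("nan")

    return ComparisonResult(
        group_means=means, group_se=ses, difference=diff,
        se_clustered=se_cl, p_clustered=p_cl, p_naive=p_naive,
        n_obs=len(df), n_clusters=n_clusters, df_clustered=dof,
        shapiro_p=shapiro, p_rank=p_rank,
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with its two-sided test and regression line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    lr = sps.linregress(x, y)
    return CorrelationResult(
        r=float(lr.rvalue), p=float(lr.pvalue),
        slope=float(lr.slope), intercept=float(lr.intercept), n=len(x),
    )


@dataclass
class RelationPercentages:
    n_active: int
    overlapping: float
    adjacent: float
    independent: float
    defined: bool

    def rounded(self) -> dict[str, int]:
        """Nearest-integer percentages (may not sum to exactly 100)."""
        return {
            "overlapping": round(self.overlapping),
            "adjacent": round(self.adjacent),
            "independent": round(self.independent),
        }


def summarize_relations(tables) -> RelationPercentages:
    """Cohort-wide percentages of overlapping / adjacent / independent
    active lesions over all retained active records.

    Requires :func:`mslesion.taxonomy.spatial_relation` to have been run
    per subject.  An empty active set yields ``defined=False`` rather
    than NaN percentages.
    """
    counts = {"overlapping": 0, "adjacent": 0, "independent": 0}
    n = 0
    for table in tables:
        for r in table.records:
            if r.lesion_type != "active" or r.excluded or r.spatial_relation is None:
                continue
            counts[r.spatial_relation] += 1
            n += 1
    if n == 0:
        return RelationPercentages(0, 0.0, 0.0, 0.0, defined=False)
    return RelationPercentages(
        n_active=n,
        overlapping=100.0 * counts["overlapping"] / n,
        adjacent=100.0 * counts["adjacent"] / n,
        independent=100.0 * counts["independent"] / n,
        defined=True,
    )


def holm_adjust(pvalues: dict[str, float]) -> dict[str, float]:
    """Holm step-down adjustment (off by default in reports)."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adj = {}
    running = 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[k] = running
    return adj
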