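"""Demographics and cognition statistics.

Utilities to reproduce a demographics table from printed summary statistics
(one-way ANOVA from per-group n/mean/SD, Pearson chi-square for sex
counts), and to relate extracted cluster FC values to cognitive screening
scores (MMSE, MoCA) by partial correlation in the patient groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary of one variable: n, mean, SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def anova_from_summary(summaries: Sequence[GroupSummary]) -> tuple[float, float]:
    """One-way ANOVA computed from group summaries alone.

    Between-group SS from group means vs. the grand mean, within-group SS
    as sum of (n_i - 1) sd_i^2 — algebraically identical to a raw-data
    ANOVA on any dataset with matching summaries.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    grand = (ns * means).sum() / ns.sum()
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds ** 2).sum()
    df1 = len(summaries) - 1
    df2 = int(ns.sum()) - len(summaries)
    if ssw == 0:
        return (np.inf if ssb > 0 else 0.0), (0.0 if ssb > 0 else 1.0)
    F = (ssb / df1) / (ssw / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


def chisq_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test of independence (no continuity correction).

    For a sex-by-group table the input is 2 x 3; df = (r-1)(c-1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2D")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, dof))


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing both on the
    covariates (plus intercept); p from t with df = n - k - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or np.size(covariates) == 0:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate matrix does not match sample size")
    k = C.shape[1]
    if n < k + 3:
        raise ValueError("need at least k + 3 observations")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    Q, _ = np.linalg.qr(X)
    rx = x - Q @ (Q.T @ x)
    ry = y - Q @ (Q.T @ y)
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        raise ValueError("residual variance is zero")
    r = float(rx @ ry / denom)
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def bonferroni_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """min(1, p * m) elementwise; m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)


# --------------------------------------------------------------------------
# table-level conveniences
# --------------------------------------------------------------------------

GROUP_ORDER = ("AD", "aMCI", "NC")


def demographics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable group mean +/- SD with ANOVA p (continuous variables)
    and a chi-square p for the sex distribution."""
    rows = []
    for var in ("age", "education", "mmse", "moca"):
        summaries = []
        cells = {}
        for g in GROUP_ORDER:
            v = table.loc[table["group"] == g, var].to_numpy(dtype=float)
            summaries.append(GroupSummary(len(v), float(v.mean()), float(v.std(ddof=1))))
            cells[g] = f"{v.mean():.3f} ± {v.std(ddof=1):.3f}"
        _, p = anova_from_summary(summaries)
        rows.append(dict(variable=var, **cells, p_value=p, test="anova"))
    counts = np.array(
        [
            [(table["group"].eq(g) & table["sex"].eq(s)).sum() for g in GROUP_ORDER]
            for s in ("M", "F")
        ]
    )
    chi2, p = chisq_independence(counts)
    sex_cells = {
        g: f"{counts[0, i]}: {counts[1, i]}" for i, g in enumerate(GROUP_ORDER)
    }
    rows.append(dict(variable="sex (M: F)", **sex_cells, p_value=p, test="chi-square"))
    return pd.DataFrame(rows)


def fc_cognition_correlations(
    table: pd.DataFrame,
    cluster_values: dict[str, np.ndarray],
    scores: tuple[str, ...] = ("mmse", "moca"),
    covariates: tuple[str, ...] = ("mean_fd", "age", "sex", "education"),
    patient_groups: tuple[str, ...] = ("AD", "aMCI"),
) -> pd.DataFrame:
    """Partial correlations between cluster FC values and cognitive scores.

    Run in the pooled patient groups only (AD + aMCI — controls excluded),
    adjusting for head movement, age, sex and education.  The Bonferroni
    family is (number of clusters) x (number of scores).
    """
    sel = table["group"].isin(patient_groups).to_numpy()
    if sel.sum() < len(covariates) + 3:
        raise ValueError("too few patients for partial correlation")
    sub = table.loc[sel]
    C = np.column_stack(
        [
            sub[c].map({"M": 0.0, "F": 1.0}).to_numpy()
            if c == "sex"
            else sub[c].to_numpy(dtype=float)
            for c in covariates
        ]
    )
    rows = []
    for name, values in cluster_values.items():
        values = np.asarray(values, dtype=float)
        if len(values) != len(table):
            raise ValueError(
                f"cluster {name!r}: values must align with the full table"
            )
        for score in scores:
            r, p = partial_correlation(values[sel], sub[score].to_numpy(dtype=float), C)
            rows.append(dict(cluster=name, score=score, r=r, p_raw=p))
    out = pd.DataFrame(rows)
    m = len(cluster_values) * len(scores)
    out["p_adjusted"] = bonferroni_adjust(out["p_raw"].to_numpy(), m) if len(out) else []
    return out
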