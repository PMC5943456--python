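"""Tumour-cohort statistics: gene-pair correlation, discordant-expression
stratification, Kaplan-Meier curves and the G-rho family of weighted
log-rank tests (rho = 0 is the standard log-rank)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    gene_pair: tuple[str, str]
    r: float
    p_value: float
    p_adjusted: float
    n: int
    collinear: bool = False


@dataclass
class SurvivalComparison:
    statistic: float
    p_value: float
    df: int
    rho: float
    groups: list[str]
    km_tables: dict[str, pd.DataFrame]
    observed: dict[str, float]
    expected: dict[str, float]


def correlate_genes(expr_a, expr_b, n_tests: int = 1,
                    gene_pair=("geneA", "geneB")) -> CorrelationResult:
    """Pearson correlation with a two-sided t test (t = r sqrt((n-2)/(1-r^2))
    on n-2 df) and Bonferroni adjustment over ``n_tests`` (e.g. the number
    of tumour types tested)."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("expression vectors differ in length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the genes")
    r = float(np.corrcoef(a, b)[0, 1])
    collinear = abs(r) >= 1.0 - 1e-15
    if collinear:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(
        gene_pair=tuple(gene_pair), r=r, p_value=p,
        p_adjusted=min(1.0, p * n_tests), n=n, collinear=collinear,
    )


def stratify_cohort(expr_a, expr_b) -> np.ndarray:
    """Median-split discordant stratification: ``A_high_B_low`` (strictly
    above the A median, strictly below the B median), ``A_low_B_high``
    (the reverse), everything else — including median ties — ``other``."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant expression cannot be median-split")
    ma, mb = np.median(a), np.median(b)
    return np.where(
        (a > ma) & (b < mb), "A_high_B_low",
        np.where((a < ma) & (b > mb), "A_low_B_high", "other"),
    )


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns one row per distinct event time: time, n at risk, events,
    survival (right-continuous, starts below 1 at the first event time).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    rows = []
    surv = 1.0
    for et in event_times:
        n_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        surv *= 1.0 - d / n_risk
        rows.append(dict(time=et, n_risk=n_risk, n_events=d, survival=surv))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "survival"])


def survival_compare(records: pd.DataFrame, rho: float = 0.0) -> SurvivalComparison:
    """G-rho weighted log-rank comparison of the survival of >=2 groups.

    ``records`` needs columns group, time, event.  At each distinct event
    time the per-group observed-minus-expected event counts are weighted
    by the left-continuous pooled Kaplan-Meier survival raised to ``rho``
    (rho = 0: all weights 1, the standard log-rank test); the quadratic
    form against the hypergeometric covariance gives a chi-square
    statistic on (groups - 1) degrees of freedom.
    """
    req = {"group", "time", "event"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    groups = sorted(records["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (records["group"] == g).sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(int)
    if e.sum() == 0:
        raise ValueError("no events observed")
    gidx = records["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    k = len(groups)
    event_times = np.unique(t[e == 1])
    # left-continuous pooled KM for the weights
    pooled = km_curve(t, e)
    s_prev = np.concatenate([[1.0], pooled["survival"].to_numpy()[:-1]])
    weight_at = dict(zip(pooled["time"], s_prev ** rho))
    U = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        at_risk = t >= et
        n_j = int(at_risk.sum())
        d_j = int(((t == et) & (e == 1)).sum())
        if n_j == 0:
            continue
        w = weight_at[et]
        n_gj = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(gidx[(t == et) & (e == 1)], minlength=k).astype(float)
        frac = n_gj / n_j
        U += w * (d_gj - d_j * frac)
        if n_j > 1:
            c = d_j * (n_j - d_j) / (n_j - 1)
            V += w * w * c * (np.diag(frac) - np.outer(frac, frac))
    # drop one group (the covariance is singular by construction)
    Usub = U[:-1]
    Vsub = V[:-1, :-1]
    if np.allclose(Vsub, 0):
        chi2 = 0.0
    else:
        chi2 = float(Usub @ np.linalg.pinv(Vsub) @ Usub)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    km_tables = {
        g: km_curve(t[gidx == i], e[gidx == i]) for i, g in enumerate(groups)
    }
    expected = {}
    observed = {}
    for i, g in enumerate(groups):
        observed[g] = float(e[gidx == i].sum())
    # unweighted expected counts (reported for rho = 0 interpretability)
    E = np.zeros(k)
    for et in event_times:
        at_risk = t >= et
        n_j = int(at_risk.sum())
        d_j = int(((t == et) & (e == 1)).sum())
        E += d_j * np.bincount(gidx[at_risk], minlength=k) / n_j
    for i, g in enumerate(groups):
        expected[g] = float(E[i])
    return SurvivalComparison(
        statistic=chi2, p_value=p, df=df, rho=rho, groups=groups,
        km_tables=km_tables, observed=observed, expected=expected,
    )
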