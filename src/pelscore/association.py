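"""Non-survival statistics: cohort summaries, OLS feature screening with
Benjamini-Hochberg adjustment, and Wilcoxon rank-sum subgroup analyses of
the PEL score.

The cohort summary prints percentages truncated (not rounded) to one
decimal, matching how the source clinical tables in this field are
typically typeset.  The OLS screen regresses the binary transformation
outcome on each z-scored feature separately and reports two-sided t-test
p-values with a BH-adjusted column across the tested family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cohort_summary",
    "ols_feature_tests",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "SubgroupSpec",
    "subgroup_tests",
]

#: clinical age bins used for subgroup analyses
AGE_BINS = ((0, 50), (51, 70), (71, 100))


def truncate_percent(count: int, total: int) -> str:
    """``100*count/total`` floored to one decimal, e.g. 53/137 -> '38.6'."""
    if total <= 0:
        raise ValueError("total must be positive")
    tenths = (1000 * count) // total
    return f"{tenths // 10}.{tenths % 10}"


def cohort_summary(
    clinical: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Counts and truncated percentages per category of each variable."""
    if clinical.empty:
        raise ValueError("empty clinical table")
    columns = columns or [
        c for c in clinical.columns if c != "slide_id" and clinical[c].dtype == object
    ]
    total = len(clinical)
    rows = [{"variable": "cases", "category": "total", "count": total, "percent": "100.0"}]
    for col in columns:
        counts = clinical[col].value_counts()
        for cat, cnt in counts.items():
            rows.append(
                {
                    "variable": col,
                    "category": str(cat),
                    "count": int(cnt),
                    "percent": truncate_percent(int(cnt), total),
                }
            )
    return pd.DataFrame(rows)


def ols_feature_tests(
    features: pd.DataFrame, outcome: np.ndarray, adjust: bool = True
) -> pd.DataFrame:
    """Univariable OLS screen of each feature against the outcome.

    Each feature is z-scored and the outcome regressed on it alone; the
    slope's t statistic uses n-2 degrees of freedom with a two-sided p.
    Zero-variance (or all-missing) features are flagged untestable and
    excluded from the BH family.  Implemented in closed form (the
    univariable slope test is the correlation t-test); equivalence with a
    full OLS fit is enforced in the test suite.
    """
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rows = []
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 3 or np.nanstd(x) == 0 or ss_y == 0:
            rows.append(
                {"feature": col, "coef": np.nan, "t": np.nan, "p": np.nan, "testable": False}
            )
            continue
        xi, yi = x[ok], y[ok]
        ni = xi.size
        xz = (xi - xi.mean()) / xi.std()
        yc_i = yi - yi.mean()
        sxx = float(xz @ xz)
        beta = float(xz @ yc_i) / sxx
        resid = yc_i - beta * xz
        dof = ni - 2
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(sigma2 / sxx)
        if se == 0:  # perfect fit
            t = np.inf if beta > 0 else -np.inf
            p = 0.0
        else:
            t = beta / se
            p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append({"feature": col, "coef": beta, "t": t, "p": p, "testable": True})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adjusted"] = np.nan
        testable = out["testable"].to_numpy()
        if testable.any():
            out.loc[testable, "p_adjusted"] = bh_adjust(out.loc[testable, "p"].to_numpy())
        out["significant"] = out["p_adjusted"] < 0.05
    return out


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, set q_(i) = min_{j>=i} p_(j) * m / j capped at 1.
    ``m`` defaults to the number of p-values but may be larger when part of
    the family was untestable.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = m if m is not None else p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p values")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank-sum of ``x`` using midranks.
    ``mode='exact'`` enumerates the null distribution (valid without
    ties); ``'normal'`` uses the normal approximation with tie and
    continuity corrections; ``'auto'`` picks exact when n_x + n_y <= 20
    and the pooled sample has no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        w = stats.rankdata(pooled)[: x.size].sum()
        return float(w), 1.0
    if mode == "auto":
        mode = "exact" if (pooled.size <= 20 and not has_ties) else "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank-sum of x
    return w, float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class SubgroupSpec:
    """Subgrouping for PEL analyses: by gender or by clinical age bins."""

    grouping: str = "age"  # "gender" or "age"
    age_bins: tuple[tuple[int, int], ...] = field(default=AGE_BINS)

    def assign(self, clinical: pd.DataFrame) -> pd.Series:
        if self.grouping == "gender":
            return clinical["gender"].astype(str)
        if self.grouping == "age":
            labels = pd.Series("", index=clinical.index, dtype=object)
            for lo, hi in self.age_bins:
                sel = (clinical["age"] >= lo) & (clinical["age"] <= hi)
                labels[sel] = f"{lo}-{hi}"
            return labels
        raise ValueError("grouping must be 'gender' or 'age'")


def subgroup_tests(
    pel: np.ndarray,
    outcome: np.ndarray,
    clinical: pd.DataFrame,
    spec: SubgroupSpec,
) -> pd.DataFrame:
    """Wilcoxon comparison of PEL score between transformed and
    non-transformed cases within each subgroup.

    Subgroups with an empty outcome arm (or no members) are reported with
    ``testable=False`` rather than dropped.
    """
    pel = np.asarray(pel, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    groups = spec.assign(clinical)
    rows = []
    for g in sorted(groups.unique()):
        sel = (groups == g).to_numpy()
        x = pel[sel & (outcome == 1)]
        y = pel[sel & (outcome == 0)]
        if x.size == 0 or y.size == 0:
            rows.append(
                {"subgroup": g, "n_transformed": x.size, "n_not": y.size,
                 "statistic": np.nan, "p": np.nan, "testable": False}
            )
            continue
        w, p = wilcoxon_rank_sum(x, y)
        rows.append(
            {"subgroup": g, "n_transformed": x.size, "n_not": y.size,
             "statistic": w, "p": p, "testable": True}
        )
    return pd.DataFrame(rows)
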