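"""Progression-free survival machinery.

Kaplan-Meier curves, log-rank tests and Cox proportional-hazards fits are
delegated to ``lifelines`` (Efron tie handling) behind this module's
interface; Harrell's concordance index is implemented here and
cross-checked against independent pair enumeration in the test suite.

Risk dichotomisation follows the mean-hazard rule: per-subject hazard
score ``exp(X beta)`` from a fitted Cox model, cut at the mean of those
scores, and the resulting high/low-risk groups compared by log-rank.
Continuous covariates are z-scored before fitting so hazard ratios are
per standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "SurvivalFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "concordance_index",
    "bootstrap_cindex",
    "dichotomize_by_mean_hazard",
    "univariate_table",
    "multivariate_table",
]


@dataclass
class SurvivalFit:
    """A fitted Cox model: per-covariate summary plus apparent C-index.

    ``summary`` columns: covariate, beta, se, hr, ci_lower, ci_upper, p
    (Wald).  ``converged`` is False when the optimiser failed or the
    partial likelihood was monotone (e.g. perfect separation); such fits
    carry no summary and must not be consumed silently.
    """

    summary: pd.DataFrame
    converged: bool
    cindex: float
    model: CoxPHFitter | None = None
    linear_predictor: np.ndarray | None = None


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with risk/event counts per event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "observed": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.to_numpy(dtype=float),
        }
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >= 2 groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank needs at least two groups")
    if counts.min() == 0:
        raise ValueError("empty group")
    if events.sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def _is_binary(col: np.ndarray) -> bool:
    u = np.unique(col[np.isfinite(col)])
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


def standardize_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Z-score continuous covariates; leave 0/1 indicators untouched."""
    out = df.copy()
    for c in covariates:
        v = out[c].to_numpy(dtype=float)
        if not _is_binary(v):
            s = np.nanstd(v)
            if s > 0:
                out[c] = (v - np.nanmean(v)) / s
    return out


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    standardize: bool = True,
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties) on the given covariates.

    Returns a flagged (``converged=False``) result instead of raising on
    non-convergence or monotone likelihood.
    """
    cols = [duration_col, event_col] + list(covariates)
    df = data[cols].dropna().copy()
    n_events = int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError("need more events than covariates to fit")
    if standardize:
        df = standardize_covariates(df, covariates)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return SurvivalFit(summary=pd.DataFrame(), converged=False, cindex=np.nan)
    beta = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
        return SurvivalFit(summary=pd.DataFrame(), converged=False, cindex=np.nan)
    z = 1.959963984540054
    with np.errstate(over="ignore"):  # near-separation fits overflow exp
        summary = _summary_frame(cph, beta, se, z)
    lp = df[covariates].to_numpy(dtype=float) @ beta
    c = concordance_index(lp, df[duration_col].to_numpy(), df[event_col].to_numpy())
    return SurvivalFit(summary=summary, converged=True, cindex=c, model=cph, linear_predictor=lp)


def _summary_frame(cph, beta, se, z) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "covariate": list(cph.params_.index),
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_lower": np.exp(beta - z * se),
            "ci_upper": np.exp(beta + z * se),
            "p": cph.summary["p"].to_numpy(),
        }
    )


def concordance_index(risk_scores, times, events) -> float:
    """Harrell's C: fraction of comparable pairs ranked concordantly.

    A pair (i, j) is comparable when time_i < time_j and subject i had the
    event; it is concordant when risk_i > risk_j, with half credit for
    tied risks.  Raises when no pair is comparable.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    lt = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = lt.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs; C-index undefined")
    conc = (r[:, None] > r[None, :]) & lt
    tied = (r[:, None] == r[None, :]) & lt
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


def bootstrap_cindex(
    data: pd.DataFrame,
    covariates: list[str],
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator = 0,
    duration_col: str = "time",
    event_col: str = "event",
    max_failure_fraction: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Percentile bootstrap CI for the Cox model's C-index.

    Subjects are resampled with replacement; the model is refitted and its
    apparent C recomputed on each resample.  Aborts when more than
    ``max_failure_fraction`` of resamples fail to converge.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = cox_fit(data, covariates, duration_col, event_col)
    if not base.converged:
        raise ValueError("base Cox fit did not converge")
    df = data[[duration_col, event_col] + list(covariates)].dropna().reset_index(drop=True)
    n = len(df)
    cs = []
    failures = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        sample = df.iloc[idx]
        try:
            fit = cox_fit(sample, covariates, duration_col, event_col)
            if not fit.converged or not np.isfinite(fit.cindex):
                failures += 1
                continue
            cs.append(fit.cindex)
        except ValueError:
            failures += 1
    if failures > max_failure_fraction * n_bootstrap:
        raise RuntimeError(
            f"{failures}/{n_bootstrap} bootstrap refits failed; data too fragile for CI"
        )
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return base.cindex, (float(lo), float(hi))


def dichotomize_by_mean_hazard(
    fit: SurvivalFit,
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    standardize: bool = True,
) -> dict:
    """Split subjects at the mean relative hazard and compare by log-rank.

    Per-subject hazard score = exp(linear predictor); the cut-off is the
    mean of those scores; subjects strictly above it form the high-risk
    group.  A degenerate split (either group empty) is flagged and no p
    reported.
    """
    if not fit.converged:
        raise ValueError("cannot dichotomise on a non-converged fit")
    df = data[[duration_col, event_col] + list(covariates)].dropna().copy()
    if standardize:
        df = standardize_covariates(df, covariates)
    beta = fit.summary.set_index("covariate")["beta"]
    lp = df[covariates].to_numpy(dtype=float) @ beta.loc[covariates].to_numpy()
    hazard = np.exp(lp)
    cutoff = hazard.mean()
    high = hazard > cutoff
    result = {
        "cutoff": float(cutoff),
        "high_risk": high,
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
        "degenerate": bool(high.all() or (~high).all()),
        "logrank_chi2": np.nan,
        "logrank_p": np.nan,
    }
    if not result["degenerate"]:
        chi2, p = logrank_test(
            df[duration_col].to_numpy(), df[event_col].to_numpy(), high.astype(int)
        )
        result["logrank_chi2"], result["logrank_p"] = chi2, p
    return result


def univariate_table(
    data: pd.DataFrame,
    features: list[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-feature univariable survival analysis.

    For each feature: univariable Cox fit, log-rank p on the mean-hazard
    dichotomisation, and the C-index of the fit's linear predictor with a
    percentile bootstrap CI.  Untestable rows (non-converged fits,
    degenerate splits) are flagged inline rather than dropped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for feat in features:
        row = {"feature": feat, "testable": True, "logrank_p": np.nan,
               "cindex": np.nan, "ci_lower": np.nan, "ci_upper": np.nan}
        sub = data[[duration_col, event_col, feat]].dropna()
        try:
            fit = cox_fit(sub, [feat], duration_col, event_col)
        except ValueError:
            fit = SurvivalFit(summary=pd.DataFrame(), converged=False, cindex=np.nan)
        if not fit.converged:
            row["testable"] = False
            rows.append(row)
            continue
        split = dichotomize_by_mean_hazard(fit, sub, [feat], duration_col, event_col)
        if not split["degenerate"]:
            row["logrank_p"] = split["logrank_p"]
        try:
            c, (lo, hi) = bootstrap_cindex(
                sub, [feat], n_bootstrap, rng, duration_col, event_col
            )
            row["cindex"], row["ci_lower"], row["ci_upper"] = c, lo, hi
        except (RuntimeError, ValueError):
            row["cindex"] = fit.cindex
        rows.append(row)
    return pd.DataFrame(rows)


def multivariate_table(
    data: pd.DataFrame,
    covariates: list[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Joint Cox fit over the selected covariates.

    Returns the per-covariate HR table (Wald p, 95% CI) and the model's
    C-index with a percentile bootstrap CI.
    """
    fit = cox_fit(data, covariates, duration_col, event_col)
    if not fit.converged:
        raise ValueError("multivariate Cox fit did not converge")
    c, (lo, hi) = bootstrap_cindex(
        data, covariates, n_bootstrap, seed, duration_col, event_col
    )
    return {"summary": fit.summary, "cindex": c, "ci_lower": lo, "ci_upper": hi}
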