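"""Cross-validation harness and classification metrics.

The slide-level classifier here is a deliberately simple, CPU-fast
baseline — an L2-regularised logistic scorer on aggregated nuclear
features — used to exercise the protocol (stratified five-fold CV
repeated three times with different seeds); it makes no claim of matching
a trained weakly supervised CNN.  Feature scaling is fitted on training
folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["CVProtocol", "MetricReport", "stratified_kfold", "auroc", "f1_macro", "run_cv"]


@dataclass(frozen=True)
class CVProtocol:
    """Five-fold stratified CV repeated with three seeds."""

    n_folds: int = 5
    seeds: tuple[int, ...] = (0, 1, 2)

    @property
    def n_repeats(self) -> int:
        return len(self.seeds)


@dataclass
class MetricReport:
    """AUROC / macro-F1 summarised over all fold-repeat results."""

    auroc_mean: float
    auroc_sd: float
    f1_mean: float
    f1_sd: float
    per_fold: pd.DataFrame = field(repr=False, default=None)


def stratified_kfold(labels, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment (0..n_folds-1) stratified on the labels.

    Per-fold class counts differ by at most one from proportionality;
    deterministic under the seed.  Rejects classes smaller than n_folds.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("every class must have at least n_folds members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(y.size, dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        folds[test_idx] = k
    return folds


def auroc(scores, labels) -> float:
    """Area under the empirical ROC (equals the tie-aware pairwise
    probability that a positive outscores a negative)."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def f1_macro(predicted, truth) -> float:
    """Macro-averaged F1 over the two classes; a class with
    precision + recall = 0 contributes an F1 of 0."""
    return float(
        f1_score(np.asarray(truth), np.asarray(predicted), average="macro", zero_division=0)
    )


def _baseline_model():
    # scaling fitted inside the pipeline => train folds only
    return make_pipeline(StandardScaler(), LogisticRegression(C=1.0, max_iter=2000))


def run_cv(
    features: pd.DataFrame,
    labels,
    protocol: CVProtocol | None = None,
    model_factory=_baseline_model,
) -> MetricReport:
    """Repeated stratified CV of the baseline scorer.

    Metrics are computed per held-out fold and summarised (mean, SD) over
    all n_folds x n_repeats results.  Training folds containing a single
    class are rejected.
    """
    protocol = protocol or CVProtocol()
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = np.asarray(labels, dtype=int)
    records = []
    for seed in protocol.seeds:
        folds = stratified_kfold(y, protocol.n_folds, seed)
        for k in range(protocol.n_folds):
            test = folds == k
            train = ~test
            if np.unique(y[train]).size < 2:
                raise ValueError("training fold contains a single class")
            model = model_factory()
            model.fit(X[train], y[train])
            scores = model.decision_function(X[test])
            preds = model.predict(X[test])
            records.append(
                {
                    "seed": seed,
                    "fold": k,
                    "auroc": auroc(scores, y[test]),
                    "f1_macro": f1_macro(preds, y[test]),
                }
            )
    per_fold = pd.DataFrame(records)
    return MetricReport(
        auroc_mean=float(per_fold["auroc"].mean()),
        auroc_sd=float(per_fold["auroc"].std(ddof=1)),
        f1_mean=float(per_fold["f1_macro"].mean()),
        f1_sd=float(per_fold["f1_macro"].std(ddof=1)),
        per_fold=per_fold,
    )
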