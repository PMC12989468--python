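"""Responder stratification and the baseline responder-prediction benchmark.

Participants are split per strength metric into low (LR, bottom 20%),
medium (MR) and high responders (HR, top 20%) by empirical quantiles of
the metric's change; the "non-HR pool" contains everyone not classified HR
by *any* metric and serves as the sampling pool for the permutation-subset
null of the differential-abundance analysis.  A Random-Forest benchmark
asks whether baseline-only features can tell HR from LR, scoring a
stratified cross-validated ROC-AUC against a label-permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

LR, MR, HR = "LR", "MR", "HR"


class DegenerateStratificationError(ValueError):
    """All metric values identical: quantile cuts are meaningless."""


@dataclass
class ResponderLabels:
    """Classes and realized thresholds for one strength metric."""

    metric: str
    classes: pd.Series  # participant -> LR/MR/HR
    low_cut: float
    high_cut: float
    higher_is_better: bool = True

    def members(self, cls: str) -> set[str]:
        return set(self.classes.index[self.classes == cls])


@dataclass
class PredictionResult:
    auc: float
    permutation_p: float
    feature_importances: dict[str, float]
    n_perm: int
    fold_aucs: list[float] = field(default_factory=list)


def stratify(
    metric_values: pd.Series,
    low_q: float = 0.2,
    high_q: float = 0.8,
    higher_is_better: bool = True,
    metric: str = "metric",
) -> ResponderLabels:
    """Quantile stratification into LR / MR / HR.

    Uses linear-interpolation (type-7) quantiles with *strict* inequality:
    HR lies strictly beyond the high cut, LR strictly below the low cut,
    and ties at either cut fall to MR.  For metrics where a *decrease* is
    the improvement (e.g. the strength age-equivalent), pass
    ``higher_is_better=False``; the quantile logic is applied to the
    negated values and the realized thresholds are reported on the original
    scale.
    """
    values = metric_values.dropna().astype(float)
    if len(values) < 5:
        raise ValueError("need at least 5 participants with finite values")
    if values.nunique() == 1:
        raise DegenerateStratificationError(
            f"all values of {metric!r} identical"
        )
    work = values if higher_is_better else -values
    low_cut = float(np.quantile(work, low_q))
    high_cut = float(np.quantile(work, high_q))
    classes = pd.Series(MR, index=values.index, name=metric)
    classes[work > high_cut] = HR
    classes[work < low_cut] = LR
    if not higher_is_better:
        low_cut, high_cut = -low_cut, -high_cut
    return ResponderLabels(
        metric=metric,
        classes=classes,
        low_cut=low_cut,
        high_cut=high_cut,
        higher_is_better=higher_is_better,
    )


def non_hr_pool(labels: Mapping[str, ResponderLabels]) -> set[str]:
    """Participants not classified HR under *any* metric.

    The universe is the union of participants labelled by any metric, so
    pool + (HR in at least one metric) partitions the labelled cohort.
    """
    universe: set[str] = set()
    hr_any: set[str] = set()
    for lab in labels.values():
        universe |= set(lab.classes.index)
        hr_any |= lab.members(HR)
    return universe - hr_any


def predict_responders(
    features: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    n_estimators: int = 500,
    n_folds: int = 5,
) -> PredictionResult:
    """Random-Forest HR-vs-LR benchmark with a permutation-calibrated AUC.

    ``features`` must be baseline-only measurements (no post-training
    leakage); rows align with ``labels`` (values HR/LR).  The headline
    score is the stratified ``n_folds``-fold cross-validated ROC-AUC; the
    one-sided permutation p is (1 + #permutations with AUC >= observed) /
    (1 + n_perm).  Gini feature importances are averaged over folds and
    normalized to sum to 1.
    """
    if len(features) != len(labels):
        raise ValueError("feature/label length mismatch")
    labels = labels.loc[features.index]
    classes = set(labels.unique())
    if classes != {HR, LR}:
        raise ValueError(f"labels must be HR/LR, got {sorted(classes)}")
    counts = labels.value_counts()
    if (counts < 5).any():
        raise ValueError("each class needs at least 5 members")
    x = features.to_numpy(dtype=float)
    y = (labels == HR).to_numpy(dtype=int)
    rng = np.random.default_rng(seed)

    def cv_auc(y_vec: np.ndarray, collect: bool = False):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
        aucs, imps = [], []
        for train, test in skf.split(x, y_vec):
            clf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed, n_jobs=1
            )
            clf.fit(x[train], y_vec[train])
            prob = clf.predict_proba(x[test])[:, 1]
            aucs.append(roc_auc_score(y_vec[test], prob))
            if collect:
                imps.append(clf.feature_importances_)
        return float(np.mean(aucs)), aucs, imps

    observed, fold_aucs, imps = cv_auc(y, collect=True)
    exceed = 0
    for _ in range(n_perm):
        perm_auc, _, _ = cv_auc(rng.permutation(y))
        exceed += perm_auc >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    mean_imp = np.mean(imps, axis=0)
    total = mean_imp.sum()
    if total > 0:
        mean_imp = mean_imp / total
    importances = dict(zip(features.columns, (float(v) for v in mean_imp)))
    return PredictionResult(
        auc=observed,
        permutation_p=float(p),
        feature_importances=importances,
        n_perm=n_perm,
        fold_aucs=[float(a) for a in fold_aucs],
    )


def stratify_all(
    metrics: pd.DataFrame,
    low_q: float = 0.2,
    high_q: float = 0.8,
) -> dict[str, ResponderLabels]:
    """Stratify the three headline strength metrics from a metrics table.

    * ``legpress``: change in maximum leg-press strength (kg), W0 -> W8.
    * ``avg_gain``: average log2 fold change over machines, W0 -> W8.
    * ``bioage``: change in the strength age-equivalent (years); a larger
      *decrease* marks a high responder.
    """
    table = metrics.set_index("participant")
    out = {}
    out["legpress"] = stratify(
        table["legpress_W8"] - table["legpress_W0"],
        low_q, high_q, metric="legpress",
    )
    out["avg_gain"] = stratify(
        table["avg_log2fc_W0W8"], low_q, high_q, metric="avg_gain"
    )
    out["bioage"] = stratify(
        table["bioage_W8"] - table["bioage_W0"],
        low_q, high_q, higher_is_better=False, metric="bioage",
    )
    return out


def labels_table(labels: Mapping[str, ResponderLabels]) -> pd.DataFrame:
    """Wide per-participant class table plus the non-HR pool flag."""
    frame = pd.DataFrame(
        {name: lab.classes for name, lab in labels.items()}
    )
    pool = non_hr_pool(labels)
    frame["non_hr_pool"] = [p in pool for p in frame.index]
    frame.index.name = "participant"
    return frame.reset_index()
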