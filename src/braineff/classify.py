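"""Discriminating WMH-CIND from WMH-NC with a linear SVM under LOOCV.

Features are efficiency AUCs that differ between groups. Two selection
protocols are provided: ``"paper"`` re-uses the full-sample group
statistics (the historically common protocol; it leaks label information
into selection and is flagged as such in the report), while ``"nested"``
re-runs selection inside every training fold and is the honest default.
In both modes feature standardization is fit on the training fold only.
Sensitivity is the proportion of WMH-CIND subjects correctly predicted,
specificity the proportion of WMH-NC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm
from sklearn.svm import SVC

POSITIVE = "WMH-CIND"
NEGATIVE = "WMH-NC"


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x candidate features, with selection provenance."""

    X: pd.DataFrame  # indexed by subject_id
    y: np.ndarray  # labels aligned with X rows
    provenance: pd.DataFrame  # feature, admitted_by
    mode: str

    def __post_init__(self):
        if self.X.shape[1] < 1:
            raise ValueError("feature matrix needs at least one column")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing entries")
        labs = set(self.y)
        if not {POSITIVE, NEGATIVE} <= labs:
            raise ValueError(f"both classes required, got {labs}")


@dataclass
class ClassificationReport:
    """LOOCV outcome: per-fold records and aggregate operating statistics."""

    folds: pd.DataFrame  # subject_id, true, predicted, decision_value
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    roc_auc: float
    mode: str
    selection_leaks_labels: bool

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "selection_leaks_labels": self.selection_leaks_labels,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_auc": self.roc_auc,
            "n": int(len(self.folds)),
            "folds": self.folds.to_dict(orient="records"),
        }


def profiles_to_features(profiles: pd.DataFrame) -> pd.DataFrame:
    """Wide subjects x features table of every efficiency AUC.

    Feature names encode scope and metric, e.g. ``node:FPN_003:global`` or
    ``subnetwork:CON:local``.
    """
    p = profiles.copy()
    p["feature"] = [
        f"{st}:{nid or sc}:{met}" if st != "whole_brain" else f"whole_brain:{met}"
        for st, sc, nid, met in zip(p.scope_type, p.scope, p.node_id, p.metric)
    ]
    wide = p.pivot_table(index="subject_id", columns="feature", values="auc")
    wide.columns.name = None
    return wide


def _feature_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample Welch t-test p per feature (the selection filter)."""
    pos, neg = X[y == POSITIVE], X[y == NEGATIVE]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = sps.ttest_ind(pos, neg, axis=0, equal_var=False).pvalue
    return np.where(np.isfinite(p), p, 1.0)


def select_features(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    mode: str = "nested",
    alpha: float = 0.05,
    stats_results: dict | None = None,
) -> FeatureMatrix:
    """Assemble the two-class feature matrix.

    ``features`` is the wide AUC table (see :func:`profiles_to_features`)
    and ``cohort`` supplies group labels; only WMH-NC and WMH-CIND subjects
    enter. In ``"paper"`` mode features are those significant in the
    full-sample three-group comparisons (taken from ``stats_results`` when
    given, else a full-sample two-group t-test at ``alpha``) — this leaks
    label information and is flagged. In ``"nested"`` mode all features are
    retained here and per-fold selection happens inside the LOOCV.
    """
    if mode not in ("paper", "nested"):
        raise ValueError("mode must be 'paper' or 'nested'")
    lab = cohort.set_index("subject_id").group
    keep = lab[lab.isin([POSITIVE, NEGATIVE])]
    X = features.loc[features.index.intersection(keep.index)].sort_index()
    y = keep.loc[X.index].to_numpy()

    if mode == "paper":
        if stats_results is not None:
            admitted = _significant_features_from_stats(stats_results)
            cols = [c for c in X.columns if c in admitted]
            prov = pd.DataFrame(
                {"feature": cols, "admitted_by": [admitted[c] for c in cols]}
            )
        else:
            p = _feature_pvalues(X.to_numpy(float), y)
            cols = list(X.columns[p < alpha])
            prov = pd.DataFrame(
                {"feature": cols, "admitted_by": f"full-sample Welch t-test p<{alpha}"}
            )
        if not cols:
            raise ValueError(
                "no features pass full-sample selection; try mode='nested' or a looser alpha"
            )
        X = X[cols]
    else:
        prov = pd.DataFrame(
            {"feature": list(X.columns), "admitted_by": "per-fold selection (nested)"}
        )
    return FeatureMatrix(X=X, y=y, provenance=prov, mode=mode)


def _significant_features_from_stats(stats_results: dict) -> dict:
    """Map feature name -> admitting test, from group-statistics tables."""
    admitted = {}
    wb = stats_results.get("whole_brain")
    if wb is not None and len(wb):
        for _, r in wb.iterrows():
            if r.significant:
                metric = r.metric_id.split()[-1]
                admitted[f"whole_brain:{metric}"] = "whole-brain ANOVA + Bonferroni"
    sn = stats_results.get("subnetwork")
    if sn is not None and len(sn):
        for _, r in sn.iterrows():
            if r.significant and any(r.get(f"sig {p1} vs {p2}", False) for p1, p2 in
                                     (("HC", "WMH-NC"), ("HC", "WMH-CIND"), ("WMH-NC", "WMH-CIND"))):
                scope, metric = r.metric_id.split()
                admitted[f"subnetwork:{scope}:{metric}"] = "subnetwork ANOVA + Bonferroni"
    for key, prefix in (("nodal", "node"), ("subnetwork_nodal", "subnetwork_node")):
        tab = stats_results.get(key)
        if tab is not None and len(tab):
            for _, r in tab.iterrows():
                if r.get("fdr_reject", False):
                    admitted[f"{prefix}:{r.node_id}:{r.metric}"] = f"nodal ANOVA + BH-FDR ({key})"
    return admitted


def loocv_classify(
    fm: FeatureMatrix,
    C: float = 1.0,
    alpha: float = 0.05,
    min_nested_features: int = 1,
) -> ClassificationReport:
    """Leave-one-out cross-validated linear SVM.

    Every fold standardizes features on the n-1 training subjects (and, in
    nested mode, re-selects features on them) before predicting the held-out
    subject. Aggregates accuracy, sensitivity, specificity and the ROC over
    the held-out decision values.
    """
    X = fm.X.to_numpy(float)
    y = fm.y
    n = len(y)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    if min((y == POSITIVE).sum(), (y == NEGATIVE).sum()) < 2:
        raise ValueError("both classes need at least 2 subjects")

    records = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if len(set(ytr)) < 2:
            raise ValueError("training fold contains a single class")
        if fm.mode == "nested":
            p = _feature_pvalues(Xtr, ytr)
            cols = np.flatnonzero(p < alpha)
            if cols.size < min_nested_features:
                cols = np.argsort(p)[:min_nested_features]
        else:
            cols = np.arange(X.shape[1])
        mu = Xtr[:, cols].mean(axis=0)
        sd = Xtr[:, cols].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((Xtr[:, cols] - mu) / sd, ytr)
        xt = (X[i, cols] - mu) / sd
        pred = clf.predict(xt[None, :])[0]
        dec = float(clf.decision_function(xt[None, :])[0])
        if clf.classes_[1] != POSITIVE:  # orient decision values toward CIND
            dec = -dec
        records.append(
            {
                "subject_id": fm.X.index[i],
                "true": y[i],
                "predicted": pred,
                "decision_value": dec,
                "n_features": int(len(cols)),
            }
        )
    folds = pd.DataFrame(records)
    correct = folds.true == folds.predicted
    pos, neg = folds.true == POSITIVE, folds.true == NEGATIVE
    sens = float(correct[pos].mean())
    spec = float(correct[neg].mean())
    fpr, tpr, auc = roc_curve(folds.decision_value.to_numpy(), folds.true.to_numpy())
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ClassificationReport(
        folds=folds,
        accuracy=float(correct.mean()),
        sensitivity=sens,
        specificity=spec,
        roc_points=roc,
        roc_auc=auc,
        mode=fm.mode,
        selection_leaks_labels=(fm.mode == "paper"),
    )


def roc_curve(decision_values, labels, positive: str = POSITIVE):
    """Threshold sweep over decision values: (fpr, tpr, trapezoidal area).

    Ties in decision values are stepped together (standard convention).
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skm.roc_curve(labels == positive, np.asarray(decision_values, float))
    return fpr, tpr, float(np.trapezoid(tpr, fpr))
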