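"""Cohort-level statistics.

Three-group comparisons (one-way ANOVA with Bonferroni-corrected Welch
post hocs at alpha/3), Benjamini–Hochberg FDR across nodal families,
Kruskal–Wallis for skewed lesion volumes, chi-squared for categorical
demographics, composite cognitive Z-scores (timed tests entered as
reciprocals), lesion-volume normalization, and covariate-adjusted
multiple regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUP_ORDER = ("HC", "WMH-NC", "WMH-CIND")
PAIRS = (("HC", "WMH-NC"), ("HC", "WMH-CIND"), ("WMH-NC", "WMH-CIND"))

#: cognitive domain -> list of (instrument column, invert flag). Timed
#: instruments (seconds) are inverted as 1/time before z-scoring so that
#: higher always means better.
DEFAULT_DOMAINS = {
    "processing_speed": [
        ("tmt_a_seconds", True),
        ("stroop_a_seconds", True),
        ("stroop_b_seconds", True),
    ],
}


def normalize_log_wmh(volume_mm3, total_brain_mm3):
    """log10 of lesion volume normalized by total brain volume."""
    v = np.asarray(volume_mm3, dtype=float)
    t = np.asarray(total_brain_mm3, dtype=float)
    if (v <= 0).any() or (t <= 0).any():
        raise ValueError("volumes must be positive (zero/negative not imputed)")
    out = np.log10(v / t)
    return float(out) if out.ndim == 0 else out


def composite_z(scores: pd.DataFrame, domains: dict | None = None) -> pd.DataFrame:
    """Per-subject composite Z-score for each cognitive domain.

    Each instrument is z-scored against the full sample (all groups
    pooled); a domain score is the mean of its member Z-scores. Inverted
    instruments enter as reciprocals (1/time). Missing scores exclude the
    subject from that instrument; a zero-variance instrument is an error.
    """
    domains = DEFAULT_DOMAINS if domains is None else domains
    out = {}
    for domain, members in domains.items():
        zs = []
        for col, invert in members:
            x = scores[col].astype(float)
            if invert:
                if (x <= 0).any():
                    raise ValueError(f"cannot invert non-positive scores in {col}")
                x = 1.0 / x
            sd = x.std(ddof=0)
            if not sd > 0:
                raise ValueError(f"zero-variance instrument: {col}")
            zs.append((x - x.mean()) / sd)
        out[domain] = pd.concat(zs, axis=1).mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=scores.index)


@dataclass
class GroupComparisonResult:
    """One metric's three-group comparison."""

    metric_id: str
    f: float
    p: float
    group_means: dict
    posthoc_p: dict  # pair label -> Welch t-test p
    bonferroni_alpha: float
    significant: bool
    posthoc_significant: dict = field(default_factory=dict)
    q: float | None = None  # BH-adjusted p when part of a nodal family


def anova_three_group(
    values_by_group: dict, metric_id: str = "", alpha: float = 0.05, bonferroni_divisor: int = 3
) -> GroupComparisonResult:
    """One-way ANOVA; post hoc pairwise Welch t-tests judged at alpha/3.

    Post hoc p-values are always reported, but pairwise significance is
    only claimed when the omnibus test passes.
    """
    for g, v in values_by_group.items():
        if len(np.asarray(v)) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    groups = [g for g in GROUP_ORDER if g in values_by_group] or list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    f, p = sps.f_oneway(*arrays)
    thr = alpha / bonferroni_divisor
    posthoc, post_sig = {}, {}
    for g1, g2 in PAIRS:
        if g1 in values_by_group and g2 in values_by_group:
            key = f"{g1} vs {g2}"
            tp = sps.ttest_ind(values_by_group[g1], values_by_group[g2], equal_var=False).pvalue
            posthoc[key] = float(tp)
            post_sig[key] = bool(p < alpha and tp < thr)
    return GroupComparisonResult(
        metric_id=metric_id,
        f=float(f),
        p=float(p),
        group_means={g: float(np.mean(values_by_group[g])) for g in groups},
        posthoc_p=posthoc,
        bonferroni_alpha=thr,
        significant=bool(p < alpha),
        posthoc_significant=post_sig,
    )


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini–Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def kruskal_wallis(values_by_group: dict):
    """Kruskal–Wallis H and p for skewed (e.g. lesion-volume) variables."""
    arrays = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def chi_square(counts):
    """Chi-squared test of independence on a contingency table."""
    table = np.asarray(counts, dtype=float)
    if table.min() < 0 or table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def adjusted_regression(
    data: pd.DataFrame,
    y: str,
    x: str,
    covariates=("age", "gender", "education"),
) -> pd.DataFrame:
    """OLS of y on x adjusting for covariates, standardized coefficients.

    Continuous variables (y, x, and any covariate with more than two
    levels) are z-standardized; binary covariates are left as coded.
    Returns one row per predictor with beta and two-sided p.
    """
    import statsmodels.api as sm

    cols = [y, x, *covariates]
    df = data[cols].dropna().astype(float)
    n = len(df)
    if n <= len(cols) + 2:
        raise ValueError("too few complete cases for the requested model")

    def _std(s):
        if s.nunique() <= 2:
            return s
        return (s - s.mean()) / s.std(ddof=0)

    work = df.apply(_std)
    X = sm.add_constant(work[[x, *covariates]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        corr = work[[x, *covariates]].corr().abs()
        np.fill_diagonal(corr.values, 0)
        bad = corr.stack().idxmax()
        raise ValueError(f"collinear predictors, e.g. {bad}")
    fit = sm.OLS(work[y], X).fit()
    return pd.DataFrame(
        {"beta": fit.params.drop("const"), "p": fit.pvalues.drop("const"), "n": n}
    )


def _result_row(r: GroupComparisonResult) -> dict:
    row = {
        "metric_id": r.metric_id,
        "F": r.f,
        "p": r.p,
        "bonferroni_alpha": r.bonferroni_alpha,
        "significant": r.significant,
    }
    for g, m in r.group_means.items():
        row[f"mean {g}"] = m
    for k, v in r.posthoc_p.items():
        row[f"p {k}"] = v
        row[f"sig {k}"] = r.posthoc_significant.get(k, False)
    if r.q is not None:
        row["q"] = r.q
    return row


def compare_efficiency_families(
    profiles: pd.DataFrame,
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni_divisor: int = 3,
    fdr_q: float = 0.05,
) -> dict:
    """Three-group comparisons of efficiency AUCs, organized as families.

    ``profiles`` is the long per-subject metrics table (must carry a
    ``subject_id`` column) and ``cohort`` maps subject_id to group. Returns
    a dict of tidy DataFrames:

    * ``whole_brain`` — global & local AUC, ANOVA + Bonferroni post hocs;
    * ``subnetwork`` — 6 subnetworks x {global, local}, same protocol;
    * ``nodal`` — per-node AUCs on the whole-brain graph, ANOVA with BH-FDR
      across nodes, corrected separately within each metric family;
    * ``subnetwork_nodal`` — same, within each subnetwork's induced graph
      (one BH family per subnetwork x metric), when present;
    * ``pointwise`` — whole-brain per-sparsity pairwise Welch t-tests,
      uncorrected (exploratory).
    """
    merged = profiles.merge(cohort[["subject_id", "group"]], on="subject_id")

    def groups_of(frame, col="auc"):
        return {g: frame.loc[frame.group == g, col].to_numpy() for g in GROUP_ORDER if (frame.group == g).any()}

    out: dict = {}

    wb = merged[merged.scope_type == "whole_brain"]
    rows = []
    for metric, sub in wb.groupby("metric"):
        rows.append(_result_row(anova_three_group(groups_of(sub), f"whole_brain {metric}", alpha, bonferroni_divisor)))
    out["whole_brain"] = pd.DataFrame(rows)

    sn = merged[merged.scope_type == "subnetwork"]
    rows = []
    for (scope, metric), sub in sn.groupby(["scope", "metric"]):
        rows.append(_result_row(anova_three_group(groups_of(sub), f"{scope} {metric}", alpha, bonferroni_divisor)))
    out["subnetwork"] = pd.DataFrame(rows)

    def _nodal_family(frame, family_cols):
        rows = []
        for keys, sub in frame.groupby(family_cols):
            fam_rows = []
            for nid, node_sub in sub.groupby("node_id"):
                r = anova_three_group(groups_of(node_sub), str(nid), alpha, bonferroni_divisor)
                fam_rows.append(r)
            reject, p_adj = fdr_bh([r.p for r in fam_rows], fdr_q)
            for r, rej, q in zip(fam_rows, reject, p_adj):
                r.q = float(q)
                row = _result_row(r)
                row["fdr_reject"] = bool(rej)
                if isinstance(keys, tuple):
                    for c, k in zip(family_cols, keys):
                        row[c] = k
                else:
                    row[family_cols[0]] = keys
                row["node_id"] = r.metric_id
                rows.append(row)
        return pd.DataFrame(rows)

    nodal = merged[merged.scope_type == "node"]
    out["nodal"] = _nodal_family(nodal, ["metric"])

    sn_nodal = merged[merged.scope_type == "subnetwork_node"]
    if len(sn_nodal):
        out["subnetwork_nodal"] = _nodal_family(sn_nodal, ["scope", "metric"])
    else:
        out["subnetwork_nodal"] = pd.DataFrame()

    s_cols = [c for c in merged.columns if c.startswith("s_")]
    rows = []
    for metric, sub in wb.groupby("metric"):
        for sc in s_cols:
            for g1, g2 in PAIRS:
                v1 = sub.loc[sub.group == g1, sc]
                v2 = sub.loc[sub.group == g2, sc]
                if len(v1) and len(v2):
                    tp = sps.ttest_ind(v1, v2, equal_var=False).pvalue
                    rows.append(
                        {
                            "metric": metric,
                            "sparsity": float(sc[2:]),
                            "pair": f"{g1} vs {g2}",
                            "p_uncorrected": float(tp),
                        }
                    )
    out["pointwise"] = pd.DataFrame(rows)
    return out


def demographic_comparisons(cohort: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Cohort-description table: ANOVA for age/education, chi-squared for
    gender, Kruskal–Wallis for (skewed) lesion volumes."""
    rows = []
    by_group = {g: cohort[cohort.group == g] for g in GROUP_ORDER if (cohort.group == g).any()}
    for col in ("age", "education"):
        r = anova_three_group({g: d[col].to_numpy() for g, d in by_group.items()}, col, alpha)
        rows.append({"variable": col, "test": "anova", "statistic": r.f, "p": r.p})
    table = np.array([[ (d.gender == v).sum() for d in by_group.values()] for v in (0, 1)])
    chi2, p = chi_square(table)
    rows.append({"variable": "gender", "test": "chi2", "statistic": chi2, "p": p})
    for col in ("wmh_mm3", "pwmh_mm3", "dwmh_mm3", "total_brain_mm3"):
        h, p = kruskal_wallis({g: d[col].to_numpy() for g, d in by_group.items()})
        rows.append({"variable": col, "test": "kruskal", "statistic": h, "p": p})
    return pd.DataFrame(rows)
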