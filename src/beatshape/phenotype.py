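"""Phenotypic characterization of heartbeat clusters.

Beats are annotated with glycemic class (hypoglycemia 15-70 mg/dL, severe
hypoglycemia < 15 mg/dL), the eight experimental groups crossing glycemia x
diabetes x death (H/SH x ND/D x L/X), and interval-prolongation flags
against published Sprague-Dawley reference limits (PR > 70 ms, QT > 75.9 ms,
QRS > 22 ms). Cluster-level summaries include feature percentages,
chi-square tests of independence, Kolmogorov-Smirnov normality checks,
median/IQR interval statistics, a group-scaled heatmap matrix with Ward
ordering, and Spearman glucose-interval correlations with strength bands.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

__all__ = [
    "PR_LIMIT_MS",
    "QT_LIMIT_MS",
    "QRS_LIMIT_MS",
    "mgdl_to_mmoll",
    "classify_glycemia",
    "assign_group",
    "flag_intervals",
    "annotate_beats",
    "cluster_centers",
    "phenotype_table",
    "feature_cluster_table",
    "chi_square_independence",
    "ks_normality",
    "summarize_median_iqr",
    "group_cluster_heatmap",
    "strength_band",
    "spearman_by_group",
    "spearman_table",
]

#: Upper reference limits for Sprague-Dawley rats (ms); prolongation flags
#: use strict > comparisons.
PR_LIMIT_MS = 70.0
QT_LIMIT_MS = 75.9
QRS_LIMIT_MS = 22.0

GROUP_LABELS = [
    "H-ND-L", "SH-ND-L", "H-ND-X", "SH-ND-X",
    "H-D-L", "SH-D-L", "H-D-X", "SH-D-X",
]


def mgdl_to_mmoll(glucose_mgdl: float) -> float:
    """Convert glucose from mg/dL to mmol/L (70 mg/dL -> 3.89 mmol/L)."""
    return glucose_mgdl / 18.016


def classify_glycemia(glucose_mg_dl: float) -> str:
    """'severe' below 15 mg/dL, 'hypoglycemia' in [15, 70], 'euglycemic'
    above 70."""
    g = float(glucose_mg_dl)
    if g <= 0:
        raise ValueError("glucose must be > 0")
    if g < 15.0:
        return "severe"
    if g <= 70.0:
        return "hypoglycemia"
    return "euglycemic"


def assign_group(diabetic: bool, died: bool, glycemic_class: str) -> str:
    """One of the eight H/SH x ND/D x L/X labels; euglycemic beats belong to
    no experimental group ('none')."""
    if glycemic_class == "euglycemic":
        return "none"
    if glycemic_class not in ("hypoglycemia", "severe"):
        raise ValueError(f"unknown glycemic class {glycemic_class!r}")
    gly = "SH" if glycemic_class == "severe" else "H"
    dia = "D" if diabetic else "ND"
    death = "X" if died else "L"
    return f"{gly}-{dia}-{death}"


def _flag(value: float, limit: float):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return bool(value > limit)


def flag_intervals(pr_ms, qt_ms, qrs_ms):
    """(pr_increased, qt_increased, qrs_increased) with strict-> comparisons;
    an absent interval yields an absent flag."""
    return _flag(pr_ms, PR_LIMIT_MS), _flag(qt_ms, QT_LIMIT_MS), _flag(qrs_ms, QRS_LIMIT_MS)


def annotate_beats(
    beat_table: pd.DataFrame, labels: np.ndarray, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Join cluster labels and rat metadata onto the beat table and derive
    glycemic class, experimental group, and interval flags."""
    df = beat_table.copy()
    df["cluster"] = np.asarray(labels, dtype=int)
    meta = metadata.set_index("rat_id")[["diabetic", "died"]]
    df = df.join(meta, on="rat_id")
    df["glycemic_class"] = df["glucose_mg_dl"].map(classify_glycemia)
    df["group"] = [
        assign_group(d, x, g)
        for d, x, g in zip(df["diabetic"], df["died"], df["glycemic_class"])
    ]
    for col, src, limit in (
        ("pr_increased", "pr_ms", PR_LIMIT_MS),
        ("qt_increased", "qt_ms", QT_LIMIT_MS),
        ("qrs_increased", "qrs_ms", QRS_LIMIT_MS),
    ):
        flags = pd.array(df[src] > limit, dtype="boolean")
        flags[df[src].isna().to_numpy()] = pd.NA
        df[col] = flags
    return df


def cluster_centers(beats: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Arithmetic-mean trajectory of all member beats per cluster (computed
    over the full beat set, not the senators)."""
    X = np.asarray(beats, dtype=float)
    labels = np.asarray(labels)
    rows = {}
    for k in np.unique(labels):
        mask = labels == k
        if not mask.any():
            raise ValueError(f"cluster {k} is empty")
        rows[k] = X[mask].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def summarize_median_iqr(values) -> tuple[float, float]:
    """(median, Q3 - Q1) over non-missing values, linear-interpolation
    quantiles."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise ValueError("no observed values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q3 - q1)


def phenotype_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster phenotype summary: beat count, percentage of each binary
    feature, and median/IQR of each interval."""
    rows = []
    for k, sub in annotations.groupby("cluster"):
        row = {"cluster": int(k), "n": len(sub)}
        for feat in ("diabetic", "died"):
            row[f"pct_{feat}"] = 100.0 * sub[feat].mean()
        row["pct_hypoglycemia"] = 100.0 * (sub["glycemic_class"] == "hypoglycemia").mean()
        row["pct_severe"] = 100.0 * (sub["glycemic_class"] == "severe").mean()
        for feat in ("pr_increased", "qt_increased", "qrs_increased"):
            obs = sub[feat].dropna()
            row[f"pct_{feat}"] = 100.0 * obs.astype(bool).mean() if len(obs) else np.nan
        for iv in ("pr_ms", "qt_ms", "qrs_ms"):
            vals = sub[iv].dropna()
            if len(vals):
                med, iqr = summarize_median_iqr(vals)
            else:
                med = iqr = np.nan
            row[f"median_{iv}"] = med
            row[f"iqr_{iv}"] = iqr
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)


def feature_cluster_table(annotations: pd.DataFrame, feature: str) -> np.ndarray:
    """Cluster x {False, True} count table for one binary feature."""
    if feature in ("hypoglycemia", "severe"):
        vals = annotations["glycemic_class"] == feature
    else:
        vals = annotations[feature]
    sub = pd.DataFrame({"cluster": annotations["cluster"], "v": vals}).dropna()
    tab = pd.crosstab(sub["cluster"], sub["v"].astype(bool))
    tab = tab.reindex(columns=[False, True], fill_value=0)
    return tab.to_numpy()


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence without continuity
    correction; returns (statistic, dof, p)."""
    tab = np.asarray(table, dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, dof, _ = stats.chi2_contingency(tab, correction=False)
    return float(stat), int(dof), float(p)


def ks_normality(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic against a normal with the
    sample's own mean and SD; p from the asymptotic KS distribution."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        raise ValueError("need n >= 8")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def group_cluster_heatmap(
    annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Group x cluster matrix of percentages scaled by experimental group
    (each row sums to 100), with row order from Ward/Euclidean hierarchical
    clustering.

    Returns (matrix in original group order, leaf-ordered group labels).
    """
    sub = annotations[annotations["group"] != "none"]
    present = [g for g in GROUP_LABELS if (sub["group"] == g).any()]
    dropped = [g for g in GROUP_LABELS if g not in present]
    if dropped:
        log.warning("empty experimental groups dropped: %s", dropped)
    if len(present) < 2:
        raise ValueError("need at least 2 nonempty experimental groups")
    clusters = sorted(annotations["cluster"].unique())
    mat = pd.DataFrame(0.0, index=present, columns=clusters)
    for g in present:
        counts = sub.loc[sub["group"] == g, "cluster"].value_counts()
        total = counts.sum()
        for k, c in counts.items():
            mat.loc[g, k] = 100.0 * c / total
    Z = hierarchy.ward(pdist(mat.to_numpy()))
    leaves = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(Z, pdist(mat.to_numpy())))
    leaf_order = [present[i] for i in leaves]
    return mat, leaf_order


def strength_band(rho: float) -> str:
    """Correlation strength from |rho|: negligible [0, 0.10), weak
    [0.10, 0.40), moderate [0.40, 0.70), strong [0.70, 0.90), very strong
    [0.90, 1.00]."""
    r = abs(float(rho))
    if r < 0.10:
        return "negligible"
    if r < 0.40:
        return "weak"
    if r < 0.70:
        return "moderate"
    if r < 0.90:
        return "strong"
    if r <= 1.0:
        return "very strong"
    raise ValueError("|rho| must not exceed 1")


def spearman_by_group(glucose, interval) -> tuple[float, float, str]:
    """Spearman rank correlation (average ranks for ties) between paired
    glucose and interval values, with its strength band."""
    g = np.asarray(glucose, dtype=float)
    v = np.asarray(interval, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(v))
    g, v = g[ok], v[ok]
    if len(g) < 10:
        raise ValueError("need at least 10 paired values")
    if np.all(g == g[0]) or np.all(v == v[0]):
        raise ValueError("constant input: Spearman undefined")
    rho, p = stats.spearmanr(g, v)
    return float(rho), float(p), strength_band(rho)


def spearman_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Glucose-interval Spearman correlations per experimental group."""
    rows = []
    for g in GROUP_LABELS:
        sub = annotations[annotations["group"] == g]
        for iv in ("pr_ms", "qt_ms", "qrs_ms"):
            pair = sub[["glucose_mg_dl", iv]].dropna()
            if len(pair) < 10:
                continue
            try:
                rho, p, band = spearman_by_group(pair["glucose_mg_dl"], pair[iv])
            except ValueError:
                continue
            rows.append({"group": g, "interval": iv, "rho": rho, "p": p, "band": band})
    return pd.DataFrame(rows)
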