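"""Grid search over senator/cluster/timepoint configurations and internal
validity scoring.

Models are scored with the Calinski-Harabasz (higher better) and
Davies-Bouldin (lower better) indices computed on the weighted senator set;
the optimal configuration is the one simultaneously best on both, falling
back to elbow heuristics (maximum discrete curvature of the score curve)
when no configuration dominates. Non-converged models are reported but
excluded from selection.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from .shape_cluster import ClusterConfig, fit_kmlshape, reduce_senators, reduce_times

log = logging.getLogger(__name__)

__all__ = [
    "enumerate_grid",
    "calinski_harabasz",
    "davies_bouldin",
    "run_grid",
    "knee_point",
    "elbow_select",
    "STUDY_SENATORS",
    "STUDY_CLUSTERS",
    "STUDY_TIMES",
]

#: The published sweep: 9 senator counts x 9 cluster counts x 4 time
#: reductions = 324 configurations.
STUDY_SENATORS = [100, 150, 200, 250, 300, 350, 400, 450, 500]
STUDY_CLUSTERS = [10, 15, 20, 25, 30, 35, 40, 45, 50]
STUDY_TIMES = [100, 200, 250, None]


def enumerate_grid(
    senator_list: list[int],
    cluster_list: list[int],
    time_list: list[int | None],
    seed: int = 0,
    max_iter: int = 100,
) -> list[ClusterConfig]:
    """Full Cartesian product of the three lists (deduplicated), ordered by
    senators, then clusters, then timepoints (no reduction last)."""
    if not senator_list or not cluster_list or not time_list:
        raise ValueError("grid lists must be nonempty")
    ss = sorted(set(senator_list))
    ks = sorted(set(cluster_list))
    ts = sorted(set(time_list), key=lambda t: (t is None, t if t is not None else 0))
    return [
        ClusterConfig(n_senators=s, n_clusters=k, n_times=t, seed=seed, max_iter=max_iter)
        for s, k, t in itertools.product(ss, ks, ts)
    ]


def _weighted_stats(points: np.ndarray, labels: np.ndarray, weights: np.ndarray | None):
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    n = w.sum()
    c_all = np.average(X, axis=0, weights=w)
    return X, labels, w, uniq, n, c_all


def calinski_harabasz(
    points: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """CH = [B/(K-1)] / [W/(n-K)] with Euclidean dispersion; supports
    weighted points (a senator contributes its weight to n and to B/W).
    Returns +inf (with a warning) when within-cluster dispersion is zero."""
    X, labels, w, uniq, n, c_all = _weighted_stats(points, labels, weights)
    K = len(uniq)
    B = 0.0
    W = 0.0
    for k in uniq:
        mask = labels == k
        n_k = w[mask].sum()
        c_k = np.average(X[mask], axis=0, weights=w[mask])
        B += n_k * float(np.sum((c_k - c_all) ** 2))
        W += float(np.sum(w[mask] * np.sum((X[mask] - c_k) ** 2, axis=1)))
    if W <= 0.0:
        warnings.warn("zero within-cluster dispersion; CH is infinite")
        return float("inf")
    return (B / (K - 1)) / (W / (n - K))


def davies_bouldin(
    points: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """DB = mean_k max_{j!=k} (s_k + s_j) / d(c_k, c_j), where s is the
    (weighted) mean Euclidean distance to the own centroid."""
    X, labels, w, uniq, n, _ = _weighted_stats(points, labels, weights)
    K = len(uniq)
    cents = np.empty((K, X.shape[1]))
    scatter = np.empty(K)
    for i, k in enumerate(uniq):
        mask = labels == k
        cents[i] = np.average(X[mask], axis=0, weights=w[mask])
        d = np.sqrt(np.sum((X[mask] - cents[i]) ** 2, axis=1))
        scatter[i] = np.average(d, weights=w[mask])
    total = 0.0
    for i in range(K):
        worst = -np.inf
        for j in range(K):
            if i == j:
                continue
            gap = float(np.sqrt(np.sum((cents[i] - cents[j]) ** 2)))
            if gap <= 0.0:
                raise ValueError("coincident centroids: Davies-Bouldin undefined")
            worst = max(worst, (scatter[i] + scatter[j]) / gap)
        total += worst
    return total / K


def run_grid(
    beats: np.ndarray,
    grid: list[ClusterConfig],
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit every configuration and score converged models on the weighted
    senator set. Senator and timepoint reductions are cached across
    configurations that share them.

    Returns one row per configuration: (n_senators, n_clusters, n_times,
    converged, ch, db, n_iter).
    """
    X = np.asarray(beats, dtype=float)
    time_cache: dict[int | None, tuple[np.ndarray, np.ndarray]] = {}
    senator_cache: dict[tuple[int | None, int, int], tuple] = {}
    rows = []
    for cfg in grid:
        if cfg.n_times not in time_cache:
            time_cache[cfg.n_times] = reduce_times(X, cfg.n_times, times)
        Xt, tt = time_cache[cfg.n_times]
        skey = (cfg.n_times, cfg.n_senators, cfg.seed)
        if skey not in senator_cache:
            senator_cache[skey] = reduce_senators(Xt, cfg.n_senators, cfg.seed)
        senators, weights, _ = senator_cache[skey]
        model = fit_kmlshape(senators, weights, cfg, tt)
        ch = db = np.nan
        if model.converged:
            try:
                ch = calinski_harabasz(model.senators, model.senator_labels, model.weights)
                db = davies_bouldin(model.senators, model.senator_labels, model.weights)
            except ValueError as exc:  # degenerate partition
                log.warning("scoring failed for %s: %s", cfg, exc)
        rows.append(
            {
                "n_senators": cfg.n_senators,
                "n_clusters": cfg.n_clusters,
                "n_times": cfg.n_times,
                "converged": model.converged,
                "ch": ch,
                "db": db,
                "n_iter": model.n_iter,
            }
        )
    return pd.DataFrame(rows)


def knee_point(xs: np.ndarray, ys: np.ndarray) -> float:
    """Knee of a score curve: the interior point of maximum discrete
    curvature (most negative second difference) of y over x."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3:
        raise ValueError("need at least 3 points for a knee")
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    second = ys[:-2] - 2.0 * ys[1:-1] + ys[2:]
    return float(xs[1 + int(np.argmin(second))])


def elbow_select(grid_result: pd.DataFrame) -> tuple[int, int, int | None]:
    """Pick (S, K, T') from a scored grid.

    Primary rule: the converged configuration that simultaneously maximizes
    CH and minimizes DB. Otherwise, the CH-knee over the cluster axis whose
    DB is within 10% of the minimum. Ties break toward smaller S, then
    smaller K. With fewer than 3 converged rows, falls back to argmax CH
    with a warning.
    """
    df = grid_result[grid_result["converged"] & grid_result["ch"].notna()].copy()
    if df.empty:
        raise ValueError("no converged configurations to select from")

    def _cfg(row) -> tuple[int, int, int | None]:
        t = row["n_times"]
        return (
            int(row["n_senators"]),
            int(row["n_clusters"]),
            None if pd.isna(t) else int(t),
        )

    df = df.sort_values(["n_senators", "n_clusters"], kind="stable")
    if len(df) < 3:
        warnings.warn("fewer than 3 converged configurations; using argmax CH")
        return _cfg(df.loc[df["ch"].idxmax()])

    best_ch = df["ch"].max()
    best_db = df["db"].min()
    dominant = df[(df["ch"] == best_ch) & (df["db"] == best_db)]
    if len(dominant):
        return _cfg(dominant.iloc[0])

    candidates = []
    for (s, t), sub in df.groupby(["n_senators", "n_times"], dropna=False):
        sub = sub.sort_values("n_clusters")
        if len(sub) < 3:
            continue
        knee_k = knee_point(sub["n_clusters"].to_numpy(), sub["ch"].to_numpy())
        row = sub[sub["n_clusters"] == knee_k].iloc[0]
        candidates.append(row)
    if candidates:
        cand = pd.DataFrame(candidates)
        ok = cand[cand["db"] <= 1.1 * best_db]
        pool = ok if len(ok) else cand
        pool = pool.sort_values(["n_senators", "n_clusters"], kind="stable")
        return _cfg(pool.loc[pool["ch"].idxmax()])
    warnings.warn("no axis with >= 3 points; using argmax CH")
    return _cfg(df.loc[df["ch"].idxmax()])
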