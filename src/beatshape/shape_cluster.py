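"""Shape-respecting k-means over beat trajectories (kmlShape-style).

Trajectories are compared with the discrete Fréchet distance over points
(lambda * t, value), where lambda weights the time axis relative to the
value axis. Because the Fréchet distance is expensive, the beat set is first
reduced to weighted "senators" (representative trajectories from a Euclidean
k-means partition, each carrying its group size as weight) and optionally
resampled to fewer timepoints. Centers are updated as weight-weighted
pointwise arithmetic means, which keeps iterations deterministic and cheap
and matches how cluster centers are reported downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

__all__ = [
    "ClusterConfig",
    "ClusterModel",
    "frechet_distance",
    "reduce_senators",
    "reduce_times",
    "fit_kmlshape",
    "assign_all",
]


def _frechet_dp_matrix_py(D: np.ndarray) -> float:
    """Coupling recursion over a precomputed point-distance matrix; only
    max/min operations, hence exact for any metric supplied in ``D``."""
    n, m = D.shape
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = D[0, 0]
    for j in range(1, m):
        prev[j] = max(prev[j - 1], D[0, j])
    for i in range(1, n):
        cur[0] = max(prev[0], D[i, 0])
        for j in range(1, m):
            cur[j] = max(D[i, j], min(prev[j], prev[j - 1], cur[j - 1]))
        prev, cur = cur, prev
    return float(prev[m - 1])


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _frechet_dp_matrix = njit(cache=True)(_frechet_dp_matrix_py)
except Exception:  # pragma: no cover
    log.warning("numba unavailable; falling back to pure-Python Frechet DP")
    _frechet_dp_matrix = _frechet_dp_matrix_py


def _frechet_dp(ax: np.ndarray, ay: np.ndarray, bx: np.ndarray, by: np.ndarray) -> float:
    # only correctly-rounded IEEE ops (-, *, +, sqrt) so the distance matrix
    # is reproducible bit-for-bit across implementations
    dx = ax[:, None] - bx[None, :]
    dy = ay[:, None] - by[None, :]
    D = np.sqrt(dx * dx + dy * dy)
    return _frechet_dp_matrix(D)


def frechet_distance(a: np.ndarray, b: np.ndarray, timescale: float = 1.0) -> float:
    """Discrete Fréchet distance between two trajectories.

    ``a`` and ``b`` are either (n, 2) arrays of (time, value) points or 1-D
    value arrays (times taken as sample indices). The time coordinate is
    multiplied by ``timescale`` before computing Euclidean point distances;
    ``timescale=0`` compares values only (pure shape).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("trajectories must be nonempty")
    if a.ndim == 1:
        a = np.column_stack([np.arange(len(a)), a])
    if b.ndim == 1:
        b = np.column_stack([np.arange(len(b)), b])
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("trajectories must not contain missing values")
    lam = float(timescale)
    return _frechet_dp(
        np.ascontiguousarray(lam * a[:, 0]),
        np.ascontiguousarray(a[:, 1]),
        np.ascontiguousarray(lam * b[:, 0]),
        np.ascontiguousarray(b[:, 1]),
    )


@dataclass(frozen=True)
class ClusterConfig:
    """Configuration of one kmlShape-style model: S senators, K clusters,
    optional timepoint reduction T', iteration cap and seed.

    ``timescale`` is the Fréchet time-axis weight (default 0.1 per unit
    time against the min-max-scaled amplitude, so a 10-unit time shift
    costs as much as the full amplitude range; interval prolongations stay
    visible to the distance instead of being absorbed by time warping);
    None balances the value span against the time span of the data at fit
    time. ``n_init`` restarts the seeded initialization and keeps the fit
    with the lowest weighted within-cluster Fréchet cost."""

    n_senators: int
    n_clusters: int
    n_times: int | None = None
    max_iter: int = 100
    seed: int = 0
    timescale: float | None = 0.1
    n_init: int = 5

    def __post_init__(self) -> None:
        if self.n_senators < self.n_clusters:
            raise ValueError("need n_senators >= n_clusters")
        if self.n_clusters < 1:
            raise ValueError("need n_clusters >= 1")


@dataclass
class ClusterModel:
    senators: np.ndarray  # (S, T) value trajectories
    weights: np.ndarray  # (S,) positive group sizes
    centers: np.ndarray  # (K, T)
    senator_labels: np.ndarray  # (S,) in 1..K
    converged: bool
    n_iter: int
    config: ClusterConfig
    times: np.ndarray | None = None
    timescale: float = 0.0
    cost_history: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": {
                "n_senators": self.config.n_senators,
                "n_clusters": self.config.n_clusters,
                "n_times": self.config.n_times,
                "max_iter": self.config.max_iter,
                "seed": self.config.seed,
                "timescale": self.config.timescale,
                "n_init": self.config.n_init,
            },
            "senators": self.senators.tolist(),
            "weights": self.weights.tolist(),
            "centers": self.centers.tolist(),
            "senator_labels": self.senator_labels.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "times": None if self.times is None else self.times.tolist(),
            "timescale": self.timescale,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        cfg = ClusterConfig(**d["config"])
        return cls(
            senators=np.asarray(d["senators"]),
            weights=np.asarray(d["weights"]),
            centers=np.asarray(d["centers"]),
            senator_labels=np.asarray(d["senator_labels"]),
            converged=d["converged"],
            n_iter=d["n_iter"],
            config=cfg,
            times=None if d.get("times") is None else np.asarray(d["times"]),
            timescale=d.get("timescale", 0.0),
        )

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reduce_senators(
    beats: np.ndarray, n_senators: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition beats into ``n_senators`` groups by Euclidean k-means and
    represent each group by its pointwise mean, weighted by group size.

    Returns (senators, weights, beat_to_senator map). When ``n_senators`` is
    at least the number of beats the reduction is the identity.
    """
    if n_senators < 1:
        raise ValueError("n_senators must be >= 1")
    X = np.asarray(beats, dtype=float)
    n = len(X)
    if np.isnan(X).any():
        raise ValueError("beats must be imputed before senator reduction")
    if n_senators >= n:
        return X.copy(), np.ones(n), np.arange(n)
    km = KMeans(n_clusters=n_senators, n_init=2, random_state=seed)
    mapping = km.fit_predict(X)
    counts = np.bincount(mapping, minlength=n_senators)
    keep = counts > 0
    if not keep.all():
        # drop empty senators and compact the mapping
        new_ids = -np.ones(n_senators, dtype=int)
        new_ids[keep] = np.arange(keep.sum())
        mapping = new_ids[mapping]
    senators = km.cluster_centers_[keep]
    weights = counts[keep].astype(float)
    return senators, weights, mapping


def reduce_times(
    beats: np.ndarray, n_times: int | None, times: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of every trajectory onto ``n_times`` equally
    spaced timepoints spanning the original window; None is the identity.

    Returns (reduced beats, reduced times).
    """
    X = np.asarray(beats, dtype=float)
    if times is None:
        times = np.arange(X.shape[1], dtype=float)
    times = np.asarray(times, dtype=float)
    if n_times is None:
        return X, times
    if n_times < 2:
        raise ValueError("n_times must be >= 2")
    if n_times > X.shape[1]:
        raise ValueError("n_times exceeds current trajectory length")
    new_times = np.linspace(times[0], times[-1], n_times)
    out = np.empty((X.shape[0], n_times))
    for i in range(X.shape[0]):
        out[i] = np.interp(new_times, times, X[i])
    return out, new_times


def _distances_to_centers(
    tx: np.ndarray, senators: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    S, K = len(senators), len(centers)
    D = np.empty((S, K))
    for k in range(K):
        cy = np.ascontiguousarray(centers[k])
        for s in range(S):
            D[s, k] = _frechet_dp(tx, np.ascontiguousarray(senators[s]), tx, cy)
    return D


def _kmeanspp_init(
    tx: np.ndarray, senators: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++-style seeding over Fréchet distances."""
    S = len(senators)
    centers = [int(rng.integers(S))]
    d2 = np.array(
        [
            _frechet_dp(tx, np.ascontiguousarray(senators[s]), tx, np.ascontiguousarray(senators[centers[0]])) ** 2
            for s in range(S)
        ]
    )
    while len(centers) < k:
        total = d2.sum()
        if total <= 0:
            remaining = [s for s in range(S) if s not in centers]
            centers.append(int(rng.choice(remaining)))
            continue
        probs = d2 / total
        nxt = int(rng.choice(S, p=probs))
        if nxt in centers:
            nxt = int(np.argmax(d2))
        centers.append(nxt)
        new_d = np.array(
            [
                _frechet_dp(tx, np.ascontiguousarray(senators[s]), tx, np.ascontiguousarray(senators[nxt])) ** 2
                for s in range(S)
            ]
        )
        d2 = np.minimum(d2, new_d)
    return senators[np.array(centers)].copy()


def _fit_once(
    tx: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    K: int,
    max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool, int, float, list[tuple[float, float]]]:
    centers = _kmeanspp_init(tx, X, K, rng)
    D = _distances_to_centers(tx, X, centers)
    labels = D.argmin(axis=1)
    history: list[tuple[float, float]] = []
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        # center update (weighted pointwise mean); re-seed empty clusters
        for k in range(K):
            mask = labels == k
            if mask.any():
                centers[k] = np.average(X[mask], axis=0, weights=w[mask])
        empty = [k for k in range(K) if not (labels == k).any()]
        if empty:
            own = D[np.arange(len(X)), labels]
            order = np.argsort(own)[::-1]
            for k, s in zip(empty, order):
                centers[k] = X[s].copy()
        D = _distances_to_centers(tx, X, centers)
        cost_before = float(np.sum(w * D[np.arange(len(X)), labels]))
        new_labels = D.argmin(axis=1)
        cost_after = float(np.sum(w * D[np.arange(len(X)), new_labels]))
        history.append((cost_before, cost_after))
        n_iter = it
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    final_cost = float(np.sum(w * D[np.arange(len(X)), labels]))
    return labels, centers, converged, n_iter, final_cost, history


def fit_kmlshape(
    senators: np.ndarray,
    weights: np.ndarray,
    config: ClusterConfig,
    times: np.ndarray | None = None,
) -> ClusterModel:
    """Fréchet k-means over weighted senators.

    Deterministically seeded k-means++ initialization (``n_init`` restarts,
    best final cost kept); iterate assignment of each senator to its nearest
    center by Fréchet distance, then update each center as the
    weight-weighted pointwise mean of its senators. Converged when
    assignments stop changing; an empty cluster is re-seeded from the
    senator farthest from its own center. Cluster ids are renumbered 1..K by
    descending total weight.
    """
    X = np.asarray(senators, dtype=float)
    w = np.asarray(weights, dtype=float)
    K = config.n_clusters
    if len(X) < K:
        raise ValueError("need at least as many senators as clusters")
    if times is None:
        times = np.arange(X.shape[1], dtype=float)
    times = np.asarray(times, dtype=float)
    lam = config.timescale
    if lam is None:
        t_span = float(times[-1] - times[0]) or 1.0
        v_span = float(X.max() - X.min()) or 1.0
        lam = v_span / t_span
    tx = np.ascontiguousarray(lam * times)

    best = None
    for init in range(max(config.n_init, 1)):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, init]))
        fit = _fit_once(tx, X, w, K, config.max_iter, rng)
        # prefer converged fits, then lower final cost
        key = (not fit[2], fit[4])
        if best is None or key < best[0]:
            best = (key, fit)
    labels, centers, converged, n_iter, _, history = best[1]

    # renumber clusters 1..K by descending total weight (ties by old id)
    totals = np.array([w[labels == k].sum() for k in range(K)])
    order = np.argsort(-totals, kind="stable")
    rank = np.empty(K, dtype=int)
    rank[order] = np.arange(1, K + 1)
    final_labels = rank[labels]
    centers = centers[order]

    return ClusterModel(
        senators=X,
        weights=w,
        centers=centers,
        senator_labels=final_labels,
        converged=converged,
        n_iter=n_iter,
        config=config,
        times=times,
        timescale=lam,
        cost_history=history,
    )


def assign_all(beat_to_senator: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Propagate senator cluster labels (1..K) back to every beat through
    the beat -> senator map."""
    mapping = np.asarray(beat_to_senator, dtype=int)
    if mapping.min() < 0 or mapping.max() >= len(model.senator_labels):
        raise ValueError("beat->senator map refers to unknown senators")
    return model.senator_labels[mapping]
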