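"""K-means clustering of longitudinal adherence trajectories.

Patients are clustered on their vectors of windowed CMA9 values (12 monthly
values in the default design) using Lloyd's algorithm with squared
Euclidean distance — the same family of longitudinal k-means used for
group-based trajectory modelling of adherence. No standardization or
smoothing is applied: every dimension already lives on the shared [0, 1]
adherence scale.

The number of groups is chosen by maximizing the Calinski–Harabasz
variance-ratio criterion over a candidate range, and fitted clusters are
given semantic adherence labels (high / partial drop-off / moderate / low)
by deterministic rules on their centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ClusterModel",
    "kmeans_longitudinal",
    "calinski_harabasz",
    "select_k",
    "label_clusters",
    "plot_trajectory_bundles",
]

#: Semantic labels in decreasing adherence order (plus the shape-based one).
GROUP_LABELS = ("high", "partial_drop_off", "moderate", "low", "other")


@dataclass
class ClusterModel:
    """A fitted k-means solution over trajectory space."""

    k: int
    centroids: np.ndarray  # (k, n_windows)
    assignments: np.ndarray  # (n,) cluster index per row
    inertia: float  # within-cluster sum of squares
    ch_score: float
    labels: dict = field(default_factory=dict)  # cluster index -> semantic label
    patient_ids: Optional[np.ndarray] = None
    ch_by_k: dict = field(default_factory=dict)  # populated by select_k

    def label_of(self, patient_index: int) -> str:
        return self.labels[int(self.assignments[patient_index])]


def _validate_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("trajectories must be a non-empty 2-D array")
    if not np.isfinite(X).all():
        raise ValueError("trajectories contain non-finite values")
    return X


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by D^2 sampling."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0.0:  # all remaining points coincide with a center
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Lloyd iterations until assignments stabilize.

    Empty clusters are re-seeded from the point farthest from its assigned
    centroid. Returns (centroids, assignments, inertia, per-iteration WCSS
    trace); the trace is non-increasing.
    """
    centers = centers.copy()
    prev = None
    trace: list[float] = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        point_d2 = d2[np.arange(len(X)), assign]
        trace.append(float(point_d2.sum()))
        for j in range(len(centers)):
            members = assign == j
            if members.any():
                centers[j] = X[members].mean(axis=0)
            else:
                far = int(point_d2.argmax())
                centers[j] = X[far]
                assign[far] = j
                point_d2[far] = 0.0
        if prev is not None and np.array_equal(assign, prev):
            break
        prev = assign
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(len(X)), assign].sum())
    return centers, assign, inertia, trace


def kmeans_longitudinal(
    trajectories: np.ndarray,
    k: int,
    n_starts: int = 20,
    max_iter: int = 100,
    seed: Optional[int] = None,
    patient_ids: Optional[Sequence] = None,
) -> ClusterModel:
    """Fit k-means on trajectory vectors; best of ``n_starts`` k-means++ restarts.

    Raises if ``k < 2`` or the data hold fewer than ``k`` distinct rows
    (degenerate input such as all-identical trajectories).
    """
    X = _validate_matrix(trajectories)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct trajectories; cannot form k={k} clusters"
        )
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        centers0 = _kmeanspp_init(X, k, rng)
        centers, assign, inertia, _ = _lloyd(X, centers0, max_iter)
        if best is None or inertia < best[2]:
            best = (centers, assign, inertia)
    centers, assign, inertia = best
    model = ClusterModel(
        k=k,
        centroids=centers,
        assignments=assign,
        inertia=inertia,
        ch_score=float("nan"),
        patient_ids=None if patient_ids is None else np.asarray(patient_ids),
    )
    model.ch_score = calinski_harabasz(X, model.assignments)
    return model


def calinski_harabasz(trajectories: np.ndarray, assignments: np.ndarray) -> float:
    """Variance-ratio criterion CH = (B/(k-1)) / (W/(n-k)).

    B is the between-group scatter (size-weighted squared distances of
    cluster means from the grand mean) and W the pooled within-group
    scatter. A perfect partition (W = 0) scores +inf.
    """
    X = _validate_matrix(trajectories)
    assign = np.asarray(assignments)
    groups = np.unique(assign)
    n, k = X.shape[0], len(groups)
    if k <= 1:
        raise ValueError(f"Calinski-Harabasz requires k >= 2 groups, got {k}")
    if n <= k:
        raise ValueError(f"Calinski-Harabasz requires n > k, got n={n}, k={k}")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for g in groups:
        members = X[assign == g]
        c = members.mean(axis=0)
        B += len(members) * float(((c - grand) ** 2).sum())
        W += float(((members - c) ** 2).sum())
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def select_k(
    trajectories: np.ndarray,
    k_range: Sequence[int] = range(2, 7),
    n_starts: int = 20,
    max_iter: int = 100,
    seed: Optional[int] = None,
    patient_ids: Optional[Sequence] = None,
) -> ClusterModel:
    """Fit each candidate k and keep the Calinski–Harabasz maximizer.

    Ties are broken toward the smaller k. The per-k scores are recorded in
    ``model.ch_by_k``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    seeds = np.random.SeedSequence(seed).spawn(len(ks))
    best_model = None
    ch_by_k: dict[int, float] = {}
    for k, ss in zip(ks, seeds):
        model = kmeans_longitudinal(
            trajectories,
            k,
            n_starts=n_starts,
            max_iter=max_iter,
            seed=np.random.default_rng(ss).integers(2**31),
            patient_ids=patient_ids,
        )
        ch_by_k[k] = model.ch_score
        if best_model is None or model.ch_score > best_model.ch_score:
            best_model = model
    best_model.ch_by_k = ch_by_k
    return best_model


def label_clusters(model: ClusterModel) -> ClusterModel:
    """Attach semantic adherence labels to clusters by centroid rules.

    A cluster whose centroid starts high (mean of the first third of
    windows >= 0.7) and ends low (mean of the last third <= 0.35) is the
    drop-off pattern, ``partial_drop_off``. The remaining clusters are
    ranked by overall centroid mean: top -> ``high``, bottom -> ``low``,
    single middle -> ``moderate``; any surplus clusters are ``other``.
    """
    k, d = model.centroids.shape
    third = max(1, d // 3)
    labels: dict[int, str] = {}
    remaining = []
    for j in range(k):
        c = model.centroids[j]
        if c[:third].mean() >= 0.7 and c[-third:].mean() <= 0.35:
            labels[j] = "partial_drop_off"
        else:
            remaining.append(j)
    remaining.sort(key=lambda j: -model.centroids[j].mean())
    if remaining:
        labels[remaining[0]] = "high"
    if len(remaining) >= 2:
        labels[remaining[-1]] = "low"
    middle = remaining[1:-1]
    if middle:
        # the rank-central cluster is the moderate pattern; surplus -> other
        mid_idx = (len(middle) - 1) // 2
        for pos, j in enumerate(middle):
            labels[j] = "moderate" if pos == mid_idx else "other"
    return replace(model, labels={j: labels[j] for j in sorted(labels)})


def plot_trajectory_bundles(
    trajectories: np.ndarray, model: ClusterModel, path: str, max_lines: int = 150
) -> None:
    """Spaghetti plot of per-cluster trajectories with centroids overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = np.asarray(trajectories, dtype=float)
    order = sorted(range(model.k), key=lambda j: -model.centroids[j].mean())
    fig, axes = plt.subplots(1, model.k, figsize=(3.2 * model.k, 3), sharey=True)
    axes = np.atleast_1d(axes)
    months = np.arange(1, X.shape[1] + 1)
    for ax, j in zip(axes, order):
        members = X[model.assignments == j]
        for row in members[:max_lines]:
            ax.plot(months, row, color="grey", alpha=0.15, lw=0.6)
        ax.plot(months, model.centroids[j], color="crimson", lw=2)
        ax.set_title(model.labels.get(j, f"cluster {j}"))
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel("month")
    axes[0].set_ylabel("CMA9")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
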