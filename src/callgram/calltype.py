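"""Call-type clustering from (duration, maximum frequency).

Partitioning Around Medoids (PAM, the classic deterministic BUILD + SWAP
k-medoids of Kaufman & Rousseeuw) on z-scored features with Euclidean
dissimilarity, silhouette-based selection of the cluster count, and mapping
of the two-cluster solution to the field labels: the low-frequency class is
"A", the high-frequency class "B".

PAM rather than k-means because medoids are actual calls and the total-cost
objective is robust to outlying measurements; BUILD + SWAP is deterministic
given the row order, which keeps the whole pipeline reproducible without
restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def standardize_features(features, columns=("duration_s", "max_freq_khz")):
    """Z-score each column; returns (matrix, Standardizer).

    Raises on fewer than two rows, non-finite entries, or a zero-variance
    column (named in the error).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 calls with feature columns")
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s <= 0:
            name = columns[j] if j < len(columns) else f"column {j}"
            raise ValueError(f"zero-variance feature column: {name}")
    scaler = Standardizer(mean, sd, tuple(columns))
    return scaler.transform(x), scaler


@dataclass
class PamResult:
    """k-medoids solution on one feature matrix."""

    k: int
    medoids: np.ndarray          # row indices of the medoid calls
    labels: np.ndarray           # per-call cluster id in [0, k)
    total_cost: float            # sum of distances to the nearest medoid
    n_swaps: int
    per_point_silhouette: np.ndarray | None = None
    mean_silhouette: float | None = None


def _dissimilarity(x: np.ndarray) -> np.ndarray:
    d = x[:, None, :] - x[None, :, :]
    return np.sqrt((d * d).sum(axis=-1))


def pam_cluster(features, k: int, max_iter: int = 100) -> PamResult:
    """Classic PAM: greedy BUILD seeding then best-improvement SWAP.

    SWAP evaluates every (medoid, non-medoid) exchange, applies the single
    best cost-decreasing one, and repeats until no exchange improves the
    total cost or ``max_iter`` sweeps have run.  Total cost is non-increasing
    across sweeps.  Deterministic given input order (first best exchange in
    scan order wins ties).
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    dist = _dissimilarity(x)

    # BUILD: first medoid minimizes total distance; each next medoid gives
    # the largest reduction of the cost against the current nearest-medoid
    # distances.
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(dist, nearest[None, :]).sum(axis=1)
        gains[medoids] = np.inf
        m = int(np.argmin(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, dist[m])

    medoids = np.array(medoids)
    n_swaps = 0
    for _ in range(max_iter):
        dmed = dist[medoids]                    # (k, n)
        cost = dmed.min(axis=0).sum()
        best = (0.0, None)
        for mi in range(k):
            others = np.delete(medoids, mi)
            rest = dist[others].min(axis=0) if len(others) else np.full(n, np.inf)
            # cost after swapping medoid mi for candidate h, all h at once
            cand_cost = np.minimum(rest[:, None], dist).sum(axis=0)
            cand_cost[medoids] = np.inf
            h = int(np.argmin(cand_cost))
            delta = cand_cost[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        n_swaps += 1
    dmed = dist[medoids]
    labels = dmed.argmin(axis=0)
    labels[medoids] = np.arange(k)  # medoids belong to their own cluster
    total_cost = float(dmed[labels, np.arange(n)].sum())
    sil, mean_sil = silhouette_from_dist(dist, labels)
    return PamResult(k, medoids, labels, total_cost, n_swaps, sil, mean_sil)


def silhouette_from_dist(dist: np.ndarray, labels: np.ndarray):
    """Silhouette widths s(i) = (b-a)/max(a,b) from a dissimilarity matrix.

    a(i) is the mean distance to the other members of i's cluster, b(i) the
    smallest mean distance to any other cluster.  Points in singleton
    clusters get s(i)=0 by convention.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = dist.shape[0]
    sums = np.stack([dist[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if sizes[c] == 1:
            continue
        a = sums[i, c] / (sizes[c] - 1)
        b = np.min(np.delete(sums[i] / sizes, c))
        s[i] = (b - a) / max(a, b)
    return s, float(s.mean())


def silhouette(features, labels):
    """Silhouette widths on Euclidean distances of a feature matrix."""
    x = np.asarray(features, dtype=float)
    return silhouette_from_dist(_dissimilarity(x), labels)


def select_k(features, k_range=range(2, 11), max_iter: int = 100):
    """Cluster for each k and return (best_k, {k: mean silhouette}).

    The mean silhouette is undefined at k=1, so scanning starts at 2; ties
    break toward the smaller k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    curve: dict[int, float] = {}
    for k in ks:
        curve[k] = pam_cluster(features, k, max_iter=max_iter).mean_silhouette
    best_k = max(ks, key=lambda k: (curve[k], -k))
    return best_k, curve


def label_clusters(result: PamResult, max_frequency) -> np.ndarray:
    """Map the two clusters to "A"/"B" by mean maximum frequency.

    The low-frequency cluster is "A" (short, low call), the high-frequency
    cluster "B".  Only defined for k=2.
    """
    if result.k != 2:
        raise ValueError("A/B labeling requires exactly 2 clusters")
    freq = np.asarray(max_frequency, dtype=float)
    means = [freq[result.labels == c].mean() for c in (0, 1)]
    if means[0] == means[1]:
        raise ValueError("ambiguous mapping: equal mean max frequencies")
    low = int(np.argmin(means))
    out = np.where(result.labels == low, "A", "B")
    return out
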