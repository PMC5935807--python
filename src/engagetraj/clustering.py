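"""k-medoids clustering of FPC scores and prediction-strength model selection.

PAM (partitioning around medoids) is implemented with the classic BUILD
phase (greedy medoid selection minimizing incremental total cost) followed
by steepest-descent SWAP (repeatedly apply the single best medoid/non-medoid
exchange that strictly lowers total cost). CLARA scales PAM to large N by
running it on random subsamples — each subsequent subsample seeded with the
incumbent best medoids — and keeping the medoid set with the lowest
full-data cost. Distances are unweighted Euclidean on the score vectors;
an option to scale scores by 1/sqrt(eigenvalue) is available upstream but
off by default, since FPC scores are already variance-ordered.

The number of clusters is chosen by prediction strength: the data are
randomly halved, both halves clustered separately, and each test cluster is
scored by the fraction of its ordered point pairs that remain co-assigned
when test points are classified by their nearest *training* medoid; the
split's score for a given k is the minimum over test clusters. k = 1 scores
1 by construction. The selected k is the largest candidate whose mean score
over splits reaches the threshold (default 0.85).

All procedures are deterministic given the input order and a single integer
seed; ties are always broken toward the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusteringResult",
    "PredictionStrengthCurve",
    "pam",
    "clara",
    "assign_to_medoids",
    "prediction_strength",
    "relabel_by_size",
]


@dataclass
class ClusteringResult:
    """Hard k-medoids partition: medoid rows, 1-based labels and total cost."""

    k: int
    medoid_indices: np.ndarray  # (k,) row indices into the clustered data
    labels: np.ndarray  # (N,) values in 1..k
    total_cost: float
    medoids: np.ndarray  # (k, p) medoid coordinates

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def _as_points(points: np.ndarray) -> np.ndarray:
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or not np.isfinite(x).all():
        raise ValueError("points must be a finite N x p array")
    return x


def _pam_core(d: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """BUILD + SWAP on a precomputed distance matrix; returns (medoids, cost)."""
    n = d.shape[0]
    # BUILD: greedy, ties to the lowest index (np.argmin is first-minimum)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        costs = np.minimum(nearest[None, :], d).sum(axis=1)
        costs[medoids] = np.inf
        j = int(np.argmin(costs))
        medoids.append(j)
        nearest = np.minimum(nearest, d[j])
    medoids = np.array(sorted(medoids))
    if k == n:
        return medoids, 0.0
    # SWAP: steepest descent over all (medoid, non-medoid) exchanges
    while True:
        dm = d[medoids]  # (k, N)
        order = np.argsort(dm, axis=0, kind="stable")
        lab = order[0]  # position of nearest medoid
        d1 = dm[lab, np.arange(n)]
        if k > 1:
            d2 = dm[order[1], np.arange(n)]
        else:
            d2 = np.full(n, np.inf)
        current = d1.sum()
        non = np.setdiff1d(np.arange(n), medoids)
        best = (current, None)
        for m_pos in range(k):
            others = np.where(lab == m_pos, d2, d1)  # (N,) nearest among retained medoids
            cand = np.minimum(others[None, :], d[non]).sum(axis=1)  # (len(non),)
            h = int(np.argmin(cand))
            if cand[h] < best[0]:
                best = (float(cand[h]), (m_pos, non[h]))
        if best[1] is None:
            return medoids, float(current)
        m_pos, h = best[1]
        medoids = np.array(sorted(np.concatenate([np.delete(medoids, m_pos), [h]])))


def pam(points: np.ndarray, k: int, seed: int | None = None) -> ClusteringResult:
    """Partitioning around medoids with Euclidean distance.

    Deterministic given the input row order (``seed`` is accepted only for
    interface symmetry with :func:`clara` and is ignored).
    """
    x = _as_points(points)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    d = cdist(x, x)
    medoids, cost = _pam_core(d, k)
    labels = _labels_from(d[medoids])
    return ClusteringResult(k, medoids, labels, cost, x[medoids].copy())


def _labels_from(dist_to_medoids: np.ndarray) -> np.ndarray:
    """1-based labels by nearest medoid; exact ties go to the lowest medoid index."""
    return np.argmin(dist_to_medoids, axis=0) + 1


def assign_to_medoids(points: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Label each point by its nearest medoid coordinate (ties: lowest index)."""
    x = _as_points(points)
    m = _as_points(medoids)
    if m.shape[0] < 1:
        raise ValueError("medoids must be nonempty")
    return _labels_from(cdist(m, x))


def clara(
    points: np.ndarray,
    k: int,
    n_samples: int = 5,
    sample_size: int | None = None,
    seed: int = 0,
) -> ClusteringResult:
    """CLARA: PAM on random subsamples, keeping the best full-data medoid set.

    With ``sample_size >= N`` and ``n_samples = 1`` this reduces exactly to
    :func:`pam`. After the first draw, each subsample is forced to include
    the incumbent best medoids, per the classic scheme.
    """
    x = _as_points(points)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if sample_size is None:
        sample_size = min(n, 40 + 2 * k)
    if sample_size < k:
        raise ValueError(f"sample_size must be >= k, got {sample_size} < {k}")
    sample_size = min(sample_size, n)
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_medoids: np.ndarray | None = None
    for _ in range(max(1, n_samples)):
        if sample_size >= n:
            subset = np.arange(n)
        elif best_medoids is None:
            subset = np.sort(rng.choice(n, size=sample_size, replace=False))
        else:
            pool = np.setdiff1d(np.arange(n), best_medoids)
            extra = rng.choice(pool, size=sample_size - k, replace=False)
            subset = np.sort(np.concatenate([best_medoids, extra]))
        sub_res = _pam_core(cdist(x[subset], x[subset]), k)
        medoids = subset[sub_res[0]]
        cost = float(cdist(x[medoids], x).min(axis=0).sum())
        if cost < best_cost:
            best_cost = cost
            best_medoids = medoids
    assert best_medoids is not None
    best_medoids = np.sort(best_medoids)
    dist = cdist(x[best_medoids], x)
    labels = _labels_from(dist)
    return ClusteringResult(k, best_medoids, labels, float(dist.min(axis=0).sum()), x[best_medoids].copy())


@dataclass
class PredictionStrengthCurve:
    """Mean/sd prediction strength per candidate k and the selected k."""

    k_values: np.ndarray  # (k_max,) = 1..k_max
    ps_mean: np.ndarray
    ps_sd: np.ndarray
    threshold: float
    selected_k: int


def _split_strength(
    x: np.ndarray, train: np.ndarray, test: np.ndarray, k: int, seed_train: int, seed_test: int
) -> float:
    ctrain = clara(x[train], k, seed=seed_train)
    ctest = clara(x[test], k, seed=seed_test)
    by_train_medoid = assign_to_medoids(x[test], ctrain.medoids)
    strengths = []
    for j in range(1, k + 1):
        members = by_train_medoid[ctest.labels == j]
        nj = len(members)
        if nj < 2:
            continue
        counts = np.bincount(members)
        strengths.append(float((counts * (counts - 1)).sum() / (nj * (nj - 1))))
    return min(strengths) if strengths else 1.0


def prediction_strength(
    points: np.ndarray,
    k_max: int,
    n_splits: int = 20,
    threshold: float = 0.85,
    seed: int = 0,
) -> PredictionStrengthCurve:
    """Prediction-strength curve over k = 1..k_max and the selected k.

    The selected k is the largest candidate with mean prediction strength at
    or above the threshold; k = 1 always qualifies (its strength is 1 by
    construction), so the fallback is 1.
    """
    x = _as_points(points)
    n = x.shape[0]
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if 2 * k_max > n:
        raise ValueError(f"k_max must be <= N/2 = {n // 2}, got {k_max}")
    rng = np.random.default_rng(seed)
    ps = np.ones((n_splits, k_max))
    for s in range(n_splits):
        perm = rng.permutation(n)
        train, test = perm[: n // 2], perm[n // 2 :]
        for k in range(2, k_max + 1):
            seeds = rng.integers(0, 2**31 - 1, size=2)
            ps[s, k - 1] = _split_strength(x, train, test, k, int(seeds[0]), int(seeds[1]))
    ps_mean = ps.mean(axis=0)
    ps_sd = ps.std(axis=0, ddof=1) if n_splits > 1 else np.zeros(k_max)
    qualifying = np.nonzero(ps_mean >= threshold)[0]
    selected = int(qualifying[-1] + 1) if len(qualifying) else 1
    return PredictionStrengthCurve(
        k_values=np.arange(1, k_max + 1),
        ps_mean=ps_mean,
        ps_sd=ps_sd,
        threshold=float(threshold),
        selected_k=selected,
    )


def relabel_by_size(result: ClusteringResult) -> ClusteringResult:
    """Canonicalize cluster ids: 1 = largest cluster, ties by medoid index."""
    sizes = result.cluster_sizes()
    order = sorted(range(result.k), key=lambda g: (-sizes[g], result.medoid_indices[g]))
    new_of_old = np.empty(result.k, dtype=int)
    for new, old in enumerate(order):
        new_of_old[old] = new + 1
    return ClusteringResult(
        k=result.k,
        medoid_indices=result.medoid_indices[order],
        labels=new_of_old[result.labels - 1],
        total_cost=result.total_cost,
        medoids=result.medoids[order],
    )
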