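"""k-medoids clustering with bootstrap Jaccard cluster-stability profiling.

Expression profiles are z-scored per gene and clustered by partitioning
around medoids (PAM, BUILD + SWAP) on Euclidean dissimilarity — on
z-scored rows this is equivalent to a correlation-based distance up to an
affine transform.  Stability of each reference cluster is assessed by
resampling genes with replacement, re-clustering, and recording the best
Jaccard similarity of the reference cluster against the resample's
clusters over the distinct genes present in the resample.  A cluster is
stable when its median Jaccard is >= 0.75 and the standard deviation is
<= 10% of the mean; the optimal k is the largest k in the first
contiguous all-stable run starting at k = 2, which excludes the trivial
recovery of high Jaccard values at very large k.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import squareform, pdist


@dataclasses.dataclass
class ClusterSolution:
    k: int
    medoids: np.ndarray  # row indices into the clustered matrix
    labels: np.ndarray  # 1..k per row
    total_dissimilarity: float


@dataclasses.dataclass
class StabilityReport:
    """Per-k reference solutions, bootstrap Jaccard distributions, flags."""

    k_values: list[int]
    solutions: dict[int, ClusterSolution]
    jaccard: dict[int, np.ndarray]  # (k, n_boot) per k
    median: dict[int, np.ndarray]
    sd: dict[int, np.ndarray]
    stable: dict[int, np.ndarray]
    all_stable: dict[int, bool]
    optimal_k: int | None = None


def scale_center_profiles(matrix):
    """Z-score each gene row (mean 0, population SD 1).

    Constant rows are mapped to all-zeros and flagged.  Returns
    (scaled array, boolean flags of constant rows).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    out = (X - mean) / sd
    out[constant] = 0.0
    return out, constant


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -1.0
        best = int(np.argmax(gain))
        medoids.append(best)
        nearest = np.minimum(nearest, D[:, best])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int], max_iter: int = 200):
    n = D.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        Dm = D[:, medoids]  # n x k
        order = np.argsort(Dm, axis=1)
        nearest_idx = order[:, 0]
        d_nearest = Dm[np.arange(n), nearest_idx]
        if len(medoids) > 1:
            d_second = Dm[np.arange(n), order[:, 1]]
        else:
            d_second = np.full(n, np.inf)
        current = d_nearest.sum()
        best_delta, best_swap = -1e-9, None
        for pos in range(len(medoids)):
            # distance to nearest medoid excluding medoid `pos`
            d_excl = np.where(nearest_idx == pos, d_second, d_nearest)
            costs = np.minimum(D, d_excl[:, None]).sum(axis=0)  # per candidate h
            costs[medoids] = np.inf
            h = int(np.argmin(costs))
            delta = current - costs[h]
            if delta > best_delta:
                best_delta, best_swap = delta, (pos, h)
        if best_swap is None or best_delta <= 1e-9:
            break
        medoids[best_swap[0]] = best_swap[1]
    return medoids


def _total_cost(D: np.ndarray, medoids) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _pam_on_dist(D: np.ndarray, k: int, n_restarts: int = 2, seed: int = 0) -> ClusterSolution:
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    medoids = _pam_swap(D, _pam_build(D, k))
    # SWAP only reaches a local optimum; a few seeded random restarts make
    # the search reliable on small instances at negligible cost
    if n_restarts and n > k:
        best_cost = _total_cost(D, medoids)
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            init = list(rng.choice(n, size=k, replace=False))
            cand = _pam_swap(D, init)
            cost = _total_cost(D, cand)
            if cost < best_cost - 1e-12:
                medoids, best_cost = cand, cost
    Dm = D[:, medoids]
    labels = np.argmin(Dm, axis=1)
    # medoids belong to their own cluster even under distance ties
    for pos, m in enumerate(medoids):
        labels[m] = pos
    total = Dm[np.arange(n), labels].sum()
    return ClusterSolution(
        k=k, medoids=np.array(medoids), labels=labels + 1, total_dissimilarity=float(total)
    )


def pam_cluster(X, k: int, seed: int = 0, n_restarts: int = 2) -> ClusterSolution:
    """PAM (BUILD + SWAP + seeded restarts); deterministic given seed."""
    X = np.asarray(X, dtype=float)
    D = squareform(pdist(X))
    return _pam_on_dist(D, k, n_restarts=n_restarts, seed=seed)


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def bootstrap_stability(X, k: int, n_boot: int = 100, seed: int = 0):
    """Clusterwise bootstrap Jaccard stability.

    Returns (reference ClusterSolution, (k, n_boot) array of Jaccard
    similarities).  Resamples draw genes with replacement; duplicated
    rows are kept during re-clustering and Jaccard is computed on the
    distinct-gene support of each resample.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = squareform(pdist(X))
    reference = _pam_on_dist(D, k)
    ref_clusters = [set(np.where(reference.labels == c + 1)[0]) for c in range(k)]
    rng = np.random.default_rng(seed)
    jac = np.zeros((k, n_boot))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Db = D[np.ix_(idx, idx)]
        sol = _pam_on_dist(Db, k)
        support = set(idx.tolist())
        boot_clusters = [
            set(idx[sol.labels == c + 1].tolist()) for c in range(k)
        ]
        for c, A in enumerate(ref_clusters):
            A_sup = A & support
            jac[c, b] = max(jaccard(A_sup, B) for B in boot_clusters)
    return reference, jac


def stability_flags(jac: np.ndarray, median_threshold=0.75, sd_fraction=0.10):
    """Per-cluster stability: median >= threshold AND sd <= fraction of mean."""
    med = np.median(jac, axis=1)
    sd = jac.std(axis=1)
    mean = jac.mean(axis=1)
    stable = (med >= median_threshold) & (sd <= sd_fraction * mean)
    return med, sd, stable


def stability_profile(
    X,
    k_max: int | None = None,
    n_boot: int = 100,
    seed: int = 0,
    median_threshold: float = 0.75,
    sd_fraction: float = 0.10,
) -> StabilityReport:
    """Bootstrap-stability report over k = 2..k_max.

    Default ``k_max = min(10, n_genes // 20)`` (at least 2) scales the
    explored range with the gene-set size.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_max is None:
        k_max = max(2, min(10, n // 20))
    ks = list(range(2, k_max + 1))
    report = StabilityReport(
        k_values=ks, solutions={}, jaccard={}, median={}, sd={}, stable={}, all_stable={}
    )
    for i, k in enumerate(ks):
        sol, jac = bootstrap_stability(X, k, n_boot=n_boot, seed=seed + i)
        med, sd, stable = stability_flags(jac, median_threshold, sd_fraction)
        report.solutions[k] = sol
        report.jaccard[k] = jac
        report.median[k] = med
        report.sd[k] = sd
        report.stable[k] = stable
        report.all_stable[k] = bool(stable.all())
    report.optimal_k = select_optimal_k(report)
    return report


def select_optimal_k(report, rule: str = "first_run") -> int | None:
    """Largest k of the first contiguous all-stable run starting at k = 2.

    ``rule="max_stable"`` instead returns the largest all-stable k
    anywhere (including the large-k recovery regime).  Returns None when
    k = 2 is already unstable.
    """
    flags = report.all_stable if isinstance(report, StabilityReport) else dict(report)
    ks = sorted(flags)
    if not ks or ks[0] != 2:
        raise ValueError("report must cover a contiguous k range starting at 2")
    if rule == "max_stable":
        stable_ks = [k for k in ks if flags[k]]
        return max(stable_ks) if stable_ks else None
    if not flags[2]:
        return None
    best = 2
    for k in ks[1:]:
        if k != best + 1 or not flags[k]:
            break
        best = k
    return best
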