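"""Shape-based clustering of short trait time series.

Implements the shape-based distance (SBD) and k-Shape partitional clustering
for the 4-stage trait trajectories this pipeline produces.  SBD between two
series is 1 minus the maximum, over all alignment shifts, of the
coefficient-normalized cross-correlation of the z-normalized series; it lies
in [0, 2], is invariant to positive affine transforms of either series, and
treats two series with the same shape but different level or amplitude as
identical.  k-Shape alternates (a) assignment of each series to the nearest
centroid under SBD and (b) shape extraction, which replaces each centroid by
the principal eigenvector of the shift-aligned members' centered Gram matrix
-- the series maximizing the summed squared normalized cross-correlation to
the members.

Cluster validity uses the Davies-Bouldin index (lower is better) and the Dunn
index (higher is better), both with SBD as the dissimilarity, and the cluster
number is chosen as the k that optimizes both simultaneously when one exists,
falling back to the best DBI/DI rank sum (ties to the smaller k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TraitMatrix:
    """Genotypes x stages series matrix for one trait."""

    series: np.ndarray
    trait: str = ""
    names: list = field(default_factory=list)
    groups: np.ndarray | None = None
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if self.series.shape[0] < 2:
            raise ValueError("clustering needs at least 2 series")
        if not np.isfinite(self.series).all():
            raise ValueError("series submitted to clustering must have no missing entries")
        if not self.names:
            self.names = [str(i) for i in range(len(self.series))]


def znormalize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd transform per series; constant series map to zeros.

    Accepts a single series or a matrix of row series.  Idempotent.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    mat = np.atleast_2d(x)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (mat - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out[0] if single else out


def _shift(x: np.ndarray, s: int) -> np.ndarray:
    """Shift right by s (left for negative), zero-padding the vacated entries."""
    out = np.zeros_like(x)
    if s >= 0:
        out[s:] = x[: len(x) - s] if s < len(x) else 0.0
    else:
        out[:s] = x[-s:]
    return out


def _max_ncc(zx: np.ndarray, zy: np.ndarray) -> tuple[float, int]:
    """Max coefficient-normalized cross-correlation over all 2T-1 shifts.

    Returns (max NCC, shift of y achieving it).  Inputs are z-normalized.
    """
    denom = np.linalg.norm(zx) * np.linalg.norm(zy)
    if denom == 0:
        # at least one constant series: NCC undefined; two constants agree
        both = np.linalg.norm(zx) == 0 and np.linalg.norm(zy) == 0
        return (1.0, 0) if both else (0.0, 0)
    cc = np.correlate(zx, zy, mode="full")  # shift of y from -(T-1) to T-1
    idx = int(np.argmax(cc))
    return float(cc[idx] / denom), idx - (len(zy) - 1)


def sbd(x: np.ndarray, y: np.ndarray) -> float:
    """Shape-based distance in [0, 2] between two equal-length series."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ncc, _ = _max_ncc(znormalize(x), znormalize(y))
    return float(np.clip(1.0 - ncc, 0.0, 2.0))


def _pairwise_max_ncc(za: np.ndarray, zb: np.ndarray) -> np.ndarray:
    """Max-NCC matrix between row series of two z-normalized matrices."""
    T = za.shape[1]
    na = np.linalg.norm(za, axis=1)
    nb = np.linalg.norm(zb, axis=1)
    best = np.full((len(za), len(zb)), -np.inf)
    for s in range(-(T - 1), T):
        shifted = np.array([_shift(row, s) for row in zb])
        np.maximum(best, za @ shifted.T, out=best)
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > 0, best / denom, 0.0)
    # constant-vs-constant pairs agree perfectly
    ncc[np.ix_(na == 0, nb == 0)] = 1.0
    return ncc


def pairwise_sbd(series: np.ndarray) -> np.ndarray:
    """Symmetric SBD matrix between all row series."""
    z = znormalize(series)
    d = np.clip(1.0 - _pairwise_max_ncc(z, z), 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def shape_extract_centroid(
    members: np.ndarray, current_centroid: np.ndarray | None = None
) -> np.ndarray:
    """k-Shape centroid: principal eigenvector of the aligned, centered Gram.

    Members are z-normalized, shift-aligned to the current centroid (no shift
    when the reference is absent or flat), and stacked into A; the centroid is
    the principal eigenvector of Q A^T A Q with Q the centering projector,
    z-normalized, with its sign chosen to maximize similarity to the members.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if len(members) == 0:
        raise ValueError("cannot extract a centroid from an empty cluster")
    z = znormalize(members)
    T = z.shape[1]
    ref = None if current_centroid is None else znormalize(current_centroid)
    if ref is not None and np.linalg.norm(ref) > 0:
        aligned = []
        for row in z:
            _, s = _max_ncc(ref, row)
            aligned.append(_shift(row, s))
        A = np.array(aligned)
    else:
        A = z
    Q = np.eye(T) - np.full((T, T), 1.0 / T)
    M = Q @ (A.T @ A) @ Q
    eigvals, eigvecs = np.linalg.eigh(M)
    centroid = eigvecs[:, -1]
    if eigvals[-1] <= 1e-12:  # all members flat
        return np.zeros(T)
    centroid = znormalize(centroid)
    if (A @ centroid).sum() < 0:  # sign ambiguity of the eigenvector
        centroid = -centroid
    return centroid


@dataclass
class ClusterResult:
    """A k-Shape partition with its validity indices."""

    k: int
    assignments: np.ndarray  # 1-based cluster labels
    centroids: np.ndarray  # (k, T), z-normalized shapes
    iterations: int
    seed: int
    objective: float  # sum of within-cluster SBD to centroid
    dbi: float = float("nan")
    dunn: float = float("nan")


def _assign(z: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.clip(1.0 - _pairwise_max_ncc(z, znormalize(centroids)), 0.0, 2.0)
    labels = d.argmin(axis=1)
    return labels, d[np.arange(len(z)), labels]


def _kshape_once(
    z: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int, float]:
    n = len(z)
    labels = rng.permutation(n) % k  # balanced random start, no empty cluster
    centroids = np.zeros((k, z.shape[1]))
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for c in range(k):
            members = z[labels == c]
            if len(members):
                centroids[c] = shape_extract_centroid(members, centroids[c])
        new_labels, dist = _assign(z, centroids)
        # repair empty clusters from the worst-fitting rows
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(dist))
                new_labels[far] = c
                dist[far] = -1.0
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    _, dist = _assign(z, centroids)
    return labels, centroids, iterations, float(dist.sum())


def kshape_cluster(
    matrix: TraitMatrix, k: int, seed: int = 0, max_iter: int = 100, n_init: int = 5
) -> ClusterResult:
    """Partition the series into k shape clusters, deterministically per seed.

    The alternating refinement is restarted ``n_init`` times from different
    seeded initial partitions and the run with the lowest within-cluster SBD
    sum is kept; short series offer many equivalent shift alignments, so a
    single start can settle on a distorted centroid.
    """
    X = matrix.series
    n = len(X)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available series")
    z = znormalize(X)
    if k == n:
        result = ClusterResult(k, np.arange(1, n + 1), z.copy(), 0, seed, 0.0)
    else:
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(max(1, n_init)):
            run = _kshape_once(z, k, rng, max_iter)
            if best is None or run[3] < best[3] - 1e-12:
                best = run
        labels, centroids, iterations, objective = best
        result = ClusterResult(k, labels + 1, centroids, iterations, seed, objective)
    if k >= 2:
        result.dbi = davies_bouldin(matrix, result)
        result.dunn = dunn(matrix, result)
    return result


def davies_bouldin(matrix: TraitMatrix, result: ClusterResult) -> float:
    """Davies-Bouldin index with SBD dissimilarity; lower is better."""
    z = znormalize(matrix.series)
    labels = result.assignments - 1
    k = result.k
    scatter = np.zeros(k)
    for c in range(k):
        members = z[labels == c]
        scatter[c] = np.mean(
            [sbd(m, result.centroids[c]) for m in members]
        ) if len(members) else 0.0
    sep = pairwise_sbd(result.centroids)
    ratios = np.zeros(k)
    with np.errstate(divide="ignore"):
        for i in range(k):
            r = [
                (scatter[i] + scatter[j]) / sep[i, j] if sep[i, j] > 0 else np.inf
                for j in range(k) if j != i
            ]
            ratios[i] = max(r)
    return float(np.mean(ratios))


def dunn(matrix: TraitMatrix, result: ClusterResult) -> float:
    """Dunn index with SBD dissimilarity; higher is better."""
    d = pairwise_sbd(matrix.series)
    labels = result.assignments
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    intra = d[iu][same[iu]]
    inter = d[iu][~same[iu]]
    if len(inter) == 0:
        raise ValueError("Dunn index needs at least 2 clusters")
    diameter = intra.max() if len(intra) else 0.0
    if diameter == 0:
        return float("inf") if inter.min() > 0 else 0.0
    return float(inter.min() / diameter)


def select_cluster_number(
    matrix: TraitMatrix, k_max: int = 20, seed: int = 0, max_iter: int = 100
) -> tuple[int, pd.DataFrame]:
    """Cluster for k = 2..k_max and pick the k optimizing DBI and DI jointly.

    If one k both minimizes DBI and maximizes DI it is chosen outright;
    otherwise the k with the smallest sum of ranks (DBI ascending, DI
    descending) wins, ties resolved toward the smaller k.
    """
    n = len(matrix.series)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if k_max > n:
        warnings.warn(f"k_max={k_max} exceeds {n} series; truncated to {n}")
        k_max = n
    rows = []
    for k in range(2, k_max + 1):
        res = kshape_cluster(matrix, k, seed=seed, max_iter=max_iter)
        rows.append({"k": k, "dbi": res.dbi, "dunn": res.dunn})
    table = pd.DataFrame(rows)
    finite_dbi = np.where(np.isfinite(table["dbi"]), table["dbi"], np.inf)
    dunn_vals = table["dunn"].to_numpy()
    best_dbi = int(table["k"][int(np.argmin(finite_dbi))])
    best_dunn = int(table["k"][int(np.argmax(dunn_vals))])
    if best_dbi == best_dunn:
        return best_dbi, table
    rank_dbi = pd.Series(finite_dbi).rank(method="min")
    rank_dunn = pd.Series(-dunn_vals).rank(method="min")
    total = rank_dbi + rank_dunn
    k_star = int(table["k"][int(np.argmin(total.to_numpy()))])  # argmin keeps first=smaller k
    return k_star, table
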