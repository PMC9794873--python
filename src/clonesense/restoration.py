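"""Restoring clonal identity of fragments and spatial autocorrelation.

Fragments of one clone stay closer to each other than independently
induced clones, so clonality can be restored by a distance threshold:
link two same-color clusters when their centroid distance is below w*.
For Poisson-distributed induction the nearest-neighbour distance law
gives a closed form for the threshold at significance level alpha,

    w* = [ Gamma(d/2 + 1) V / (pi^(d/2) k f) * |ln(1 - alpha e^(-f))| ]^(1/d),

which shrinks as the fragmentation rate f or the observed cluster count k
grows.  alpha = 0.5 is a natural default: below w* a pair is more likely
clonal than not.

Moran's I is provided as the spatial-autocorrelation statistic for
comparing labelling patterns between conditions when clone sizes alone
are uninformative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .clonedata import ClusterTable, DomainError
from .merging import unit_ball_volume


@dataclass(frozen=True)
class DistanceThreshold:
    """Clonality distance threshold w* and the inputs that produced it."""

    w_star: float
    alpha: float
    d: int
    f: float
    volume: float
    k: int

    def __post_init__(self) -> None:
        if self.w_star < 0:
            raise DomainError("w_star must be nonnegative")


def w_star(
    f: float, volume: float, k: int, alpha: float = 0.5, d: int = 2
) -> DistanceThreshold:
    """Distance below which two same-color clusters are considered clonal
    at significance level alpha (default 0.5)."""
    if d not in (1, 2, 3):
        raise DomainError("dimension must be 1, 2 or 3")
    if f <= 0:
        raise DomainError("fragmentation rate f must be positive")
    if volume <= 0:
        raise DomainError("volume must be positive")
    if k < 1:
        raise DomainError("k must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    x = alpha * math.exp(-f)
    if x >= 1.0:
        raise DomainError("alpha * exp(-f) must be below 1")
    gamma_term = math.exp(gammaln(d / 2 + 1))
    w = (
        gamma_term * volume / (math.pi ** (d / 2) * k * f) * abs(math.log1p(-x))
    ) ** (1.0 / d)
    return DistanceThreshold(w_star=w, alpha=alpha, d=d, f=f, volume=volume, k=k)


@dataclass(frozen=True)
class ClonalDistanceProbability:
    """Components of the distance-threshold criterion at separation w."""

    p_distance_given_clonal: float  # P(w | m = 2): nearest-neighbour survival
    alpha_level: float  # solves alpha_level(w) = alpha at w = w*


def clonal_distance_probability(
    w: float, rho: float, f: float, d: int
) -> ClonalDistanceProbability:
    """Evaluate the two ingredients of the threshold criterion at distance w.

    ``rho`` is the observed density of labelled clusters (k / V).
    P(w | m = 2) = exp(-rho V_d(w)) is the probability that the nearest
    independently induced neighbour lies beyond w.  ``alpha_level`` is the
    cumulative polyclonal fraction below w in the closed form whose root at
    level alpha reproduces :func:`w_star` exactly:

        alpha_level(w) = e^f * (1 - exp(-rho f V_d(w))).
    """
    if w < 0:
        raise DomainError("w must be nonnegative")
    if rho <= 0:
        raise DomainError("rho must be positive")
    if d not in (1, 2, 3):
        raise DomainError("dimension must be 1, 2 or 3")
    vd = unit_ball_volume(d) * w**d
    p_given = math.exp(-rho * vd)
    level = math.exp(f) * -math.expm1(-rho * f * vd)
    return ClonalDistanceProbability(p_distance_given_clonal=p_given,
                                     alpha_level=level)


@dataclass(frozen=True)
class ClonalPartition:
    """Assignment of clusters to putative clones plus the link audit."""

    assignment: dict[str, str]  # cluster_id -> clone id
    links: pd.DataFrame  # cluster_a, cluster_b, distance, within_threshold
    w_star: float

    def n_clones(self) -> int:
        return len(set(self.assignment.values()))


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ri, rj))
            self.parent[hi] = lo


def restore_clones(
    table: ClusterTable, threshold: DistanceThreshold | float
) -> ClonalPartition:
    """Single-linkage restoration: same-color clusters within one sample
    whose centroids lie closer than w* are joined into one putative clone.

    Clone ids are the lexicographically smallest member cluster_id, so the
    result is independent of row order.  Different colors never join.
    """
    if isinstance(threshold, DistanceThreshold):
        if threshold.d != table.ndim:
            raise DomainError(
                f"threshold is {threshold.d}-dimensional but table is {table.ndim}-dimensional"
            )
        w = threshold.w_star
    else:
        w = float(threshold)
        if w < 0:
            raise DomainError("threshold must be nonnegative")
    ids = table.df["cluster_id"].tolist()
    uf = _UnionFind(ids)
    link_rows = []
    for _, group in table.df.groupby(["sample_id", "color"], sort=False):
        if len(group) < 2:
            continue
        pos = group[table.coord_columns].to_numpy(float)
        gids = group["cluster_id"].tolist()
        tree = cKDTree(pos)
        for i, j in sorted(tree.query_pairs(w)):
            dist = float(np.linalg.norm(pos[i] - pos[j]))
            a, b = sorted((gids[i], gids[j]))
            uf.union(a, b)
            link_rows.append({"cluster_a": a, "cluster_b": b,
                              "distance": dist, "within_threshold": True})
    assignment = {cid: uf.find(cid) for cid in ids}
    links = pd.DataFrame(link_rows,
                         columns=["cluster_a", "cluster_b", "distance",
                                  "within_threshold"])
    if len(links):
        links = links.sort_values(["cluster_a", "cluster_b"]).reset_index(drop=True)
    return ClonalPartition(assignment=assignment, links=links, w_star=w)


def annotate_clones(table: ClusterTable, partition: ClonalPartition) -> ClusterTable:
    """Return a copy of the table with a derived ``clone_id`` column."""
    df = table.df.copy()
    df["clone_id"] = df["cluster_id"].map(partition.assignment)
    return ClusterTable(df)


# ---------------------------------------------------------------------------
# Moran's I

def knn_weights(coords: np.ndarray, k: int, row_standardize: bool = True) -> np.ndarray:
    """Symmetric-by-construction k-nearest-neighbour weight matrix (binary
    before optional row standardization; neighbour relation is directed)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k < 1 or k >= n:
        raise DomainError("need 1 <= k < number of locations")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    W = np.zeros((n, n))
    for i in range(n):
        for j in idx[i, 1:]:
            W[i, j] = 1.0
    if row_standardize:
        W = _row_standardize(W)
    return W


def distance_band_weights(
    coords: np.ndarray, radius: float, row_standardize: bool = True
) -> np.ndarray:
    """Binary weights for all pairs within ``radius`` (zero diagonal)."""
    coords = np.asarray(coords, dtype=float)
    if radius <= 0:
        raise DomainError("radius must be positive")
    n = len(coords)
    W = np.zeros((n, n))
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(radius):
        W[i, j] = W[j, i] = 1.0
    if row_standardize:
        W = _row_standardize(W)
    return W


def _row_standardize(W: np.ndarray) -> np.ndarray:
    rows = W.sum(axis=1, keepdims=True)
    out = np.divide(W, rows, out=np.zeros_like(W), where=rows > 0)
    return out


def morans_i(values, weights: np.ndarray) -> float:
    """Global Moran's I:

        I = n / S0 * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with S0 the total weight.  Weights must be nonnegative with a zero
    diagonal; constant values leave I undefined.
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = x.size
    if n < 2:
        raise DomainError("need at least 2 locations")
    if W.shape != (n, n):
        raise DomainError("weight matrix shape must match the number of values")
    if np.any(W < 0):
        raise DomainError("weights must be nonnegative")
    if np.any(np.diag(W) != 0):
        raise DomainError("weight matrix must have a zero diagonal")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise DomainError("Moran's I is undefined for constant values")
    s0 = float(W.sum())
    if s0 == 0.0:
        raise DomainError("weight matrix has no nonzero weights")
    return float(n / s0 * (z @ W @ z) / denom)
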