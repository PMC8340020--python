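"""Word-level validation of the embedding.

The embedded n-grams are reduced to 2-D with t-SNE, partitioned with
two-level k-means (k1 top-level clusters, each re-clustered into k2
sub-clusters), and the resulting clusters are checked for homogeneity of the
biophysicochemical properties: the ratio of the overall sample variance to
the Bessel-weighted pooled within-cluster variance, a Mann-Whitney test on
within-cluster vs. all-pairs property distances, and — independently of any
clustering — global spatial autocorrelation via Moran's I with binary
distance-band weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .errors import NoNeighborsError, UndefinedVarianceError, ZeroVarianceError


@dataclass
class ClusterSet:
    """Assignment of members to clusters; ids are dense in [0, k)."""

    assignment: dict[int, int]
    k: int
    centers: np.ndarray | None = None

    @classmethod
    def from_labels(cls, labels: Sequence[int], centers: np.ndarray | None = None) -> "ClusterSet":
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        remap = {old: new for new, old in enumerate(uniq)}
        return cls(
            assignment={i: remap[lab] for i, lab in enumerate(labels)},
            k=len(uniq),
            centers=centers,
        )

    def members_of(self, cluster_id: int) -> list[int]:
        return [m for m, c in self.assignment.items() if c == cluster_id]

    def groups(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {c: [] for c in range(self.k)}
        for m, c in self.assignment.items():
            out[c].append(m)
        return out


@dataclass(frozen=True)
class MoranResult:
    """Moran's I at one distance band."""

    d: float
    I: float
    n: int
    S0: float


def reduce_2d(vectors: np.ndarray, method: str = "tsne", seed: int = 0) -> np.ndarray:
    """Reduce an (m x d) matrix to 2-D; reproducible given the seed.

    t-SNE with perplexity min(30, (m-1)/3), PCA initialization, 1000
    iterations.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need at least 2 vectors to reduce")
    if method != "tsne":
        raise ValueError(f"unknown reduction method {method!r}")
    m = vectors.shape[0]
    perplexity = min(30.0, max(1.0, (m - 1) / 3))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        learning_rate="auto",
        max_iter=1000,
        random_state=seed,
    )
    return tsne.fit_transform(vectors)


class TwoLevelKMeans(ClusterMixin, BaseEstimator):
    """k-means with a depth of two: k1 clusters, each split into k2 sub-clusters.

    The final number of clusters is k1*k2 when every top-level cluster holds
    at least k2 points; a smaller top-level cluster keeps fewer sub-clusters
    and the honest total is reported in ``n_clusters_`` with a warning.
    """

    def __init__(self, k1: int = 20, k2: int = 20, n_init: int = 10, seed: int = 0) -> None:
        self.k1 = k1
        self.k2 = k2
        self.n_init = n_init
        self.seed = seed

    def fit(self, X, y=None) -> "TwoLevelKMeans":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.k1 * self.k2:
            raise ValueError(
                f"{X.shape[0]} points cannot support {self.k1}x{self.k2} clusters"
            )
        top = KMeans(n_clusters=self.k1, n_init=self.n_init, random_state=self.seed).fit(X)
        labels = np.empty(X.shape[0], dtype=int)
        centers = []
        next_id = 0
        short = 0
        for c in range(self.k1):
            idx = np.flatnonzero(top.labels_ == c)
            k2 = min(self.k2, len(idx))
            if k2 < self.k2:
                short += 1
            sub = KMeans(n_clusters=k2, n_init=self.n_init, random_state=self.seed + 1 + c).fit(
                X[idx]
            )
            labels[idx] = sub.labels_ + next_id
            centers.append(sub.cluster_centers_)
            next_id += k2
        if short:
            warnings.warn(
                f"{short} top-level cluster(s) had fewer than k2={self.k2} points; "
                f"returning {next_id} clusters instead of {self.k1 * self.k2}",
                stacklevel=2,
            )
        self.labels_ = labels
        self.cluster_centers_ = np.vstack(centers)
        self.n_clusters_ = next_id
        return self


def kmeans_two_level(points: np.ndarray, k1: int, k2: int, seed: int = 0) -> ClusterSet:
    """Functional wrapper over :class:`TwoLevelKMeans` returning a :class:`ClusterSet`."""
    est = TwoLevelKMeans(k1=k1, k2=k2, seed=seed).fit(points)
    return ClusterSet.from_labels(est.labels_, centers=est.cluster_centers_)


def silhouette_search(
    points: np.ndarray,
    k1_grid: Sequence[int],
    k2_grid: Sequence[int],
    seed: int = 0,
) -> tuple[tuple[int, int], pd.DataFrame]:
    """Pick (k1, k2) from a user grid by silhouette score of the final partition."""
    points = np.asarray(points, dtype=float)
    rows = []
    for k1 in k1_grid:
        for k2 in k2_grid:
            cs = kmeans_two_level(points, k1, k2, seed=seed)
            labels = np.array([cs.assignment[i] for i in range(len(points))])
            score = silhouette_score(points, labels)
            rows.append({"k1": k1, "k2": k2, "silhouette": score})
    table = pd.DataFrame(rows)
    best = table.loc[table["silhouette"].idxmax()]
    return (int(best["k1"]), int(best["k2"])), table


def pooled_variance(values: Mapping[int, float], clusters: ClusterSet) -> float:
    """Bessel-weighted pooled within-cluster variance.

    s_p^2 = sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1) over clusters with at
    least two valued members; singletons are excluded from both sums.
    """
    num = 0.0
    den = 0.0
    for members in clusters.groups().values():
        vals = np.array([values[m] for m in members if m in values])
        if len(vals) < 2:
            continue
        num += (len(vals) - 1) * np.var(vals, ddof=1)
        den += len(vals) - 1
    if den == 0:
        raise UndefinedVarianceError("all clusters are singletons; pooled variance undefined")
    return num / den


def homogeneity_report(properties: pd.DataFrame, clusters: ClusterSet) -> pd.DataFrame:
    """Per property: overall sample variance, pooled in-cluster variance, ratio.

    A ratio well above 1 means the property is much more homogeneous inside
    clusters than across the whole embedding.
    """
    rows = {}
    for name in properties.columns:
        col = properties[name].to_numpy(dtype=float)
        general = float(np.var(col, ddof=1))
        pooled = pooled_variance(dict(enumerate(col)), clusters)
        rows[name] = {
            "general_variance": general,
            "pooled_variance": pooled,
            "ratio": general / pooled if pooled > 0 else np.inf,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def distance_distribution_test(
    values: Mapping[int, float], clusters: ClusterSet
) -> dict:
    """Within-cluster vs. all-pairs absolute property differences.

    One-sided Mann-Whitney U with the alternative that within-cluster
    distances are stochastically smaller.
    """
    members = sorted(values)
    vals = np.array([values[m] for m in members])
    if len(vals) < 2:
        raise ValueError("need at least two valued members")
    all_pairs = pdist(vals[:, None], metric="cityblock")
    pos = {m: i for i, m in enumerate(members)}
    within = []
    for group in clusters.groups().values():
        idx = [pos[m] for m in group if m in pos]
        if len(idx) >= 2:
            within.extend(pdist(vals[idx][:, None], metric="cityblock"))
    if not within:
        raise UndefinedVarianceError("no within-cluster pairs")
    within = np.asarray(within)
    stat, p = mannwhitneyu(within, all_pairs, alternative="less")
    return {
        "within": within,
        "all_pairs": all_pairs,
        "statistic": float(stat),
        "p_value": float(p),
    }


def morans_i(points: np.ndarray, values: Sequence[float], d_x: float) -> MoranResult:
    """Global Moran's I with binary distance-band weights.

    w_ij = 1 iff 0 < ||p_i - p_j|| < d_x (strict; diagonal zero, no row
    standardization):  I = (n / S0) * (z' W z) / (z' z) with z the centered
    attribute.  Expected value under no autocorrelation is ~0 for large n.
    """
    points = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    n = len(points)
    if n < 2 or len(z) != n:
        raise ValueError("need >= 2 points and one value per point")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ZeroVarianceError("attribute is constant; Moran's I undefined")
    # row-chunked accumulation keeps memory at O(chunk * n)
    from scipy.spatial.distance import cdist

    S0 = 0.0
    cross = 0.0
    chunk = max(1, int(5e6) // max(n, 1))
    for start in range(0, n, chunk):
        block = points[start : start + chunk]
        d = cdist(block, points)
        w = (d > 0) & (d < d_x)  # strict band; self-pairs have d == 0
        S0 += float(w.sum())
        cross += float(z[start : start + chunk] @ (w @ z))
    if S0 == 0:
        raise NoNeighborsError(f"no pair of points closer than d_x={d_x}")
    return MoranResult(d=d_x, I=(n / S0) * cross / denom, n=n, S0=S0)


def morans_profile(
    points: np.ndarray, values: Sequence[float], distances: Sequence[float]
) -> list[MoranResult]:
    """Moran's I at each distance band; bands with no neighbors are skipped
    with a warning."""
    results = []
    for d in distances:
        try:
            results.append(morans_i(points, values, d))
        except NoNeighborsError:
            warnings.warn(f"no neighbors at distance {d}; skipped", stacklevel=2)
    return results
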