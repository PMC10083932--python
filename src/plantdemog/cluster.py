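"""Trait-space clustering and ordination.

Species are compared in normalized trait space with the Bray-Curtis
dissimilarity, grouped by average-linkage (UPGMA) hierarchical
clustering cut at a fixed height, with the cluster count sanity-checked
against a K-means elbow profile.  Differences among clusters are tested
with PERMANOVA (global and pairwise), and a PCA shows which traits
dominate each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "Dendrogram",
    "bray_curtis",
    "upgma",
    "cut_dendrogram",
    "select_k",
    "permanova",
    "pairwise_permanova",
    "pca",
    "dendrogram_to_newick",
]


@dataclass
class Dendrogram:
    """Average-linkage merge tree in scipy linkage form plus leaf labels.

    ``merges`` row k is (left, right, height, size): the two node ids
    merged (ids < m are leaves, id m+k is the node created at row k),
    the Bray-Curtis height of the merge, and the merged cluster size.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic(self) -> np.ndarray:
        return squareform(cophenet(self.merges))


def bray_curtis(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix of non-negative trait profiles.

    ``D[a, b] = sum|x_a - x_b| / sum(x_a + x_b)``; two all-zero profiles
    are defined as identical (distance 0).  Values lie in [0, 1] for
    non-negative input, hence the requirement to normalize traits first.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError(
            "Bray-Curtis requires non-negative entries; normalize traits first"
        )
    m = X.shape[0]
    D = np.zeros((m, m))
    for a in range(m):
        diff = np.abs(X[a] - X[a + 1 :]).sum(axis=1)
        tot = (X[a] + X[a + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        D[a, a + 1 :] = d
        D[a + 1 :, a] = d
    return D


def upgma(D: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """UPGMA (average-linkage) dendrogram of a distance matrix.

    Merges the closest pair at the height of their distance; distances
    from a merged node are size-weighted arithmetic means, which makes
    merge heights monotone non-decreasing (no inversions).
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    if m < 2:
        raise ValueError("need at least 2 items to cluster")
    if labels is None:
        labels = [f"item{i}" for i in range(m)]
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(merges=Z, labels=list(labels))


def cut_dendrogram(dend: Dendrogram, height: float = 0.3) -> pd.Series:
    """Cluster assignment from cutting the dendrogram at a fixed height.

    Clusters are the connected components after removing merges higher
    than the cut; labels are integers 1..k ordered by first appearance
    down the leaf ordering.
    """
    raw = fcluster(dend.merges, t=height, criterion="distance")
    # renumber so cluster ids are 1..k in order of first appearance
    seen: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen) + 1
        out[i] = seen[r]
    return pd.Series(out, index=dend.labels, name="cluster")


def select_k(
    X: np.ndarray | pd.DataFrame,
    k_range: range | list[int] | None = None,
    n_init: int = 10,
    seed: int | None = 0,
) -> tuple[int, pd.DataFrame]:
    """Recommend a cluster count from the K-means elbow.

    Fits K-means for each k and returns the k at the maximum-curvature
    (largest second difference) point of the within-cluster
    sum-of-squares profile, along with the full profile.  A zero-variance
    dataset recommends k = 1.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if k_range is None:
        k_range = range(1, min(11, m))
    ks = sorted(k for k in k_range if 1 <= k <= m)
    if not ks:
        raise ValueError("k_range contains no feasible k")
    wss = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        km.fit(X)
        wss.append(float(km.inertia_))
    profile = pd.DataFrame({"k": ks, "wss": wss})
    if wss[0] <= 1e-12:  # no variance at all
        return ks[0], profile
    if len(ks) <= 2:
        return ks[-1], profile
    # maximum curvature of the log-WSS profile: the absolute-scale second
    # difference is dominated by the first split, the log scale measures
    # relative drops and flags where the profile flattens
    w = np.maximum(np.array(wss), 1e-12)
    curv = np.log(w[:-2]) - 2 * np.log(w[1:-1]) + np.log(w[2:])
    return ks[1 + int(np.argmax(curv))], profile


def _permanova_stats(D2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from a squared-distance matrix and group labels.

    Uses sum_{a<b in g} D2[a,b] = (1_g' D2 1_g) / 2 to avoid index
    gymnastics in the permutation loop.
    """
    m = D2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    ss_total = D2.sum() / (2 * m)
    ss_within = 0.0
    for grp, n_g in zip(groups, counts):
        if n_g > 1:
            mask = (labels == grp).astype(float)
            ss_within += float(mask @ D2 @ mask) / (2 * n_g)
    ss_among = ss_total - ss_within
    if m == g:  # all singletons: no within-group degrees of freedom
        return float("nan")
    if ss_within == 0.0:
        return float("inf") if ss_among > 0 else float("nan")
    return (ss_among / (g - 1)) / (ss_within / (m - g))


def permanova(
    D: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """PERMANOVA: pseudo-F and permutation p-value for group separation.

    Partitions the sum of squared distances into among- and
    within-group components; significance comes from permuting the
    group labels.  ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``.
    The p-value is NaN when any group has fewer than two members.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    m = D.shape[0]
    if labels.shape[0] != m:
        raise ValueError("labels length must match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    D2 = D**2
    f_obs = _permanova_stats(D2, labels)
    if counts.min() < 2:
        return f_obs, float("nan")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_stats(D2, perm) >= f_obs:
            count += 1
    return f_obs, (1 + count) / (n_perm + 1)


def pairwise_permanova(
    D: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """PERMANOVA restricted to each pair of groups, with raw and
    Holm-adjusted (step-down) p-values."""
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    rows = []
    rng = np.random.default_rng(seed)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            idx = np.nonzero((labels == ga) | (labels == gb))[0]
            sub_seed = int(rng.integers(0, 2**31 - 1))
            f, p = permanova(
                D[np.ix_(idx, idx)], labels[idx], n_perm=n_perm, seed=sub_seed
            )
            rows.append({"group_a": ga, "group_b": gb, "pseudo_F": f, "p_raw": p})
    table = pd.DataFrame(rows)
    # Holm step-down on the testable (non-NaN) p-values
    p = table["p_raw"].to_numpy(dtype=float)
    adj = np.full_like(p, np.nan)
    testable = ~np.isnan(p)
    k = int(testable.sum())
    if k:
        order = np.argsort(p[testable])
        stacked = np.maximum.accumulate(
            [(k - r) * p[testable][order[r]] for r in range(k)]
        )
        vals = np.minimum(stacked, 1.0)
        tmp = np.empty(k)
        tmp[order] = vals
        adj[testable] = tmp
    table["p_holm"] = adj
    return table


def pca(X: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of (already range-normalized) traits: centered, not re-scaled.

    Returns (loadings, scores, variance_explained); loadings are columns
    (orthonormal), variance_explained is in percent and sums to 100.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[int(np.argmax(np.abs(col)))] < 0:
            loadings[:, j] = -col
            U[:, j] = -U[:, j]
    scores = U * s
    var = s**2
    variance_explained = 100.0 * var / var.sum() if var.sum() > 0 else var
    if cols is not None:
        loadings = pd.DataFrame(
            loadings,
            index=cols,
            columns=[f"PC{i + 1}" for i in range(loadings.shape[1])],
        )
    return loadings, scores, variance_explained


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram as Newick with branch lengths derived
    from merge heights (leaf depth = merge height of its parent)."""
    m = dend.n_leaves
    heights = {i: 0.0 for i in range(m)}
    parts: dict[int, str] = {i: dend.labels[i] for i in range(m)}
    for k, (left, right, h, _size) in enumerate(dend.merges):
        left, right = int(left), int(right)
        node = m + k
        bl_l = h - heights[left]
        bl_r = h - heights[right]
        parts[node] = f"({parts[left]}:{bl_l:.10g},{parts[right]}:{bl_r:.10g})"
        heights[node] = h
    return parts[m + len(dend.merges) - 1] + ";"
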