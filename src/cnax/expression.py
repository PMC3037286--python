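"""Expression-matrix preprocessing, unsupervised clustering, and
nearest-centroid subtype assignment.

Matrices are pandas frames, genes x samples, log2 scale. The floor filter
works on the linear scale (a gene must reach 100 units in at least one
sample); the variance filter keeps the top-k most variable genes. Sample
clustering uses Pearson-correlation distance (d = 1 - r) with complete or
centroid linkage; cluster robustness is estimated by ordinary bootstrap
resampling of genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "floor_filter",
    "variance_filter",
    "hierarchical_cluster",
    "bootstrap_cluster_support",
    "assign_subtype",
    "ClusterResult",
]


def floor_filter(matrix: pd.DataFrame, floor: float = 100.0) -> pd.DataFrame:
    """Drop genes whose linear-scale expression stays below ``floor`` in
    every sample. ``matrix`` is log2; floor = 0 keeps everything."""
    linear_max = np.power(2.0, matrix.to_numpy(dtype=float)).max(axis=1)
    return matrix.loc[linear_max >= floor]


def variance_filter(matrix: pd.DataFrame, top_k: int) -> pd.DataFrame:
    """Keep the ``top_k`` genes with the largest across-sample variance.

    Ties are broken by row order (stable sort), so the result is
    deterministic for a given gene ordering.
    """
    if top_k < 0:
        raise ValueError("top_k must be non-negative")
    var = matrix.to_numpy(dtype=float).var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[: min(top_k, len(var))]
    keep = np.zeros(len(var), dtype=bool)
    keep[order] = True
    return matrix.loc[keep]


@dataclass
class ClusterResult:
    labels: pd.Series          # sample -> flat cluster id (1..k)
    merges: list[tuple]        # (left members, right members, distance)
    newick: str
    linkage: str


def _corr_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson r between columns of x, clipped to [0, 2]."""
    r = np.corrcoef(x, rowvar=False)
    return np.clip(1.0 - r, 0.0, 2.0)


def _newick(children: dict, dists: dict, node: int, names: list[str]) -> str:
    if node < len(names):
        return names[node]
    l, r = children[node]
    dl = max(dists[node] - dists.get(l, 0.0), 0.0) / 2
    dr = max(dists[node] - dists.get(r, 0.0), 0.0) / 2
    return f"({_newick(children, dists, l, names)}:{dl:.6g},{_newick(children, dists, r, names)}:{dr:.6g})"


def _centroid_agglomerate(x: np.ndarray, k: int, names: list[str]):
    """Eisen-style centroid linkage under correlation distance: the distance
    between clusters is 1 - r of their mean profiles. Ties merge the pair
    with the smallest node indices."""
    n = x.shape[1]
    centroids = {i: x[:, i].astype(float).copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    members = {i: [i] for i in range(n)}
    active = sorted(centroids)
    children: dict[int, tuple[int, int]] = {}
    dists: dict[int, float] = {}
    merges: list[tuple] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                ca, cb = centroids[a], centroids[b]
                sa, sb = ca.std(), cb.std()
                if sa == 0 or sb == 0:
                    d = 1.0 if not np.allclose(ca, cb) else 0.0
                else:
                    d = 1.0 - float(np.corrcoef(ca, cb)[0, 1])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        new = next_id
        next_id += 1
        children[new] = (a, b)
        dists[new] = d
        merges.append((sorted(members[a]), sorted(members[b]), d))
        centroids[new] = (centroids[a] * sizes[a] + centroids[b] * sizes[b]) / (sizes[a] + sizes[b])
        sizes[new] = sizes[a] + sizes[b]
        members[new] = sorted(members[a] + members[b])
        active.remove(a)
        active.remove(b)
        active.append(new)
        active.sort()
    # flat clusters: replay merges until k clusters remain
    groups = [[i] for i in range(n)]
    for left, right, _ in merges:
        if len(groups) <= k:
            break
        gi = next(i for i, g in enumerate(groups) if set(left) <= set(g))
        gj = next(i for i, g in enumerate(groups) if set(right) <= set(g))
        merged = sorted(groups[gi] + groups[gj])
        groups = [g for i, g in enumerate(groups) if i not in (gi, gj)] + [merged]
    labels = np.zeros(n, dtype=int)
    for lab, g in enumerate(sorted(groups), start=1):
        for i in g:
            labels[i] = lab
    newick = _newick(children, dists, next_id - 1, names) + ";"
    return labels, merges, newick


def hierarchical_cluster(
    matrix: pd.DataFrame, k: int, linkage: str = "complete"
) -> ClusterResult:
    """Cluster the samples (columns) of a genes x samples log2 matrix.

    Distance is 1 - Pearson correlation. ``linkage`` is "complete"
    (scipy agglomeration on the precomputed distances) or "centroid"
    (cluster mean profiles re-correlated at every merge). Flat clusters are
    obtained by cutting the dendrogram into ``k`` groups.
    """
    x = matrix.to_numpy(dtype=float)
    names = list(matrix.columns)
    n = len(names)
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of samples")
    if linkage == "complete":
        d = _corr_distance(x)
        z = sch.linkage(squareform(d, checks=False), method="complete")
        labels = sch.fcluster(z, t=k, criterion="maxclust")
        tree = sch.to_tree(z)
        def nw(node):
            if node.is_leaf():
                return names[node.id]
            dl = max(node.dist - node.left.dist, 0.0) / 2
            dr = max(node.dist - node.right.dist, 0.0) / 2
            return f"({nw(node.left)}:{dl:.6g},{nw(node.right)}:{dr:.6g})"
        merges = [
            (int(row[0]), int(row[1]), float(row[2])) for row in z
        ]
        return ClusterResult(
            labels=pd.Series(labels, index=names),
            merges=merges,
            newick=nw(tree) + ";",
            linkage="complete",
        )
    if linkage == "centroid":
        labels, merges, newick = _centroid_agglomerate(x, k, names)
        return ClusterResult(
            labels=pd.Series(labels, index=names),
            merges=merges,
            newick=newick,
            linkage="centroid",
        )
    raise ValueError("linkage must be 'complete' or 'centroid'")


def bootstrap_cluster_support(
    matrix: pd.DataFrame,
    k: int,
    linkage: str = "complete",
    n_boot: int = 1000,
    seed: int = 0,
    robust_threshold: float = 90.0,
) -> pd.DataFrame:
    """Bootstrap (gene-resampling) support for each flat sample cluster.

    For every bootstrap draw of genes (rows, with replacement) the samples
    are re-clustered and a reference cluster counts as recovered when its
    exact member set reappears among the bootstrap flat clusters. Returns a
    frame (cluster, members, support_pct, robust) where robust means
    support >= ``robust_threshold`` percent.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    ref = hierarchical_cluster(matrix, k=k, linkage=linkage)
    ref_sets = {
        cid: frozenset(ref.labels.index[ref.labels == cid]) for cid in sorted(ref.labels.unique())
    }
    hits = {cid: 0 for cid in ref_sets}
    n_genes = matrix.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        boot = hierarchical_cluster(matrix.iloc[idx], k=k, linkage=linkage)
        boot_sets = {
            frozenset(boot.labels.index[boot.labels == cid]) for cid in boot.labels.unique()
        }
        for cid, s in ref_sets.items():
            if s in boot_sets:
                hits[cid] += 1
    rows = [
        {
            "cluster": cid,
            "members": sorted(ref_sets[cid]),
            "support_pct": 100.0 * hits[cid] / n_boot,
            "robust": 100.0 * hits[cid] / n_boot >= robust_threshold,
        }
        for cid in ref_sets
    ]
    return pd.DataFrame(rows)


def assign_subtype(sample: pd.Series, centroids: pd.DataFrame) -> str:
    """Nearest-centroid label: the centroid (column) with the highest
    Pearson correlation to the sample over the shared gene set. Exact ties
    go to the earlier centroid column, with a warning."""
    shared = centroids.index.intersection(sample.index)
    if len(shared) < 2:
        raise ValueError("need at least two shared genes to correlate")
    x = sample.loc[shared].to_numpy(dtype=float)
    cors = []
    for name in centroids.columns:
        c = centroids.loc[shared, name].to_numpy(dtype=float)
        if x.std() == 0 or c.std() == 0:
            cors.append(-np.inf)
        else:
            cors.append(float(np.corrcoef(x, c)[0, 1]))
    cors = np.asarray(cors)
    best = int(np.argmax(cors))
    if np.count_nonzero(cors == cors[best]) > 1:
        warnings.warn("tie between centroids; keeping the first")
    return str(centroids.columns[best])
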