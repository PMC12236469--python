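"""Dimensionality reduction, graph clustering, and cluster statistics.

Profiles are reduced by PCA to the smallest number of components explaining
a target fraction of variance (70% for the single-barcode screen, 60% for
the dual-barcode screen), joined into an unweighted cosine k-nearest-neighbour
graph (k=25), and partitioned with Louvain modularity maximization.  Cluster
phenotypes are characterized by Mann-Whitney feature ranking against robust
z effect-size filters, and per-position averages of the PCA profiles support
hierarchical grouping of mutated positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from dataclasses import dataclass, field


@dataclass
class EmbedConfig:
    variance_target: float = 0.7
    knn_k: int = 25
    louvain_seed: int = 0
    louvain_resolution: float = 1.0
    umap_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.variance_target < 1:
            raise ValueError("variance_target must lie in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def pca_reduce(matrix: np.ndarray, variance_target: float = 0.7
               ) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered PCA keeping the fewest components reaching the target.

    Returns (scores, explained_fractions) where ``explained_fractions`` spans
    all computable components and ``scores`` is cut at the smallest d with
    cumulative explained variance >= ``variance_target``.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 variants")
    pca = PCA()
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    if cum[-1] < variance_target:
        d = len(frac)                       # numerically unreachable target
    else:
        d = int(np.searchsorted(cum, variance_target) + 1)
    return scores[:, :d], frac


def knn_graph(scores: np.ndarray, k: int = 25, metric: str = "cosine") -> nx.Graph:
    """Undirected union of each node's k nearest neighbours.

    Distance ties break by node index (stable sort).  Rows must be nonzero
    for the cosine metric to be defined.
    """
    from sklearn.metrics import pairwise_distances

    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if n <= k:
        raise ValueError("need more nodes than k")
    if metric == "cosine" and np.any(np.linalg.norm(X, axis=1) == 0):
        raise ValueError("zero-norm rows are undefined under cosine distance")
    D = pairwise_distances(X, metric=metric)
    np.fill_diagonal(D, np.inf)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        nbrs = np.argsort(D[i], kind="stable")[:k]
        g.add_edges_from((i, int(j)) for j in nbrs)
    return g


def louvain_cluster(graph: nx.Graph, seed: int = 0, resolution: float = 1.0
                    ) -> "ClusterResult":
    """Louvain modularity clustering; labels are contiguous from 1.

    Communities are relabelled deterministically by their smallest member so
    the output is reproducible given the seed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(graph, seed=seed, resolution=resolution)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = {}
    for lab, members in enumerate(comms, start=1):
        for m in members:
            labels[m] = lab
    mod = nx.community.modularity(graph, comms, resolution=resolution)
    return ClusterResult(labels=labels, modularity=float(mod), n_clusters=len(comms))


@dataclass
class ClusterResult:
    labels: dict
    modularity: float
    n_clusters: int


def umap_embed(scores: np.ndarray, seed: int = 0, **params) -> np.ndarray:
    """2-D UMAP for visualization only; no quantitative claims are made on it."""
    import warnings
    from umap import UMAP

    params.setdefault("metric", "cosine")
    params.setdefault("n_components", 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")     # umap warns that a fixed seed disables parallelism
        emb = UMAP(random_state=seed, **params).fit_transform(np.asarray(scores, dtype=float))
    return emb


def rank_cluster_features(profiles: pd.DataFrame, cluster_labels: dict,
                          synonymous_labels: list[str],
                          z_thresh: float = 1.5) -> pd.DataFrame:
    """Mann-Whitney ranking of (feature, cluster) pairs with robust z filters.

    For each pair: MWU of the cluster's variants against all other variants;
    effect sizes z_all = (median_cluster - median_all)/MAD_all and
    z_syn = (median_cluster - median_syn)/MAD_syn.  Pairs pass only when
    both |z| exceed ``z_thresh``; survivors are sorted by increasing p.
    Size-1 clusters are skipped.
    """
    from scipy.stats import mannwhitneyu
    from .profiles import mad

    cols = [c for c in profiles.columns if c != "n_cells"]
    syn = profiles.loc[profiles.index.isin(synonymous_labels), cols]
    labels = pd.Series(cluster_labels)
    rows = []
    for cl in sorted(set(labels)):
        members = labels[labels == cl].index
        members = [m for m in members if m in profiles.index]
        if len(members) < 2:
            continue
        rest = profiles.index.difference(members)
        for f in cols:
            a = profiles.loc[members, f].to_numpy()
            b = profiles.loc[rest, f].to_numpy()
            all_v = profiles[f].to_numpy()
            mad_all, mad_syn = mad(all_v), mad(syn[f].to_numpy())
            if mad_all == 0 or mad_syn == 0:
                continue
            z_all = (np.median(a) - np.median(all_v)) / mad_all
            z_syn = (np.median(a) - np.median(syn[f])) / mad_syn
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            rows.append({"feature": f, "cluster": cl, "p_mwu": p,
                         "z_all": z_all, "z_syn": z_syn,
                         "retained": abs(z_all) > z_thresh and abs(z_syn) > z_thresh})
    out = pd.DataFrame(rows, columns=["feature", "cluster", "p_mwu", "z_all",
                                      "z_syn", "retained"])
    return out.sort_values(["p_mwu", "feature", "cluster"],
                           kind="stable").reset_index(drop=True)


def position_average_cluster(pca_scores: pd.DataFrame, position_of: dict,
                             n_clusters: int = 3,
                             subset: list[str] | None = None) -> pd.Series:
    """Group mutated positions by the correlation of their averaged profiles.

    Variant PCA vectors are averaged per position (restricted to ``subset``
    if given), the Pearson correlation matrix between position averages is
    formed, and average-linkage agglomerative clustering on (1 - r) is cut
    at ``n_clusters``.  Returns position -> cluster label.
    """
    from scipy.cluster.hierarchy import linkage, fcluster
    from scipy.spatial.distance import squareform

    use = pca_scores.index if subset is None else [v for v in subset
                                                  if v in pca_scores.index]
    groups: dict = {}
    for v in use:
        if v in position_of:
            groups.setdefault(position_of[v], []).append(v)
    positions = sorted(groups)
    if len(positions) < 2:
        raise ValueError("need at least 2 positions")
    avg = np.vstack([pca_scores.loc[groups[p]].mean(axis=0) for p in positions])
    r = np.corrcoef(avg)
    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    n_clusters = min(n_clusters, len(positions))
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=positions, name="position_cluster")
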