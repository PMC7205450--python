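"""PCA, SNN graph, modularity clustering with resolution sweep,
cluster-tree construction, marker testing, and merge of clusters
lacking unique markers.

Community detection uses resolution-parameterized modularity
optimization (Leiden refinement of Louvain); the SNN graph carries
Jaccard overlap weights of k-nearest-neighbour sets with the
conventional 1/15 pruning threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata, norm
from sklearn.neighbors import NearestNeighbors

from ovatlas.iodata import ValidationError
from ovatlas.qc import NormalizedMatrix, ScaledMatrix

__all__ = [
    "PCADecomposition",
    "SNNGraph",
    "ClusterLabels",
    "ClusterTree",
    "MarkerResult",
    "run_pca",
    "choose_elbow",
    "build_snn",
    "cluster_modularity",
    "resolution_sweep",
    "find_markers",
    "merge_unmarked_clusters",
    "umap_embed",
]


@dataclass
class PCADecomposition:
    embeddings: np.ndarray  # cells x n_pcs
    loadings: np.ndarray  # genes x n_pcs (unit columns)
    explained_variance_ratio: np.ndarray
    hvgs: list[str]


def run_pca(sm: ScaledMatrix, hvgs: list[str], n_pcs: int) -> PCADecomposition:
    """PCA of the scaled matrix restricted to HVG columns.

    The sign of each component is fixed so that its largest-magnitude
    gene loading is positive, making reruns bitwise identical.
    """
    idx = {g: i for i, g in enumerate(sm.gene_ids)}
    missing = [g for g in hvgs if g not in idx]
    if missing:
        raise ValidationError(f"HVGs not in matrix: {missing[:5]}")
    cols = np.array([idx[g] for g in hvgs])
    X = sm.values[:, cols]
    n_cells, n_feat = X.shape
    if n_pcs >= min(n_cells, n_feat):
        raise ValidationError(
            f"n_pcs={n_pcs} must be < min(cells, |hvgs|) = {min(n_cells, n_feat)}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(n_pcs):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total_var = (Xc**2).sum() / max(n_cells - 1, 1)
    evr = (s**2 / max(n_cells - 1, 1)) / total_var
    return PCADecomposition(
        embeddings=U * s,
        loadings=Vt.T,
        explained_variance_ratio=evr,
        hvgs=list(hvgs),
    )


def choose_elbow(explained_fractions: np.ndarray) -> int:
    """Elbow of a scree curve by the triangle (max chord distance) method.

    The corner of the scree is the point with the maximum perpendicular
    distance to the chord from the first to the last point (ties break
    to the smallest index); the returned count keeps the components
    before that corner. A flat scree returns 1 with a warning.
    """
    y = np.asarray(explained_fractions, dtype=float)
    if len(y) < 3:
        raise ValidationError("elbow selection needs >= 3 components")
    x = np.arange(len(y), dtype=float)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm_c = np.hypot(*chord)
    if norm_c == 0 or np.allclose(y, y[0]):
        warnings.warn("flat scree curve; elbow defaulting to 1", stacklevel=2)
        return 1
    d = np.abs(chord[0] * (p0[1] - y) - (p0[0] - x) * chord[1]) / norm_c
    # near-ties (e.g. an exactly linear scree) break to the smallest index
    corner = int(np.flatnonzero(d >= d.max() - 1e-12 * max(d.max(), 1))[0])
    return max(corner, 1)


@dataclass
class SNNGraph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""

    adjacency: sp.csr_matrix  # symmetric, weights in (prune, 1]
    k: int
    prune: float


def build_snn(
    pca: PCADecomposition | np.ndarray,
    k: int = 30,
    prune: float = 1.0 / 15.0,
) -> SNNGraph:
    """kNN (self excluded, Euclidean) then Jaccard overlap of kNN sets.

    Edge weight(i, j) = |N_i ∩ N_j| / |N_i ∪ N_j| over the k-neighbour
    sets; weights <= ``prune`` are dropped.
    """
    X = pca.embeddings if isinstance(pca, PCADecomposition) else np.asarray(pca)
    n = X.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]  # drop self
    rows = np.repeat(np.arange(n), k)
    member = sp.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    inter = (member @ member.T).tocoo()
    jac_data = inter.data / (2 * k - inter.data)
    keep = (jac_data > prune) & (inter.row != inter.col)
    adj = sp.csr_matrix(
        (jac_data[keep], (inter.row[keep], inter.col[keep])), shape=(n, n)
    )
    adj = adj.maximum(adj.T)
    return SNNGraph(adjacency=adj, k=k, prune=prune)


@dataclass
class ClusterLabels:
    labels: np.ndarray  # contiguous 0..K-1
    resolution: float
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    _, inv = np.unique(labels, return_inverse=True)
    return inv


def cluster_modularity(
    g: SNNGraph, resolution: float = 1.0, seed: int = 0
) -> ClusterLabels:
    """Resolution-parameterized modularity community detection (Leiden)."""
    adj = sp.triu(g.adjacency, k=0).tocoo()
    n = g.adjacency.shape[0]
    if n == 0:
        raise ValidationError("empty graph")
    graph = ig.Graph(
        n=n,
        edges=list(zip(adj.row.tolist(), adj.col.tolist())),
        edge_attrs={"weight": adj.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = _relabel_contiguous(np.array(part.membership))
    return ClusterLabels(
        labels=labels, resolution=resolution, modularity=part.quality()
    )


@dataclass
class ClusterTree:
    """Cross-resolution cluster overlap graph.

    ``edges`` columns: res_from, cluster_from, res_to, cluster_to,
    weight = fraction of the lower-resolution cluster's cells assigned
    to the higher-resolution cluster (out-weights of a node sum to 1).
    """

    edges: pd.DataFrame


def resolution_sweep(
    g: SNNGraph,
    resolutions: list[float] | None = None,
    seed: int = 0,
) -> tuple[list[ClusterLabels], ClusterTree]:
    """Cluster at each resolution and build the cluster tree."""
    if resolutions is None:
        resolutions = [0.5 * i for i in range(1, 13)]  # 0.5 .. 6.0
    if len(resolutions) < 2:
        raise ValidationError("sweep needs >= 2 resolutions")
    all_labels = [cluster_modularity(g, r, seed=seed) for r in resolutions]
    rows = []
    for lo, hi in zip(all_labels, all_labels[1:]):
        for c in range(lo.n_clusters):
            members = lo.labels == c
            total = members.sum()
            dest, counts = np.unique(hi.labels[members], return_counts=True)
            for d, cnt in zip(dest, counts):
                rows.append(
                    {
                        "res_from": lo.resolution,
                        "cluster_from": int(c),
                        "res_to": hi.resolution,
                        "cluster_to": int(d),
                        "weight": cnt / total,
                    }
                )
    return all_labels, ClusterTree(edges=pd.DataFrame(rows))


@dataclass
class MarkerResult:
    """Per (gene, cluster) differential expression table.

    Columns: gene_id, cluster, log2fc, pct_in, pct_out, p, p_adj,
    significant. p from a two-sided Wilcoxon rank-sum of the cluster's
    cells vs all others; Bonferroni correction over all tested genes.
    """

    table: pd.DataFrame
    min_pct: float
    min_log2fc: float
    alpha: float

    def significant_genes(self, cluster: int) -> set[str]:
        t = self.table
        m = (t["cluster"] == cluster) & t["significant"]
        return set(t.loc[m, "gene_id"])


def _ranksum_pvalues(
    X: np.ndarray,
    mask: np.ndarray,
    ranks: np.ndarray | None = None,
) -> np.ndarray:
    """Two-sided normal-approximation Wilcoxon rank-sum, vectorized over
    genes (columns of X). Tie correction is exact: the permutation
    variance of the rank sum is n1*n2/(n*(n-1)) * sum((r - rbar)^2),
    which reduces to the usual tie-term formula. Precomputed ranks may
    be passed to amortize across clusters."""
    if ranks is None:
        ranks = rankdata(X, axis=0)
    n = X.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    R1 = ranks[mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    rank_ss = ((ranks - (n + 1) / 2.0) ** 2).sum(axis=0)
    sigma2 = n1 * n2 / (n * (n - 1)) * rank_ss
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (R1 - mu) / sigma
    # continuity correction
    z = np.sign(z) * np.maximum(np.abs(z) - 0.5 / sigma, 0.0)
    return 2 * norm.sf(np.abs(z))


def _exact_ranksum_pvalue(ranks: np.ndarray, mask: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value under the permutation null.

    Enumerates the distribution of the group-1 rank sum over all
    C(n, n1) assignments by dynamic programming over the (tie-adjusted)
    rank multiset; p = P(|R1 - E[R1]| >= |observed - E[R1]|). Exact for
    tied data; counts stay below 2^53 for n <= 50.
    """
    n = len(ranks)
    n1 = int(mask.sum())
    r2 = np.round(2 * ranks).astype(int)  # half-integer ranks -> ints
    total = int(r2.sum())
    # dp[k][s] = number of k-subsets with rank*2 sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    counts = dp[n1]
    obs = int(np.round(2 * ranks[mask].sum()))
    mu = n1 * total / n
    dev = abs(obs - mu)
    sums = np.arange(total + 1)
    p = counts[np.abs(sums - mu) >= dev - 1e-9].sum() / counts.sum()
    return float(min(p, 1.0))


def find_markers(
    nm: NormalizedMatrix,
    labels: np.ndarray,
    min_pct: float = 0.25,
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
    min_cluster_size: int = 3,
    exact_max_cells: int = 50,
) -> MarkerResult:
    """Per-cluster marker genes by Wilcoxon rank-sum vs all other cells.

    Genes are prefiltered to those detected in >= ``min_pct`` of the
    cluster's cells; log2FC compares de-logged mean expression in vs
    out of the cluster (pseudocount 1). Bonferroni correction is over
    all (gene, cluster) tests performed; a gene is a significant marker
    when p_adj < alpha and log2FC >= min_log2fc. Instances with at most
    ``exact_max_cells`` cells use the exact (tie-aware) permutation
    distribution of the rank sum; larger ones the tie-corrected normal
    approximation with continuity correction.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValidationError("marker testing needs >= 2 clusters")
    X = nm.values.toarray()
    expm1 = np.expm1(X)
    all_ranks = rankdata(X, axis=0)
    rank_center = (X.shape[0] + 1) / 2.0
    rank_ss = ((all_ranks - rank_center) ** 2).sum(axis=0)
    rows = []
    for c in ids:
        mask = labels == c
        if mask.sum() < min_cluster_size:
            warnings.warn(
                f"cluster {c} below {min_cluster_size} cells; skipped",
                stacklevel=2,
            )
            continue
        pct_in = (X[mask] > 0).mean(axis=0)
        pct_out = (X[~mask] > 0).mean(axis=0)
        tested = np.flatnonzero(pct_in >= min_pct)
        if len(tested) == 0:
            continue
        mean_in = expm1[mask][:, tested].mean(axis=0)
        mean_out = expm1[~mask][:, tested].mean(axis=0)
        log2fc = np.log2(mean_in + 1) - np.log2(mean_out + 1)
        n = X.shape[0]
        if n <= exact_max_cells:
            p = np.array(
                [_exact_ranksum_pvalue(all_ranks[:, gi], mask) for gi in tested]
            )
        else:
            n1 = int(mask.sum())
            n2 = n - n1
            R1 = all_ranks[mask][:, tested].sum(axis=0)
            mu = n1 * (n + 1) / 2.0
            sigma = np.sqrt(
                np.maximum(n1 * n2 / (n * (n - 1)) * rank_ss[tested], 1e-300)
            )
            z = (R1 - mu) / sigma
            z = np.sign(z) * np.maximum(np.abs(z) - 0.5 / sigma, 0.0)
            p = 2 * norm.sf(np.abs(z))
        for j, gi in enumerate(tested):
            rows.append(
                {
                    "gene_id": nm.gene_ids[gi],
                    "cluster": int(c),
                    "log2fc": log2fc[j],
                    "pct_in": pct_in[gi],
                    "pct_out": pct_out[gi],
                    "p": p[j],
                }
            )
    table = pd.DataFrame(
        rows, columns=["gene_id", "cluster", "log2fc", "pct_in", "pct_out", "p"]
    )
    n_tests = max(len(table), 1)
    table["p_adj"] = np.minimum(table["p"] * n_tests, 1.0)
    table["significant"] = (table["p_adj"] < alpha) & (
        table["log2fc"] >= min_log2fc
    )
    return MarkerResult(
        table=table, min_pct=min_pct, min_log2fc=min_log2fc, alpha=alpha
    )


def _centroids(nm: NormalizedMatrix, labels: np.ndarray, hvgs: list[str] | None):
    X = nm.values
    if hvgs is not None:
        X = X[:, nm.gene_index(hvgs)]
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    ids = np.unique(labels)
    cent = np.vstack([X[labels == c].mean(axis=0) for c in ids])
    return ids, cent


def merge_unmarked_clusters(
    labels: np.ndarray,
    markers: MarkerResult,
    nm: NormalizedMatrix,
    hvgs: list[str] | None = None,
    max_iter: int = 10,
    find_markers_kwargs: dict | None = None,
) -> ClusterLabels:
    """Merge clusters lacking unique markers into their nearest neighbour.

    A cluster's unique marker is a significant marker gene that is not a
    significant marker of its nearest-neighbour cluster (the cluster
    with the highest centroid Pearson correlation in HVG log-normalized
    space). Clusters without any unique marker are merged into that
    neighbour; markers are recomputed and the procedure iterates to a
    fixed point (or ``max_iter``). Never increases the cluster count.
    """
    labels = np.asarray(labels).copy()
    kwargs = find_markers_kwargs or {}
    current = markers
    for _ in range(max_iter):
        ids, cent = _centroids(nm, labels, hvgs)
        if len(ids) < 2:
            break
        corr = np.corrcoef(cent)
        np.fill_diagonal(corr, -np.inf)
        merged_any = False
        for pos, c in enumerate(ids):
            nb = ids[int(np.argmax(corr[pos]))]
            own = current.significant_genes(c)
            unique = own - current.significant_genes(nb)
            if not unique:
                labels[labels == c] = nb
                merged_any = True
                break  # recompute neighbours/markers after each merge
        if not merged_any:
            break
        labels = _relabel_contiguous(labels)
        if len(np.unique(labels)) < 2:
            break
        current = find_markers(nm, labels, **kwargs)
    else:
        warnings.warn(
            f"cluster merging did not reach a fixed point in {max_iter} "
            "iterations",
            stacklevel=2,
        )
    labels = _relabel_contiguous(labels)
    return ClusterLabels(labels=labels, resolution=float("nan"), modularity=float("nan"))


def umap_embed(pca: PCADecomposition, n_pcs: int | None = None, seed: int = 0):
    """2-D UMAP embedding of the PC space (delegated to umap-learn).

    Contract only: returns a cells x 2 array, deterministic under the
    seed. Used for visualization, never for any statistic.
    """
    import umap

    X = pca.embeddings if n_pcs is None else pca.embeddings[:, :n_pcs]
    reducer = umap.UMAP(n_components=2, random_state=seed)
    return reducer.fit_transform(X)
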