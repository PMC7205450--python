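"""Canonical correlation alignment of two replicate data sets.

CCA is computed as a truncated SVD of the cross-covariance of the two
gene-standardized expression matrices over a shared high-dispersion
gene set, yielding paired cell-space canonical vectors (CVs). Biweight
midcorrelation (bicor) saturation curves diagnose how deep into the CV
spectrum each data set carries shared signal, and a kNN batch-entropy
mixing score quantifies how well the replicates interleave in the
aligned space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors

from ovatlas.iodata import ValidationError
from ovatlas.qc import HVGCriteria, NormalizedMatrix, select_hvg

__all__ = [
    "CCAResult",
    "shared_dispersion_genes",
    "run_cca",
    "bicor",
    "bicor_saturation",
    "mixing_score",
]


def shared_dispersion_genes(
    nm1: NormalizedMatrix,
    nm2: NormalizedMatrix,
    n_per_set: int = 1000,
) -> list[str]:
    """Union of each data set's top-dispersion genes, detected in both.

    Genes are ranked by standardized dispersion within each data set;
    the top ``n_per_set`` of each are united and intersected with the
    genes detected (nonzero) in both data sets.
    """
    common = set(nm1.gene_ids) & set(nm2.gene_ids)
    if not common:
        raise ValidationError("no shared gene universe")

    def top(nm: NormalizedMatrix) -> list[str]:
        _, stats = select_hvg(nm, HVGCriteria(min_dispersion=-np.inf,
                                              min_mean=-np.inf, max_mean=np.inf))
        stats = stats.sort_values("dispersion_std", ascending=False)
        return stats["gene_id"].head(n_per_set).tolist()

    def detected(nm: NormalizedMatrix) -> set[str]:
        nnz = np.asarray((nm.values > 0).sum(axis=0)).ravel()
        return {g for g, k in zip(nm.gene_ids, nnz) if k > 0}

    union = set(top(nm1)) | set(top(nm2))
    result = union & detected(nm1) & detected(nm2) & common
    if not result:
        raise ValidationError("shared dispersion gene set is empty")
    # deterministic order: data set 1 gene order
    return [g for g in nm1.gene_ids if g in result]


@dataclass
class CCAResult:
    """Paired canonical vectors of two data sets.

    ``proj1``/``proj2`` are cells x n_cv cell-space canonical vectors
    (unit-norm columns); ``correlations`` are the canonical
    correlations in [0, 1], sorted non-increasing; ``loadings`` are the
    shared gene-space axes (genes x n_cv) of data set 1.
    """

    proj1: np.ndarray
    proj2: np.ndarray
    correlations: np.ndarray
    genes: list[str]
    X1: np.ndarray  # standardized cells1 x genes
    X2: np.ndarray


def _standardize_genes(nm: NormalizedMatrix, genes: list[str]) -> np.ndarray:
    X = nm.values[:, nm.gene_index(genes)].toarray()
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return X / sd


def run_cca(
    nm1: NormalizedMatrix,
    nm2: NormalizedMatrix,
    genes: list[str],
    n_cv: int = 30,
) -> CCAResult:
    """Diagonal-penalized CCA via SVD of the cross-covariance matrix.

    Both matrices are gene-standardized; the SVD of K = X1 X2ᵀ / G
    gives paired cell-space canonical vectors. The canonical
    correlation per CV is the Pearson correlation (over genes) of the
    two metagenes X1ᵀu and X2ᵀv, clipped to [0, 1]; CVs are ordered by
    singular value. Signs are fixed so each CV's largest-|u| entry is
    positive, making reruns deterministic.
    """
    n1, n2 = nm1.n_cells, nm2.n_cells
    if n_cv > min(n1, n2, len(genes)):
        raise ValidationError(
            f"n_cv={n_cv} exceeds min(cells1, cells2, genes)="
            f"{min(n1, n2, len(genes))}"
        )
    X1 = _standardize_genes(nm1, genes)
    X2 = _standardize_genes(nm2, genes)
    K = (X1 @ X2.T) / len(genes)
    if n_cv < min(K.shape) - 1:
        U, s, Vt = svds(K, k=n_cv)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    else:
        U, s, Vt = np.linalg.svd(K, full_matrices=False)
        U, s, Vt = U[:, :n_cv], s[:n_cv], Vt[:n_cv]
    V = Vt.T
    for j in range(n_cv):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            U[:, j] *= -1
            V[:, j] *= -1
    m1 = X1.T @ U  # genes x n_cv metagenes
    m2 = X2.T @ V
    corrs = np.empty(n_cv)
    for j in range(n_cv):
        a, b = m1[:, j], m2[:, j]
        denom = np.linalg.norm(a - a.mean()) * np.linalg.norm(b - b.mean())
        corrs[j] = 0.0 if denom == 0 else float(
            np.dot(a - a.mean(), b - b.mean()) / denom
        )
    corrs = np.clip(corrs, 0.0, 1.0)
    order = np.argsort(corrs, kind="stable")[::-1]
    return CCAResult(
        proj1=U[:, order],
        proj2=V[:, order],
        correlations=corrs[order],
        genes=list(genes),
        X1=X1,
        X2=X2,
    )


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors.

    u_i = (x_i - med(x)) / (9 mad(x)); weight w_i = (1 - u_i²)² for
    |u_i| < 1 else 0; bicor is the correlation of the weighted centred
    vectors. Falls back to Pearson (with a warning) when either MAD is
    zero. Robust to outliers and invariant to positive affine
    transforms of either argument.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("bicor needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("bicor undefined for constant vectors")

    def weights(v: np.ndarray) -> np.ndarray | None:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = weights(x), weights(y)
    if a is None or b is None:
        warnings.warn("zero MAD; bicor falling back to Pearson", stacklevel=2)
        return float(np.corrcoef(x, y)[0, 1])
    a = a / np.sqrt((a**2).sum())
    b = b / np.sqrt((b**2).sum())
    return float(np.clip(np.dot(a, b), -1.0, 1.0))


def bicor_saturation(cca: CCAResult) -> pd.DataFrame:
    """bicor between each CV and its metagene projection, per data set.

    For CV j and data set d the metagene is that data set's own
    post-hoc gene loading X_dᵀ proj_d; the curve value is bicor(cell
    projection, expression re-projected on the metagene). A CV that
    captures real structure in a data set reproduces its own projection
    under this round trip (bicor near 1); a CV carried only by the
    other data set decays early. Columns: cv, bicor_1, bicor_2.
    """
    n_cv = cca.proj1.shape[1]
    if n_cv < 2:
        raise ValidationError("saturation curve needs >= 2 CVs")
    rows = []
    for j in range(n_cv):
        m1 = cca.X1.T @ cca.proj1[:, j]
        m2 = cca.X2.T @ cca.proj2[:, j]
        rows.append(
            {
                "cv": j + 1,
                "bicor_1": bicor(cca.proj1[:, j], cca.X1 @ m1),
                "bicor_2": bicor(cca.proj2[:, j], cca.X2 @ m2),
            }
        )
    return pd.DataFrame(rows)


def mixing_score(
    cca: CCAResult | np.ndarray,
    batch_labels: np.ndarray | None = None,
    k: int = 20,
) -> float:
    """Mean per-cell normalized batch entropy among k nearest neighbours.

    Accepts a CCAResult (cells of both data sets stacked, proj1 then
    proj2, L2-normalized per cell) or a precomputed embedding with
    explicit batch labels. 1 = perfectly mixed batches, 0 = fully
    separated.
    """
    if isinstance(cca, CCAResult):
        emb = np.vstack([cca.proj1, cca.proj2])
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        emb = emb / norms
        labels = np.array(
            [0] * cca.proj1.shape[0] + [1] * cca.proj2.shape[0]
        )
    else:
        emb = np.asarray(cca)
        if batch_labels is None:
            raise ValidationError("batch labels required with a raw embedding")
        labels = np.asarray(batch_labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("mixing score needs >= 2 batches")
    n = emb.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    idx = idx[:, 1:]
    code = np.searchsorted(uniq, labels)
    ent = np.zeros(n)
    for i in range(n):
        counts = np.bincount(code[idx[i]], minlength=len(uniq))
        p = counts / k
        nz = p > 0
        ent[i] = -(p[nz] * np.log(p[nz])).sum() / np.log(len(uniq))
    return float(ent.mean())
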