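"""QC metrics and filtration, log-normalization, HVG selection,
cell-cycle scoring, and covariate-regressed scaling.

The filtration defaults are the atlas thresholds: cells with fewer than
775 expressed genes, more than 2,200 genes, more than 18,000 UMIs, or
more than 1% mitochondrial UMIs are removed. The upper gene/UMI bounds
are applied disjunctively by default (a cell exceeding either is
removed); a conjunctive reading is available via ``upper_joint``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ovatlas.iodata import CountMatrix, ValidationError

__all__ = [
    "QCThresholds",
    "QCMetrics",
    "HVGCriteria",
    "NormalizedMatrix",
    "CellCycleScores",
    "ScaledMatrix",
    "compute_qc_metrics",
    "filter_cells",
    "lognormalize",
    "select_hvg",
    "score_gene_module",
    "assign_cell_cycle",
    "scale_regress",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC bounds. Percentages are on a 0-100 scale."""

    min_genes: int = 775
    max_genes: int = 2200
    max_umi: int = 18000
    max_pct_mito: float = 1.0
    upper_joint: bool = False  # conjunctive reading of the two upper bounds

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if min(self.min_genes, self.max_genes, self.max_umi) <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass
class QCMetrics:
    """Per-cell QC metrics aligned with a CountMatrix."""

    n_genes: np.ndarray
    n_umi: np.ndarray
    pct_mito: np.ndarray

    def to_frame(self, barcodes: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": barcodes,
                "n_genes": self.n_genes,
                "n_umi": self.n_umi,
                "pct_mito": self.pct_mito,
            }
        )


def compute_qc_metrics(cm: CountMatrix) -> QCMetrics:
    """n_genes (genes with count > 0), n_umi (row sum), pct_mito (0-100)."""
    counts = cm.counts
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    n_umi = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, cm.mito_flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito / np.maximum(n_umi, 1), 0.0)
    return QCMetrics(n_genes=n_genes, n_umi=n_umi.astype(np.int64), pct_mito=pct)


def filter_cells(
    cm: CountMatrix,
    metrics: QCMetrics,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove out-of-range cells; report removals per reason.

    A cell is kept iff n_genes in [min_genes, max_genes], n_umi <=
    max_umi, and pct_mito <= max_pct_mito. With ``upper_joint`` the two
    upper bounds remove a cell only when both are exceeded. The report
    counts each cell once per violated bound, plus a ``removed_total``
    row (cells can violate several bounds at once).
    """
    thr = thresholds or QCThresholds()
    if len(metrics.n_genes) != cm.n_cells:
        raise ValidationError("metrics not aligned with matrix")
    low = metrics.n_genes < thr.min_genes
    hi_genes = metrics.n_genes > thr.max_genes
    hi_umi = metrics.n_umi > thr.max_umi
    hi_mito = metrics.pct_mito > thr.max_pct_mito
    if thr.upper_joint:
        upper = hi_genes & hi_umi
        removed = low | upper | hi_mito
        report = pd.DataFrame(
            {
                "reason": ["low_gene", "high_gene_and_umi", "high_mito",
                           "removed_total", "kept"],
                "n_cells": [
                    int(low.sum()),
                    int(upper.sum()),
                    int(hi_mito.sum()),
                    int(removed.sum()),
                    int((~removed).sum()),
                ],
            }
        )
    else:
        removed = low | hi_genes | hi_umi | hi_mito
        report = pd.DataFrame(
            {
                "reason": ["low_gene", "high_gene", "high_umi", "high_mito",
                           "removed_total", "kept"],
                "n_cells": [
                    int(low.sum()),
                    int(hi_genes.sum()),
                    int(hi_umi.sum()),
                    int(hi_mito.sum()),
                    int(removed.sum()),
                    int((~removed).sum()),
                ],
            }
        )
    if removed.all():
        raise ValidationError(
            "no cells survive QC filtration; report:\n" + report.to_string()
        )
    return cm.subset_cells(~removed), report


@dataclass
class NormalizedMatrix:
    """ln(1 + scale_factor * count / cell_total), cells x genes, sparse."""

    values: sp.csr_matrix
    barcodes: list[str]
    gene_ids: list[str]
    scale_factor: float = 1e4

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_index) -> "NormalizedMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NormalizedMatrix(
            values=self.values[idx],
            barcodes=[self.barcodes[i] for i in idx],
            gene_ids=list(self.gene_ids),
            scale_factor=self.scale_factor,
        )

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize to ``scale_factor`` and ln(1+x) transform."""
    totals = np.asarray(cm.counts.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        raise ValidationError("all-zero cell: cannot normalize")
    x = cm.counts.astype(np.float64).tocsr(copy=True)
    inv = scale_factor / totals
    x.data *= np.repeat(inv, np.diff(x.indptr))
    np.log1p(x.data, out=x.data)
    return NormalizedMatrix(
        values=x,
        barcodes=list(cm.barcodes),
        gene_ids=list(cm.gene_ids),
        scale_factor=scale_factor,
    )


@dataclass(frozen=True)
class HVGCriteria:
    """Mean/dispersion window for highly variable gene selection."""

    min_dispersion: float = 0.4
    min_mean: float = 0.01
    max_mean: float = 3.0
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.min_mean >= self.max_mean:
            raise ValidationError("min_mean must be < max_mean")


def _gene_mean_var(values: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    mean = np.asarray(values.mean(axis=0)).ravel()
    sq = values.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    n = values.shape[0]
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvg(
    nm: NormalizedMatrix, criteria: HVGCriteria | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Mean/dispersion HVG selection with binned dispersion z-scores.

    Dispersion is variance/mean of the de-logged (expm1) values; genes
    are binned into ``n_bins`` equal-frequency bins of log-normalized
    mean and the log dispersion is z-scored within each bin. Selected
    genes have standardized dispersion > min_dispersion and mean inside
    (min_mean, max_mean). Returns (gene list, per-gene stats frame).
    """
    crit = criteria or HVGCriteria()
    if nm.n_cells < 2:
        raise ValidationError("HVG selection needs >= 2 cells")
    log_mean = np.asarray(nm.values.mean(axis=0)).ravel()
    expm1 = nm.values.copy()
    np.expm1(expm1.data, out=expm1.data)
    mean, var = _gene_mean_var(expm1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    log_disp = np.log(np.maximum(disp, 1e-12))

    n_bins = min(crit.n_bins, max(1, nm.n_genes // 2))
    if n_bins < crit.n_bins:
        warnings.warn(
            f"fewer genes than bins; using {n_bins} dispersion bins",
            stacklevel=2,
        )
    order = np.argsort(log_mean, kind="stable")
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(nm.n_genes) * n_bins) // nm.n_genes, n_bins - 1
    )
    z = np.zeros(nm.n_genes)
    for b in range(n_bins):
        m = bins == b
        vals = log_disp[m]
        sd = vals.std()
        if sd > 0:
            z[m] = (vals - vals.mean()) / sd
    selected = (
        (z > crit.min_dispersion)
        & (log_mean > crit.min_mean)
        & (log_mean < crit.max_mean)
        & (disp > 0)
    )
    stats = pd.DataFrame(
        {
            "gene_id": nm.gene_ids,
            "mean": log_mean,
            "dispersion": disp,
            "dispersion_std": z,
            "highly_variable": selected,
        }
    )
    genes = [g for g, s in zip(nm.gene_ids, selected) if s]
    return genes, stats


def score_gene_module(
    nm: NormalizedMatrix,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Bin-matched control gene-module score per cell.

    score = mean expression over the module minus mean over control
    genes; ``n_ctrl`` controls are sampled per module gene from the
    same average-expression bin, excluding the module itself.
    """
    present = [g for g in gene_set if g in set(nm.gene_ids)]
    if not present:
        raise ValidationError("no module genes present in matrix")
    rng = np.random.default_rng(seed)
    gene_mean = np.asarray(nm.values.mean(axis=0)).ravel()
    n_bins = min(n_bins, nm.n_genes)
    order = np.argsort(gene_mean, kind="stable")
    bins = np.empty(nm.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(nm.n_genes) * n_bins) // nm.n_genes, n_bins - 1
    )
    set_idx = nm.gene_index(present)
    in_set = np.zeros(nm.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if len(pool) == 0:
            pool = np.flatnonzero(~in_set)
        if len(pool) == 0:
            raise ValidationError("no control genes outside the module")
        ctrl.append(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False))
    ctrl_idx = np.unique(np.concatenate(ctrl))
    set_mean = np.asarray(nm.values[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(nm.values[:, ctrl_idx].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


@dataclass
class CellCycleScores:
    """Per-cell S/G2M module scores, their difference, and the phase call."""

    s_score: np.ndarray
    g2m_score: np.ndarray
    phase: np.ndarray  # G1 / S / G2M

    @property
    def cc_difference(self) -> np.ndarray:
        return self.g2m_score - self.s_score


def assign_cell_cycle(
    nm: NormalizedMatrix,
    s_genes: list[str],
    g2m_genes: list[str],
    seed: int = 0,
) -> CellCycleScores:
    """Score S and G2M programs and call a phase per cell.

    Phase is S when the S score both exceeds the G2M score and is
    positive, G2M when the G2M score is >= the S score and positive,
    and G1 otherwise.
    """
    s = score_gene_module(nm, s_genes, seed=seed)
    g2m = score_gene_module(nm, g2m_genes, seed=seed + 1)
    phase = np.where(
        (s > g2m) & (s > 0),
        "S",
        np.where((g2m >= s) & (g2m > 0), "G2M", "G1"),
    )
    return CellCycleScores(s_score=s, g2m_score=g2m, phase=phase)


@dataclass
class ScaledMatrix:
    """Per-gene covariate-regressed, z-scored, clipped expression."""

    values: np.ndarray  # dense cells x genes
    barcodes: list[str]
    gene_ids: list[str]
    clip_max: float = 10.0


def scale_regress(
    nm: NormalizedMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    clip_max: float = 10.0,
) -> ScaledMatrix:
    """Regress covariates out of each gene, then z-score and clip.

    For each gene, ordinary least squares of the log-normalized values
    on the covariate columns (typically n_umi, pct_mito and the G2M-S
    score difference) plus an intercept; residuals are z-scored per
    gene and clipped at ``+-clip_max``. Collinear covariate columns are
    dropped with a warning. With no covariates this reduces to plain
    per-gene scaling.
    """
    if nm.n_cells < 3:
        raise ValidationError("scaling needs >= 3 cells")
    X = nm.values.toarray()
    n = X.shape[0]
    if covariates is not None:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValidationError("covariates not aligned with matrix")
        if not np.isfinite(C).all():
            raise ValidationError("non-finite covariate values")
        # drop constant / collinear columns
        keep: list[int] = []
        D = np.ones((n, 1))
        for j in range(C.shape[1]):
            cand = np.column_stack([D, C[:, j]])
            if np.linalg.matrix_rank(cand) > D.shape[1]:
                D = cand
                keep.append(j)
            else:
                warnings.warn(
                    f"covariate column {j} constant or collinear; dropped",
                    stacklevel=2,
                )
        beta, *_ = np.linalg.lstsq(D, X, rcond=None)
        resid = X - D @ beta
    else:
        resid = X - X.mean(axis=0, keepdims=True)
    resid = resid - resid.mean(axis=0, keepdims=True)
    sd = resid.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.clip(resid / sd, -clip_max, clip_max)
    return ScaledMatrix(
        values=z,
        barcodes=list(nm.barcodes),
        gene_ids=list(nm.gene_ids),
        clip_max=clip_max,
    )
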