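"""Marker-conflict doublet filtering.

A curated marker panel declares cell types and conflict groups; types
in different groups are "distantly related". Each cell receives a
log2-scale score per panel type, and a cell is flagged as a suspected
doublet when two conflicting types both score above a cutoff θ
(default 1, i.e. more than 2-fold over the pseudocount baseline).
Types sharing a conflict group — e.g. successive states of one
developmental trajectory — are exempt, which preserves genuine
intermediary cell states. Removed cells are always returned alongside
the kept ones, never silently dropped.

Two readings of the cutoff are provided: ``absolute`` compares the
type score itself to θ, ``relative`` compares the score's excess over
the cell population's median score for that type (a fold-change over
background). The absolute reading is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ovatlas.iodata import CountMatrix, MarkerPanel, ValidationError
from ovatlas.qc import NormalizedMatrix, select_hvg

__all__ = [
    "ConflictRule",
    "ConflictReport",
    "score_types",
    "flag_conflicts",
    "apply_cleanup",
    "retention_check",
]


@dataclass(frozen=True)
class ConflictRule:
    """Cutoff θ (log2 scale), panel aggregation, and scope.

    scope "per-cluster" counts only conflicts that involve a type
    foreign to the cell's cluster identity (mirroring cluster-by-
    cluster cleanup); "global" counts every conflicting pair.
    """

    threshold: float = 1.0
    aggregation: str = "mean"  # mean | max over a type's panel genes
    scope: str = "per-cluster"  # per-cluster | global
    reference: str = "absolute"  # absolute | relative (over median background)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("conflict threshold must be > 0")
        if self.aggregation not in ("mean", "max"):
            raise ValidationError("aggregation must be 'mean' or 'max'")
        if self.scope not in ("per-cluster", "global"):
            raise ValidationError("scope must be 'per-cluster' or 'global'")
        if self.reference not in ("absolute", "relative"):
            raise ValidationError("reference must be 'absolute' or 'relative'")


@dataclass
class ConflictReport:
    """Per-cell scores, flags, and per-cluster removal accounting."""

    scores: pd.DataFrame  # cells x types, index = barcode
    flagged: np.ndarray  # bool per cell
    conflicting_pairs: list[list[tuple[str, str]]]  # per cell
    rule: ConflictRule
    cluster_removals: pd.DataFrame  # cluster, n_cells, n_removed

    @property
    def n_removed(self) -> int:
        return int(self.flagged.sum())


def score_types(
    nm: NormalizedMatrix,
    panel: MarkerPanel,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-cell, per-type panel score: log2(1 + agg expm1 expression).

    The aggregation (mean or max) runs over the de-logged normalized
    expression of the type's panel genes, so the score is on the same
    log2 scale for every type regardless of panel size.
    """
    present = set(nm.gene_ids)
    cols = {}
    for cell_type in panel.cell_types:
        genes = [g for g in panel.genes_for(cell_type) if g in present]
        if not genes:
            raise ValidationError(
                f"panel type '{cell_type}' has no genes in the matrix"
            )
        sub = nm.values[:, nm.gene_index(genes)].toarray()
        expm1 = np.expm1(sub)
        agg = expm1.mean(axis=1) if aggregation == "mean" else expm1.max(axis=1)
        cols[cell_type] = np.log2(1.0 + agg)
    return pd.DataFrame(cols, index=list(nm.barcodes))


def flag_conflicts(
    scores: pd.DataFrame,
    panel: MarkerPanel,
    rule: ConflictRule | None = None,
    labels: np.ndarray | None = None,
    cluster_identity: dict[int, str] | None = None,
) -> ConflictReport:
    """Flag cells whose scores exceed θ for two conflicting types.

    A cell is flagged iff some declared-conflicting type pair (A, B)
    has score_A > θ and score_B > θ. In per-cluster scope (the
    cluster-by-cluster cleanup) only pairs consisting of the cell's own
    cluster identity and a type foreign to it count — evidence that the
    cell carries its cluster's signature plus a distantly related one.
    The cluster identity is the supplied mapping or, by default, the
    panel type with the highest mean score among the cluster's cells.
    """
    rule = rule or ConflictRule()
    if rule.scope == "per-cluster" and labels is None:
        raise ValidationError("per-cluster scope requires cluster labels")
    n = len(scores)
    vals = scores.to_numpy()
    types = list(scores.columns)
    if rule.reference == "relative":
        vals = vals - np.median(vals, axis=0, keepdims=True)
    above = vals > rule.threshold
    col = {t: i for i, t in enumerate(types)}
    pairs = [
        (a, b)
        for fs in panel.conflict_pairs
        for a, b in [sorted(fs)]
        if a in col and b in col
    ]

    identity: dict[int, str] = {}
    if rule.scope == "per-cluster":
        labels = np.asarray(labels)
        if cluster_identity is not None:
            identity = dict(cluster_identity)
        else:
            for c in np.unique(labels):
                mean_scores = vals[labels == c].mean(axis=0)
                identity[int(c)] = types[int(np.argmax(mean_scores))]

    flagged = np.zeros(n, dtype=bool)
    per_cell_pairs: list[list[tuple[str, str]]] = [[] for _ in range(n)]
    if rule.scope == "per-cluster":
        own = np.array(
            [identity.get(int(c), "") for c in labels], dtype=object
        )
    for a, b in pairs:
        hit = above[:, col[a]] & above[:, col[b]]
        if rule.scope == "per-cluster":
            hit = hit & ((own == a) | (own == b))  # pair must involve own type
        for i in np.flatnonzero(hit):
            per_cell_pairs[i].append((a, b))
        flagged |= hit

    if labels is not None:
        lab = np.asarray(labels)
        rows = [
            {
                "cluster": int(c),
                "n_cells": int((lab == c).sum()),
                "n_removed": int(flagged[lab == c].sum()),
            }
            for c in np.unique(lab)
        ]
    else:
        rows = [{"cluster": -1, "n_cells": n, "n_removed": int(flagged.sum())}]
    return ConflictReport(
        scores=scores,
        flagged=flagged,
        conflicting_pairs=per_cell_pairs,
        rule=rule,
        cluster_removals=pd.DataFrame(rows),
    )


def apply_cleanup(
    cm: CountMatrix, report: ConflictReport
) -> tuple[CountMatrix, CountMatrix]:
    """Partition the matrix into (high-quality, removed) by the flags."""
    if len(report.flagged) != cm.n_cells:
        raise ValidationError("conflict report not aligned with matrix")
    keep = ~report.flagged
    if not keep.any():
        raise ValidationError("conflict cleanup removed every cell")
    return cm.subset_cells(keep), cm.subset_cells(report.flagged)


def retention_check(
    nm_pre: NormalizedMatrix,
    nm_post: NormalizedMatrix,
    panel: MarkerPanel,
    threshold: float = 1.0,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Verify the cleanup kept every cell type and quenched conflicts.

    Per panel type: (a) at least one retained cell scores above θ on
    its own panel (no type eliminated); (b) among retained cells whose
    own-type score exceeds θ, every conflicting type's score is <= θ.
    Also reports the HVG count before and after cleanup.
    """
    post_barcodes = set(nm_post.barcodes)
    if not post_barcodes.issubset(set(nm_pre.barcodes)):
        raise ValidationError("post matrix is not a subset of pre matrix")
    scores = score_types(nm_post, panel, aggregation)
    groups = panel.groups
    hvg_pre = len(select_hvg(nm_pre)[0])
    hvg_post = len(select_hvg(nm_post)[0])
    rows = []
    for t in panel.cell_types:
        own_above = scores[t] > threshold
        retained = bool(own_above.any())
        conflicting = [
            u for u in panel.cell_types if u != t and groups[u] != groups[t]
        ]
        if own_above.any() and conflicting:
            conf_ok = bool(
                (scores.loc[own_above, conflicting] <= threshold).all().all()
            )
        else:
            conf_ok = True
        rows.append(
            {
                "cell_type": t,
                "type_retained": retained,
                "conflicts_quenched": conf_ok,
                "n_cells_above_threshold": int(own_above.sum()),
                "hvg_pre": hvg_pre,
                "hvg_post": hvg_post,
            }
        )
    return pd.DataFrame(rows)
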