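"""Cross-cluster shared signatures and end-to-end pipeline orchestration.

The pipeline mirrors the atlas-construction flow: ingest counts, QC
filter, log-normalize, score/regress cell cycle, select HVGs, PCA,
SNN graph, resolution sweep, marker testing with merge of unmarked
clusters, marker-conflict doublet cleanup, and re-normalization of the
high-quality cells. Every stage writes plain TSV outputs plus a JSON
manifest recording parameters, seeds, and cell counts, so a rerun
under the same seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ovatlas import clustering, conflict, qc
from ovatlas.iodata import (
    CountMatrix,
    MarkerPanel,
    ValidationError,
    read_marker_panel,
    read_mtx_triplet,
    write_cell_table,
)

__all__ = ["SharedSignature", "PipelineConfig", "shared_signature", "run_pipeline"]

log = logging.getLogger("ovatlas")


@dataclass
class SharedSignature:
    """Genes significantly enriched in both of two clusters."""

    cluster_a: int
    cluster_b: int
    common_genes: list[str]
    table: pd.DataFrame  # gene_id, mean_expr_a, mean_expr_b, rank
    top_n: int

    @property
    def top_genes(self) -> list[str]:
        return self.table["gene_id"].head(self.top_n).tolist()


def shared_signature(
    markers: clustering.MarkerResult,
    cluster_a: int,
    cluster_b: int,
    nm: qc.NormalizedMatrix,
    labels: np.ndarray,
    top_n: int = 30,
) -> SharedSignature:
    """Intersect two clusters' significant markers, rank by expression.

    The common set is the intersection of the clusters' significant
    marker genes; genes are ranked by their mean log-normalized
    expression across the two clusters' cells. An empty intersection
    yields an empty (not erroneous) signature.
    """
    labels = np.asarray(labels)
    common = markers.significant_genes(cluster_a) & markers.significant_genes(
        cluster_b
    )
    if not common:
        empty = pd.DataFrame(
            columns=["gene_id", "mean_expr_a", "mean_expr_b", "mean_expr"]
        )
        return SharedSignature(cluster_a, cluster_b, [], empty, top_n)
    genes = sorted(common)
    idx = nm.gene_index(genes)
    in_a = labels == cluster_a
    in_b = labels == cluster_b
    mean_a = np.asarray(nm.values[in_a][:, idx].mean(axis=0)).ravel()
    mean_b = np.asarray(nm.values[in_b][:, idx].mean(axis=0)).ravel()
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_expr_a": mean_a,
            "mean_expr_b": mean_b,
            "mean_expr": (mean_a + mean_b) / 2,
        }
    ).sort_values("mean_expr", ascending=False, kind="stable")
    table = table.reset_index(drop=True)
    return SharedSignature(cluster_a, cluster_b, genes, table, top_n)


@dataclass
class PipelineConfig:
    """All pipeline parameters; load from YAML with ``from_yaml``."""

    input_dir: str | None = None  # MatrixMarket triplet directory
    panel_path: str | None = None
    s_genes: list[str] = field(default_factory=list)
    g2m_genes: list[str] = field(default_factory=list)
    mito_prefix: str = "mt:"
    min_genes: int = 775
    max_genes: int = 2200
    max_umi: int = 18000
    max_pct_mito: float = 1.0
    scale_factor: float = 1e4
    hvg_min_dispersion: float = 0.4
    hvg_min_mean: float = 0.01
    hvg_max_mean: float = 3.0
    n_pcs: int = 30
    snn_k: int = 30
    snn_prune: float = 1.0 / 15.0
    resolutions: list[float] = field(
        default_factory=lambda: [0.5 * i for i in range(1, 13)]
    )
    cluster_resolution: float = 1.0
    marker_min_pct: float = 0.25
    marker_min_log2fc: float = 0.25
    marker_alpha: float = 0.05
    conflict_theta: float = 1.0
    conflict_scope: str = "per-cluster"
    signature_clusters: tuple[int, int] | None = None
    signature_top_n: int = 30
    skip: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("input_dir", "panel_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{key} does not exist: {p}")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    cm: CountMatrix | None = None,
    panel: MarkerPanel | None = None,
) -> dict:
    """Run the full flow and write stage outputs + manifest to out_dir.

    Inputs come from ``config.input_dir`` / ``config.panel_path`` or
    may be passed in memory (``cm``, ``panel``). Returns the manifest
    dict (also written as manifest.json). Stage names in
    ``config.skip`` are skipped and flagged in the manifest.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "skipped": list(config.skip),
    }
    log.info("pipeline started %s", time.strftime("%Y-%m-%dT%H:%M:%S"))

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    if cm is None:
        if config.input_dir is None:
            raise ValidationError("no input: set input_dir or pass a matrix")
        d = Path(config.input_dir)
        cm = read_mtx_triplet(
            d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv",
            mito_prefix=config.mito_prefix,
        )
    record("load", n_cells=cm.n_cells, n_genes=cm.n_genes)

    if panel is None and config.panel_path is not None:
        panel = read_marker_panel(config.panel_path)

    # ---- QC ----------------------------------------------------------
    metrics = qc.compute_qc_metrics(cm)
    metrics.to_frame(cm.barcodes).to_csv(
        out / "qc_metrics.tsv", sep="\t", index=False
    )
    if "qc" not in config.skip:
        thr = qc.QCThresholds(
            min_genes=config.min_genes,
            max_genes=config.max_genes,
            max_umi=config.max_umi,
            max_pct_mito=config.max_pct_mito,
        )
        cm, report = qc.filter_cells(cm, metrics, thr)
        report.to_csv(out / "qc_removal_report.tsv", sep="\t", index=False)
        metrics = qc.compute_qc_metrics(cm)
        record(
            "qc",
            kept=cm.n_cells,
            removed=int(report.loc[report.reason == "removed_total", "n_cells"].iloc[0]),
        )

    # ---- normalize / cell cycle / scale ------------------------------
    nm = qc.lognormalize(cm, scale_factor=config.scale_factor)
    record("normalize", scale_factor=config.scale_factor)

    cc_diff = None
    phases = np.array(["G1"] * cm.n_cells, dtype=object)
    if config.s_genes and config.g2m_genes and "cellcycle" not in config.skip:
        cc = qc.assign_cell_cycle(
            nm, config.s_genes, config.g2m_genes, seed=config.seed
        )
        cc_diff = cc.cc_difference
        phases = cc.phase
        pd.DataFrame(
            {
                "barcode": cm.barcodes,
                "s_score": cc.s_score,
                "g2m_score": cc.g2m_score,
                "phase": cc.phase,
            }
        ).to_csv(out / "cell_cycle.tsv", sep="\t", index=False)
        record("cellcycle", n_s=int((phases == "S").sum()),
               n_g2m=int((phases == "G2M").sum()))

    hvgs, hvg_stats = qc.select_hvg(
        nm,
        qc.HVGCriteria(
            min_dispersion=config.hvg_min_dispersion,
            min_mean=config.hvg_min_mean,
            max_mean=config.hvg_max_mean,
        ),
    )
    hvg_stats.to_csv(out / "hvg_stats.tsv", sep="\t", index=False)
    record("hvg", n_hvg=len(hvgs))

    covs = pd.DataFrame(
        {"n_umi": metrics.n_umi.astype(float), "pct_mito": metrics.pct_mito}
    )
    if cc_diff is not None:
        covs["cc_difference"] = cc_diff
    sm_ = qc.scale_regress(nm, covs)
    record("scale", covariates=list(covs.columns))

    # ---- PCA / SNN / sweep / markers / merge -------------------------
    n_pcs = min(config.n_pcs, min(cm.n_cells, len(hvgs)) - 1)
    pca = clustering.run_pca(sm_, hvgs, n_pcs=n_pcs)
    record("pca", n_pcs=n_pcs,
           elbow=clustering.choose_elbow(pca.explained_variance_ratio))
    snn = clustering.build_snn(pca, k=min(config.snn_k, cm.n_cells - 1),
                               prune=config.snn_prune)
    sweep_labels, tree = clustering.resolution_sweep(
        snn, config.resolutions, seed=config.seed
    )
    tree.edges.to_csv(out / "cluster_tree.tsv", sep="\t", index=False)
    sweep_df = pd.DataFrame({"barcode": cm.barcodes})
    for cl in sweep_labels:
        sweep_df[f"res_{cl.resolution:g}"] = cl.labels
    sweep_df.to_csv(out / "cluster_sweep.tsv", sep="\t", index=False)
    record("sweep", n_clusters={f"{c.resolution:g}": c.n_clusters
                                for c in sweep_labels})

    base = clustering.cluster_modularity(
        snn, resolution=config.cluster_resolution, seed=config.seed
    )
    mk_kwargs = dict(
        min_pct=config.marker_min_pct,
        min_log2fc=config.marker_min_log2fc,
        alpha=config.marker_alpha,
    )
    markers = clustering.find_markers(nm, base.labels, **mk_kwargs)
    merged = clustering.merge_unmarked_clusters(
        base.labels, markers, nm, hvgs=hvgs, find_markers_kwargs=mk_kwargs
    )
    markers = clustering.find_markers(nm, merged.labels, **mk_kwargs)
    markers.table.to_csv(out / "markers.tsv", sep="\t", index=False)
    record("cluster", n_initial=base.n_clusters, n_final=merged.n_clusters)
    labels = merged.labels

    # ---- conflict filter ---------------------------------------------
    flagged = np.zeros(cm.n_cells, dtype=bool)
    if panel is not None and "conflict" not in config.skip:
        rule = conflict.ConflictRule(
            threshold=config.conflict_theta, scope=config.conflict_scope
        )
        scores = conflict.score_types(nm, panel)
        report = conflict.flag_conflicts(scores, panel, rule, labels=labels)
        flagged = report.flagged
        report.cluster_removals.to_csv(
            out / "conflict_removals.tsv", sep="\t", index=False
        )
        (out / "removed_barcodes.txt").write_text(
            "".join(
                b + "\n" for b, f in zip(cm.barcodes, flagged) if f
            )
        )
        kept_cm, removed_cm = conflict.apply_cleanup(cm, report)
        nm_post = qc.lognormalize(kept_cm, scale_factor=config.scale_factor)
        retention = conflict.retention_check(
            nm, nm_post, panel, threshold=config.conflict_theta
        )
        retention.to_csv(out / "retention_check.tsv", sep="\t", index=False)
        record(
            "conflict",
            removed=int(flagged.sum()),
            kept=kept_cm.n_cells,
            hvg_pre=int(retention["hvg_pre"].iloc[0]),
            hvg_post=int(retention["hvg_post"].iloc[0]),
        )
    elif panel is None:
        manifest["skipped"].append("conflict (no panel)")

    # ---- shared signature --------------------------------------------
    if config.signature_clusters is not None and "signature" not in config.skip:
        a, b = config.signature_clusters
        sig = shared_signature(markers, a, b, nm, labels,
                               top_n=config.signature_top_n)
        sig.table.to_csv(out / "shared_signature.tsv", sep="\t", index=False)
        record("signature", cluster_a=a, cluster_b=b,
               n_common=len(sig.common_genes))

    # ---- cell table ---------------------------------------------------
    table = pd.DataFrame(
        {
            "barcode": cm.barcodes,
            "n_genes": metrics.n_genes,
            "n_umi": metrics.n_umi,
            "pct_mito": metrics.pct_mito,
            "phase": phases,
            "cluster": labels,
            "qc_pass": True,
            "conflict_flag": flagged,
        }
    )
    write_cell_table(table, out / "cell_table.tsv")
    log.info("pipeline finished %s", time.strftime("%Y-%m-%dT%H:%M:%S"))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
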