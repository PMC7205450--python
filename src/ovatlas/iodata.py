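"""Data model and I/O for count matrices, marker panels, and cell tables.

The on-disk formats follow the 10x Genomics conventions: a MatrixMarket
triplet file with 1-based indices plus ``barcodes.tsv`` and
``features.tsv`` sidecars (v2 dialect: id, symbol, type columns).
Matrices are held cells x genes internally regardless of the on-disk
orientation. Marker panels and per-cell result tables are plain TSV.
All text inputs may optionally be gzip-compressed.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Malformed input file (bad header, dimension mismatch, wrong dtype)."""


class ValidationError(ValueError):
    """Structurally valid input violating a semantic contract."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI count matrix with cell/gene annotations.

    Attributes
    ----------
    counts
        CSR matrix of non-negative integer UMI counts, one row per cell.
    barcodes
        Unique cell identifiers, one per row.
    gene_ids
        Unique stable gene identifiers, one per column. Gene identity is
        keyed on these; symbols are for display only.
    gene_symbols
        Display names, aligned with ``gene_ids``.
    mito_flags
        Boolean per gene marking mitochondrial genes.
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    gene_ids: list[str]
    gene_symbols: list[str]
    mito_flags: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        n_cells, n_genes = self.counts.shape
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.mito_flags) != n_genes:
            raise FormatError("mito_flags length does not match gene count")
        if len(set(self.barcodes)) != n_cells:
            raise ValidationError("duplicate barcodes")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entries")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx],
            barcodes=[self.barcodes[i] for i in idx],
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            mito_flags=self.mito_flags.copy(),
        )

    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[:, idx].tocsr(),
            barcodes=list(self.barcodes),
            gene_ids=[self.gene_ids[i] for i in idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
            mito_flags=self.mito_flags[idx],
        )


@dataclass
class MarkerPanel:
    """Curated (gene, cell type, conflict group) table.

    Cell types in different conflict groups are declared "distantly
    related": co-expression of their markers in one cell marks a
    suspected doublet. Types sharing a group (e.g. neighbouring states
    on one developmental trajectory) are exempt from conflict, which
    preserves genuine intermediary cell states.
    """

    entries: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for gene, cell_type, group in self.entries:
            if not gene or not cell_type or not group:
                raise ValidationError("panel row with blank field")

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, ct, _ in self.entries:
            seen.setdefault(ct)
        return list(seen)

    @property
    def groups(self) -> dict[str, str]:
        """cell type -> conflict group (first declaration wins)."""
        out: dict[str, str] = {}
        for _, ct, grp in self.entries:
            out.setdefault(ct, grp)
        return out

    def genes_for(self, cell_type: str) -> list[str]:
        return [g for g, ct, _ in self.entries if ct == cell_type]

    @property
    def conflict_pairs(self) -> set[frozenset[str]]:
        """Unordered pairs of cell types in different conflict groups."""
        groups = self.groups
        types = list(groups)
        pairs: set[frozenset[str]] = set()
        for i, a in enumerate(types):
            for b in types[i + 1 :]:
                if groups[a] != groups[b]:
                    pairs.add(frozenset((a, b)))
        return pairs


CELL_TABLE_COLUMNS = [
    "barcode",
    "n_genes",
    "n_umi",
    "pct_mito",
    "phase",
    "cluster",
    "pseudotime",
    "branch",
    "qc_pass",
    "conflict_flag",
]


def read_mtx_triplet(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    mito_prefix: str = "mt:",
) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet with barcode/feature sidecars.

    Orientation is normalized to cells x genes: whichever matrix axis
    matches the barcode file length becomes the row axis (features take
    the other). Mitochondrial genes are flagged by symbol prefix
    (FlyBase convention ``mt:``).
    """
    with _open_text(matrix_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
        except Exception as exc:  # noqa: BLE001 - normalize scipy errors
            raise FormatError(f"invalid MatrixMarket file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError("non-integer entries in count matrix")

    with _open_text(barcodes_path) as fh:
        barcodes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    features: list[tuple[str, str]] = []
    with _open_text(features_path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            gid = parts[0]
            symbol = parts[1] if len(parts) > 1 else parts[0]
            features.append((gid, symbol))

    nb, nf = len(barcodes), len(features)
    if mat.shape == (nb, nf):
        counts = mat.tocsr()
    elif mat.shape == (nf, nb):
        counts = mat.T.tocsr()
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {nb} barcodes x "
            f"{nf} features nor its transpose"
        )
    gene_ids = [gid for gid, _ in features]
    gene_symbols = [sym for _, sym in features]
    mito = np.array([s.startswith(mito_prefix) for s in gene_symbols], dtype=bool)
    return CountMatrix(
        counts=counts.astype(np.int64),
        barcodes=barcodes,
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        mito_flags=mito,
    )


def write_mtx_triplet(cm: CountMatrix, out_dir: str | Path) -> None:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", cm.counts.tocoo(), field="integer")
    (out / "barcodes.tsv").write_text("".join(b + "\n" for b in cm.barcodes))
    with open(out / "features.tsv", "w") as fh:
        for gid, sym in zip(cm.gene_ids, cm.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")


_PANEL_COLUMNS = ["gene", "cell_type", "conflict_group"]


def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Read a marker panel TSV with header gene / cell_type / conflict_group."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if df.empty and len(df.columns) == 0:
        raise ValidationError("empty marker panel file")
    if list(df.columns) != _PANEL_COLUMNS:
        raise FormatError(
            f"expected columns {_PANEL_COLUMNS}, found {list(df.columns)}"
        )
    if df.isna().any().any() or (df.map(lambda v: str(v).strip() == "")).any().any():
        raise ValidationError("marker panel row with blank field")
    entries = [tuple(row) for row in df.itertuples(index=False)]
    if not entries:
        raise ValidationError("marker panel has no rows")
    return MarkerPanel(entries=entries)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.entries, columns=_PANEL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell result table as TSV with fixed column order.

    Missing columns are filled with NA so the on-disk schema is stable;
    ``read_cell_table`` round-trips the result losslessly.
    """
    if "barcode" not in table.columns:
        raise ValidationError("cell table requires a barcode column")
    if table["barcode"].duplicated().any():
        raise ValidationError("duplicate barcodes in cell table")
    out = table.copy()
    for col in CELL_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out = out[CELL_TABLE_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(
            fh,
            sep="\t",
            na_values=["NA"],
            keep_default_na=False,
            dtype={"barcode": str, "phase": str, "branch": str},
        )
    if list(df.columns) != CELL_TABLE_COLUMNS:
        raise FormatError(f"unexpected cell table columns: {list(df.columns)}")
    if not df.empty and df["pct_mito"].notna().any():
        vals = df["pct_mito"].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError("pct_mito outside [0, 100]")
    return df
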