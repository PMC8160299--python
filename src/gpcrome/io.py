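"""Reading and writing expression data.

Bulk matrices travel as delimited text (genes in rows, samples in columns;
TSV or CSV picked by extension), sample metadata as a TSV table, and
single-cell data as a CellRanger-style triplet directory: ``matrix.mtx``
(Matrix Market coordinate, cells as columns), ``features.tsv``,
``barcodes.tsv``, ``clusters.tsv`` and an optional ``embedding.tsv``.
Everything is validated on read; writes are deterministic (fixed order,
``%.6g`` floats, UTF-8, LF endings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("gpcrome")

UNITS = ("FPKM", "TPM", "count")
REGIONS = ("WM", "GM", "whole", "other")
CONDITIONS = ("control", "MS", "other")


class ValidationError(ValueError):
    """Input data violates a format or invariant contract."""


# ---------------------------------------------------------------------------
# Bulk expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression matrix with dataset identity.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns.
    """

    values: pd.DataFrame
    unit: str
    species: str
    dataset_id: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValidationError(
                f"empty expression matrix for dataset {self.dataset_id!r} "
                f"(shape {self.values.shape})"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene_ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.unit == "TPM":
            sums = arr.sum(axis=0)
            off = np.abs(sums - 1e6) > 1e4
            if off.any():
                logger.warning(
                    "dataset %s: %d/%d TPM columns deviate >1%% from 1e6 "
                    "(filtered matrix?)",
                    self.dataset_id, int(off.sum()), len(sums),
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_bulk_matrix(
    path: str | Path,
    unit: str,
    species: str,
    dataset_id: str,
    id_map: Optional[str | Path] = None,
) -> ExpressionMatrix:
    """Read a genes x samples delimited matrix.

    First column holds gene symbols, header row sample ids; TSV or CSV by
    extension. Duplicate gene rows are collapsed by summation with a logged
    warning. ``id_map`` optionally names a two-column file translating row
    identifiers to symbols before validation.
    """
    path = Path(path)
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment=None, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = num.isna() & df.notna()
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[g, s]!r} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        ) from None
    if values.isna().any().any():
        bad = values.isna().to_numpy()
        g, s = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: missing value at gene {values.index[g]!r}, "
            f"sample {values.columns[s]!r}"
        )
    values.index = values.index.astype(str).str.strip()
    if id_map is not None:
        mapping = pd.read_csv(
            Path(id_map), sep=_sep_for(Path(id_map)), header=None, dtype=str
        ).set_index(0)[1]
        values.index = [mapping.get(g, g) for g in values.index]
        values.index = pd.Index(values.index, name=df.index.name)
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.warning(
            "%s: collapsed %d duplicate gene rows by summation", path, n_dup
        )
        # stable: keep first-appearance order of each symbol
        order = values.index.drop_duplicates()
        values = values.groupby(level=0, sort=False).sum().loc[order]
    return ExpressionMatrix(
        values=values.astype(float), unit=unit, species=species, dataset_id=dataset_id
    )


def write_bulk_matrix(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a matrix as delimited text, deterministically.

    Column order follows the matrix; floats use ``%.6g``; two writes of the
    same matrix are byte-identical.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene" + sep + sep.join(map(str, matrix.sample_ids)) + "\n")
        arr = matrix.values.to_numpy()
        for gene, row in zip(matrix.gene_ids, arr):
            fh.write(str(gene) + sep + sep.join("%.6g" % v for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-sample metadata: donor, brain region (WM/GM), condition, species."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "donor_id", "region", "condition", "species")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[
                self.table["sample_id"].duplicated(), "sample_id"
            ].tolist()
            raise ValidationError(f"duplicate sample_ids: {dups}")
        bad_region = set(self.table["region"]) - set(REGIONS)
        if bad_region:
            raise ValidationError(f"unknown region labels: {sorted(bad_region)}")
        bad_cond = set(self.table["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition labels: {sorted(bad_cond)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, **criteria) -> "SampleTable":
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            mask &= self.table[col] == val
        return SampleTable(self.table[mask].reset_index(drop=True))


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)), dtype=str)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    samples.table.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Single-cell datasets
# ---------------------------------------------------------------------------

@dataclass
class SingleCellDataset:
    """Cells x genes integer count matrix with cluster labels.

    ``counts`` is CSR, cells in rows (the on-disk Matrix Market file stores
    cells as columns, CellRanger-style; the reader transposes). ``embedding``
    is an optional cells x 2 array of precomputed 2-D coordinates — embeddings
    are inputs here, never computed.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_labels: np.ndarray
    embedding: Optional[np.ndarray] = None
    dataset_id: str = "sc"

    def __post_init__(self) -> None:
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"count matrix has {n_genes} genes but {len(self.gene_ids)} feature ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"count matrix has {n_cells} cells but {len(self.cell_ids)} barcodes"
            )
        if len(self.cluster_labels) != n_cells:
            raise ValidationError(
                f"{len(self.cluster_labels)} cluster labels for {n_cells} cells"
            )
        data = self.counts.data
        if data.size and (np.mod(data, 1) != 0).any():
            bad = data[np.mod(data, 1) != 0][0]
            raise ValidationError(f"non-integer count {bad!r} in matrix")
        if data.size and (data < 0).any():
            raise ValidationError("negative counts in matrix")
        if self.embedding is not None:
            emb = np.asarray(self.embedding, dtype=float)
            if emb.shape != (n_cells, 2):
                raise ValidationError(
                    f"embedding shape {emb.shape} != ({n_cells}, 2)"
                )
            self.embedding = emb
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in features")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell barcodes")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def clusters(self) -> list[str]:
        return sorted(set(map(str, self.cluster_labels)))


def read_single_cell(dir_path: str | Path, dataset_id: str = "sc") -> SingleCellDataset:
    """Read a triplet directory (matrix.mtx + features/barcodes/clusters.tsv).

    ``matrix.mtx`` stores genes x cells (cells as columns); ``clusters.tsv``
    maps every barcode to a cluster label. Cells missing a label are an error
    listing the barcodes; a dimension mismatch between the matrix header and
    the sidecar files is an error.
    """
    d = Path(dir_path)
    mtx_path = d / "matrix.mtx"
    for required in ("matrix.mtx", "features.tsv", "barcodes.tsv", "clusters.tsv"):
        if not (d / required).exists():
            raise ValidationError(f"{d}: missing {required}")
    mat = scipy.io.mmread(mtx_path)  # genes x cells on disk
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(genes), len(barcodes)):
        raise ValidationError(
            f"{mtx_path}: matrix is {mat.shape} but sidecars declare "
            f"{len(genes)} features x {len(barcodes)} barcodes"
        )
    clusters = pd.read_csv(d / "clusters.tsv", sep="\t", header=None, dtype=str)
    cluster_map = dict(zip(clusters[0], clusters[1]))
    unlabeled = [b for b in barcodes if b not in cluster_map]
    if unlabeled:
        raise ValidationError(
            f"{d}: barcodes without cluster label: {unlabeled[:10]}"
        )
    labels = np.array([cluster_map[b] for b in barcodes], dtype=object)
    embedding = None
    emb_path = d / "embedding.tsv"
    if emb_path.exists():
        emb_df = pd.read_csv(emb_path, sep="\t", header=None, dtype=str).set_index(0)
        missing = [b for b in barcodes if b not in emb_df.index]
        if missing:
            raise ValidationError(f"{emb_path}: barcodes missing coordinates: {missing[:10]}")
        embedding = emb_df.loc[barcodes, [1, 2]].astype(float).to_numpy()
    counts = sp.csr_matrix(mat.T)  # cells x genes in memory
    return SingleCellDataset(
        counts=counts,
        gene_ids=genes,
        cell_ids=barcodes,
        cluster_labels=labels,
        embedding=embedding,
        dataset_id=dataset_id,
    )


def write_single_cell(dataset: SingleCellDataset, dir_path: str | Path) -> Path:
    """Write the triplet directory; deterministic byte-for-byte."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(dataset.counts.T)  # genes x cells on disk
    with open(d / "matrix.mtx", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        order = np.lexsort((coo.row, coo.col))
        for i in order:
            fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {int(coo.data[i])}\n")
    with open(d / "features.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.writelines(f"{g}\n" for g in dataset.gene_ids)
    with open(d / "barcodes.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.writelines(f"{b}\n" for b in dataset.cell_ids)
    with open(d / "clusters.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.writelines(
            f"{b}\t{c}\n" for b, c in zip(dataset.cell_ids, dataset.cluster_labels)
        )
    if dataset.embedding is not None:
        with open(d / "embedding.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.writelines(
                f"{b}\t{x:.6g}\t{y:.6g}\n"
                for b, (x, y) in zip(dataset.cell_ids, dataset.embedding)
            )
    return d
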