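"""Per-cluster gene-panel summaries and disease-vs-homeostatic contrasts.

Counts are depth-normalized to 10,000 per cell and log(1 + x)-transformed.
Cluster summaries report, per (cluster, gene), the mean normalized expression
and the fraction of cells expressing the gene (count > 0) — the quantities
behind expression-overlay figures. Cluster contrasts test each panel gene
between two clusters with a Mann-Whitney U test across cells, adjust with
Benjamini-Hochberg across the panel, and call a direction when both the
fold change of cluster means (computed on the linear, depth-normalized
scale, so it tracks the underlying count fold change) and the q-value clear
their thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .differential import bh_adjust, fold_change, mann_whitney_u
from .io import SingleCellDataset, ValidationError

logger = logging.getLogger("gpcrome")

TARGET_DEPTH = 10_000.0


def normalize_counts(
    dataset: SingleCellDataset, log: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Depth-normalize to 10k counts per cell, then log1p.

    Returns ``(normalized, kept)`` where ``normalized`` is a dense cells x
    genes DataFrame (cell ids x gene ids) over the kept cells, and ``kept``
    is a boolean mask over the original cells — cells with zero total counts
    are excluded with a warning. ``log=False`` skips the log1p (the linear
    CP10k scale used for fold changes).
    """
    totals = np.asarray(dataset.counts.sum(axis=1)).ravel()
    kept = totals > 0
    if not kept.any():
        raise ValidationError("all cells have zero total counts")
    if (~kept).sum():
        logger.warning("excluding %d zero-count cells", int((~kept).sum()))
    counts = dataset.counts[kept].astype(float)
    scale = TARGET_DEPTH / totals[kept]
    cp10k = sp.diags(scale) @ counts
    dense = np.asarray(cp10k.todense())
    if log:
        dense = np.log1p(dense)
    cell_ids = [c for c, k in zip(dataset.cell_ids, kept) if k]
    return (
        pd.DataFrame(dense, index=cell_ids, columns=dataset.gene_ids),
        kept,
    )


@dataclass
class ClusterSummary:
    """Per (cluster, gene) expression summary.

    ``table`` has a (cluster, gene) MultiIndex with columns
    ``mean_normalized_expression``, ``fraction_expressing`` and ``n_cells``.
    """

    table: pd.DataFrame
    dataset_id: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def _panel_in_dataset(gene_panel: Sequence[str], dataset: SingleCellDataset) -> list[str]:
    present = [g for g in gene_panel if g in dataset.gene_ids]
    missing = [g for g in gene_panel if g not in dataset.gene_ids]
    if missing:
        logger.warning("panel genes absent from dataset: %s", missing)
    if not present:
        raise ValidationError("no panel gene present in the dataset")
    return present


def cluster_summary(
    dataset: SingleCellDataset, gene_panel: Sequence[str]
) -> ClusterSummary:
    """Mean normalized expression and fraction expressing per cluster.

    Missing panel genes are reported (warning), not fatal; an empty cluster
    is an error. Invariant to cell ordering and cluster renaming.
    """
    panel = _panel_in_dataset(gene_panel, dataset)
    norm, kept = normalize_counts(dataset)
    labels = np.asarray(dataset.cluster_labels, dtype=object)[kept]
    raw = np.asarray(dataset.counts[kept][:, [dataset.gene_ids.index(g) for g in panel]].todense())
    rows = []
    for cluster in sorted(set(map(str, labels))):
        mask = labels.astype(str) == cluster
        n_cells = int(mask.sum())
        if n_cells == 0:
            raise ValidationError(f"cluster {cluster!r} is empty")
        sub_norm = norm[mask]
        for j, gene in enumerate(panel):
            rows.append(
                (
                    cluster,
                    gene,
                    float(sub_norm[gene].mean()),
                    float((raw[mask, j] > 0).mean()),
                    n_cells,
                )
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster", "gene", "mean_normalized_expression",
            "fraction_expressing", "n_cells",
        ],
    ).set_index(["cluster", "gene"])
    return ClusterSummary(table=table, dataset_id=dataset.dataset_id)


@dataclass
class ClusterContrast:
    """Per-gene contrast of cluster A vs cluster B.

    direction is up_in_A / down_in_A / none; none exactly when
    |log2FC| < threshold or q >= alpha.
    """

    table: pd.DataFrame
    cluster_a: str
    cluster_b: str
    fc_threshold: float
    alpha: float

    @property
    def up_in_a(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "up_in_A"])

    @property
    def down_in_a(self) -> list[str]:
        return list(self.table.index[self.table["direction"] == "down_in_A"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def contrast_clusters(
    dataset: SingleCellDataset,
    cluster_a: str,
    cluster_b: str,
    gene_panel: Sequence[str],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> ClusterContrast:
    """Contrast two labeled clusters over a gene panel.

    Per gene: Mann-Whitney U across the cells of the two clusters on the
    normalized values, BH adjustment across the panel, log2 fold change of
    the linear CP10k cluster means, and a direction call requiring
    |log2FC| >= log2(fc_threshold) and q < alpha.
    """
    labels = set(map(str, dataset.cluster_labels))
    for cl in (cluster_a, cluster_b):
        if cl not in labels:
            raise ValidationError(f"cluster label {cl!r} absent from dataset")
    panel = _panel_in_dataset(gene_panel, dataset)
    log_norm, kept = normalize_counts(dataset, log=True)
    lin_norm, _ = normalize_counts(dataset, log=False)
    cell_labels = np.asarray(dataset.cluster_labels, dtype=object)[kept].astype(str)
    mask_a = cell_labels == cluster_a
    mask_b = cell_labels == cluster_b
    if not mask_a.any() or not mask_b.any():
        raise ValidationError("both clusters must contain cells with nonzero depth")

    lin_eps_pool = lin_norm[panel].to_numpy()
    nonzero = lin_eps_pool[lin_eps_pool > 0]
    eps = nonzero.min() / 2.0 if nonzero.size else 1.0

    rows = []
    for gene in panel:
        a_vals = log_norm.loc[mask_a, gene].to_numpy()
        b_vals = log_norm.loc[mask_b, gene].to_numpy()
        res = mann_whitney_u(a_vals, b_vals)
        mean_a = float(lin_norm.loc[mask_a, gene].mean())
        mean_b = float(lin_norm.loc[mask_b, gene].mean())
        rows.append((gene, mean_a, mean_b, fold_change(mean_a, mean_b, eps), res.p_value))
    table = pd.DataFrame(
        rows, columns=["gene", "mean_A", "mean_B", "log2_fold_change", "p"]
    ).set_index("gene")
    table["q"] = bh_adjust(table["p"].to_numpy())
    log2_thresh = np.log2(fc_threshold)
    significant = table["q"] < alpha
    table["direction"] = np.where(
        significant & (table["log2_fold_change"] >= log2_thresh), "up_in_A",
        np.where(
            significant & (table["log2_fold_change"] <= -log2_thresh),
            "down_in_A", "none",
        ),
    )
    return ClusterContrast(
        table=table, cluster_a=cluster_a, cluster_b=cluster_b,
        fc_threshold=fc_threshold, alpha=alpha,
    )


def embedding_overlay_table(dataset: SingleCellDataset, gene: str) -> pd.DataFrame:
    """Per-cell (x, y, normalized value, cluster) table for overlay plots.

    The embedding is an input (precomputed elsewhere); this only joins it
    with normalized expression of one gene. Cells with zero depth carry a
    normalized value of 0 so the row count equals the dataset cell count.
    """
    if dataset.embedding is None:
        raise ValidationError(
            "dataset has no embedding; 2-D embeddings are inputs, not computed here"
        )
    if gene not in dataset.gene_ids:
        raise ValidationError(f"gene {gene!r} absent from dataset")
    norm, kept = normalize_counts(dataset)
    values = np.zeros(dataset.n_cells)
    values[kept] = norm[gene].to_numpy()
    return pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "x": dataset.embedding[:, 0],
            "y": dataset.embedding[:, 1],
            "normalized_expression": values,
            "cluster": [str(c) for c in dataset.cluster_labels],
        }
    ).set_index("cell_id")
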