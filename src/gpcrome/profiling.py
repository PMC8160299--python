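"""Whole-transcriptome percentile profiling and expression tiers.

A gene's expression level is summarized not in absolute units but as its
percentile rank among all genes of the dataset: percentile = midrank / N,
where ties receive midranks, so the top gene sits at exactly 1.0 and the
"top 50%" corresponds to percentiles >= 0.50. Percentiles are then binned
into tiers: below_cutoff (< 0.50), low (0.50-0.67), medium (0.68-0.85) and
high (0.86-1.0). The boundary values are treated as half-open intervals at
0.50 / 0.68 / 0.86 on unrounded percentiles, reading the published two-
decimal band edges as rounding of continuous boundaries.

Because the statistic is a rank, profiles are invariant under any strictly
increasing transform of the expression values, so FPKM, TPM and gene counts
are directly comparable on the percentile scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, ValidationError
from .registry import GeneSetCatalog, map_ortholog


class Tier(enum.IntEnum):
    """Ordered expression tiers; order supports >= comparisons."""

    below_cutoff = 0
    low = 1
    medium = 2
    high = 3

    def __str__(self) -> str:  # pragma: no cover - display only
        return self.name


@dataclass(frozen=True)
class TierScheme:
    """Percentile boundaries of the tier bins.

    ``cutoff`` is the inclusion threshold (top 50% by default); ``low_upper``
    and ``medium_upper`` are the continuous boundaries whose two-decimal
    roundings give the published low/medium/high bands.
    """

    cutoff: float = 0.50
    low_upper: float = 0.68
    medium_upper: float = 0.86

    def __post_init__(self) -> None:
        if not (0 < self.cutoff < self.low_upper < self.medium_upper <= 1):
            raise ValidationError(
                f"tier boundaries must satisfy 0 < cutoff < low_upper < "
                f"medium_upper <= 1; got ({self.cutoff}, {self.low_upper}, "
                f"{self.medium_upper})"
            )


DEFAULT_SCHEME = TierScheme()


def assign_tier(percentile: float, scheme: TierScheme = DEFAULT_SCHEME) -> Tier:
    """Tier of a percentile in (0, 1]; half-open bins, top bin closed at 1."""
    if not (0 < percentile <= 1):
        raise ValidationError(f"percentile {percentile!r} outside (0, 1]")
    if percentile < scheme.cutoff:
        return Tier.below_cutoff
    if percentile < scheme.low_upper:
        return Tier.low
    if percentile < scheme.medium_upper:
        return Tier.medium
    return Tier.high


@dataclass
class PercentileProfile:
    """Per-gene whole-transcriptome percentiles for one dataset.

    ``table`` is indexed by gene with columns ``mean_expression``, ``midrank``
    (1..N scale), ``percentile`` and ``tier``. ``region`` carries an optional
    WM/GM label used by the consensus rescue rule.
    """

    dataset_id: str
    species: str
    table: pd.DataFrame
    scheme: TierScheme = field(default_factory=TierScheme)
    region: Optional[str] = None
    aggregation: str = "mean_then_rank"

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def percentile(self, gene: str) -> float:
        return float(self.table.loc[gene, "percentile"])

    def tier(self, gene: str) -> Tier:
        return Tier(int(self.table.loc[gene, "tier"]))

    def to_tsv(self, path) -> None:
        """Write the profile with a parseable metadata header (round-trips
        via :func:`read_profile_tsv`)."""
        out = self.table.copy()
        out["tier"] = [Tier(int(t)).name for t in out["tier"]]
        out.index.name = "gene"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(
                f"# dataset_id={self.dataset_id}\tspecies={self.species}"
                f"\tregion={self.region or ''}\taggregation={self.aggregation}\n"
            )
            fh.write(
                f"# scheme={self.scheme.cutoff},{self.scheme.low_upper},"
                f"{self.scheme.medium_upper}\n"
            )
            out.to_csv(fh, sep="\t", float_format="%.10g", lineterminator="\n")


def read_profile_tsv(path) -> PercentileProfile:
    """Read a profile written by :meth:`PercentileProfile.to_tsv`."""
    meta: dict[str, str] = {}
    scheme = TierScheme()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("scheme="):
                c, lo, mid = body.split("=", 1)[1].split(",")
                scheme = TierScheme(float(c), float(lo), float(mid))
            else:
                for item in body.split("\t"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        meta[k] = v
    table = pd.read_csv(path, sep="\t", comment="#", index_col="gene")
    table["tier"] = [int(Tier[t]) for t in table["tier"]]
    return PercentileProfile(
        dataset_id=meta.get("dataset_id", "unknown"),
        species=meta.get("species", "human"),
        table=table,
        scheme=scheme,
        region=meta.get("region") or None,
        aggregation=meta.get("aggregation", "mean_then_rank"),
    )


def gene_percentiles(
    matrix: ExpressionMatrix,
    aggregation: str = "mean_then_rank",
    scheme: TierScheme = DEFAULT_SCHEME,
    region: Optional[str] = None,
) -> PercentileProfile:
    """Percentile-rank every gene of a dataset against the whole matrix.

    ``mean_then_rank`` (default): average each gene across samples, midrank
    the N means, percentile = midrank / N. ``rank_then_mean``: compute
    per-sample percentiles (midrank / N within each sample) and average them
    per gene. The gene universe N is the full matrix, zero-expression genes
    included. A single-gene matrix is an error — a percentile needs a
    background.
    """
    if matrix.n_genes < 2:
        raise ValidationError(
            "percentile profile undefined for a single-gene matrix"
        )
    if aggregation not in ("mean_then_rank", "rank_then_mean"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    arr = matrix.values.to_numpy(dtype=float)
    n = arr.shape[0]
    means = arr.mean(axis=1)
    if aggregation == "mean_then_rank":
        midrank = rankdata(means, method="average")
        percentile = midrank / n
    else:
        per_sample = rankdata(arr, method="average", axis=0) / n
        percentile = per_sample.mean(axis=1)
        midrank = percentile * n
    tiers = np.array([assign_tier(p, scheme) for p in percentile], dtype=int)
    table = pd.DataFrame(
        {
            "mean_expression": means,
            "midrank": midrank,
            "percentile": percentile,
            "tier": tiers,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return PercentileProfile(
        dataset_id=matrix.dataset_id,
        species=matrix.species,
        table=table,
        scheme=scheme,
        region=region,
        aggregation=aggregation,
    )


def species_union_filter(
    profile_a: PercentileProfile,
    profile_b: PercentileProfile,
    catalog: GeneSetCatalog,
    cutoff: float = 0.50,
) -> pd.DataFrame:
    """Catalog GPCR genes above ``cutoff`` in at least one of two species.

    Implements the human-and/or-mouse union rule: a gene is kept when its
    percentile reaches ``cutoff`` in either species' profile. Genes present
    in only one species' catalog (no ortholog) are evaluated on that species
    alone and flagged ``species_specific``. Rows are indexed by the species-A
    symbol (or the species-B symbol for B-only genes) with per-species
    percentiles attached.
    """
    if profile_a.species == profile_b.species:
        raise ValidationError(
            f"union filter needs two species, got {profile_a.species} twice"
        )
    sp_a, sp_b = profile_a.species, profile_b.species

    def pct(profile: PercentileProfile, gene: Optional[str]) -> float:
        if gene is None or gene not in profile.table.index:
            return np.nan
        return float(profile.table.loc[gene, "percentile"])

    rows = []
    seen_b: set[str] = set()
    for sym_a in catalog.genes(sp_a, "gpcr"):
        sym_b = map_ortholog(sym_a, sp_a, sp_b, catalog)
        if sym_b is not None:
            seen_b.add(sym_b)
        rows.append((sym_a, sym_b, pct(profile_a, sym_a), pct(profile_b, sym_b)))
    for sym_b in catalog.genes(sp_b, "gpcr"):
        if sym_b in seen_b:
            continue
        rows.append((sym_b, sym_b, np.nan, pct(profile_b, sym_b)))

    df = pd.DataFrame(
        rows, columns=["gene", f"symbol_{sp_b}", f"percentile_{sp_a}", f"percentile_{sp_b}"]
    ).set_index("gene")
    df["species_specific"] = (
        df[f"percentile_{sp_a}"].isna() | df[f"percentile_{sp_b}"].isna()
    )
    keep = (
        (df[f"percentile_{sp_a}"] >= cutoff).fillna(False)
        | (df[f"percentile_{sp_b}"] >= cutoff).fillna(False)
    )
    return df[keep]


def relative_intensity(
    matrix: ExpressionMatrix, pseudocount: Optional[float] = None
) -> pd.DataFrame:
    """Heatmap intensities relative to the per-sample all-gene mean.

    r(g, s) = log2((x(g, s) + eps) / (mu(s) + eps)) with mu(s) the mean over
    all genes in sample s; eps defaults to half the smallest nonzero value of
    the matrix. Zero is "average expression", positive red-ward, negative
    white-ward. Within a sample the ordering of r equals the ordering of x.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if not (arr > 0).any():
        raise ValidationError("relative intensity undefined for an all-zero matrix")
    if pseudocount is None:
        pseudocount = arr[arr > 0].min() / 2.0
    mu = arr.mean(axis=0)
    rel = np.log2((arr + pseudocount) / (mu + pseudocount))
    return pd.DataFrame(rel, index=matrix.values.index, columns=matrix.values.columns)
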