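"""End-to-end pipeline runs and assembled reports.

``run_paper_mirror`` executes the whole analysis on the shipped synthetic
scenario — profile five bulk datasets, derive the consensus core set with
the WM rescue rule, run the paired WM/GM differential screen, contrast the
disease-associated against the homeostatic single-cell cluster — and returns
every stage result together with the generator truth tables.

``assemble_report`` turns a directory of stage outputs into a single
markdown summary (the artifact's analogue of a tabular core-signature
overview) with the stage TSVs as appendices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .consensus import ConsensusConfig, ConsensusResult, derive_core_set
from .differential import RegionDiffResult, region_differential
from .io import SingleCellDataset, ValidationError, write_bulk_matrix, write_sample_table
from .profiling import PercentileProfile, gene_percentiles
from .registry import GeneSetCatalog, load_catalog
from .simulate import (
    TruthTable,
    build_paper_mirror_bulk,
    build_paper_mirror_region,
    build_paper_mirror_sc,
    load_scenario,
    simulate_bulk,
    simulate_paired_regions,
    simulate_single_cell,
)
from .singlecell import ClusterContrast, ClusterSummary, cluster_summary, contrast_clusters


@dataclass
class PaperMirrorRun:
    """All stage results of one paper-mirror pipeline run."""

    profiles: list[PercentileProfile]
    gm_profile: PercentileProfile
    wm_profile: PercentileProfile
    consensus: ConsensusResult
    region: RegionDiffResult
    sc_dataset: SingleCellDataset
    sc_summary: ClusterSummary
    sc_contrast: ClusterContrast
    truth: dict[str, TruthTable]
    catalog: GeneSetCatalog
    scenario: dict
    seed: int

    @property
    def core_set(self) -> list[str]:
        return self.consensus.members

    @property
    def planted_core(self) -> list[str]:
        return list(self.scenario["core_genes"]) + list(self.scenario["rescue_genes"])


def run_paper_mirror(
    seed: int,
    scenario: Optional[dict] = None,
    catalog: Optional[GeneSetCatalog] = None,
    config: Optional[ConsensusConfig] = None,
    include_single_cell: bool = True,
) -> PaperMirrorRun:
    """Run the full pipeline on the synthetic paper-mirror scenario."""
    scenario = scenario or load_scenario()
    catalog = catalog or load_catalog()
    config = config or ConsensusConfig()
    gpcr_genes = catalog.genes(scenario.get("species", "human"), "gpcr")

    truth: dict[str, TruthTable] = {}
    profiles: list[PercentileProfile] = []
    gm_profile = wm_profile = None
    for spec, region in build_paper_mirror_bulk(scenario, gpcr_genes, seed):
        matrix, t = simulate_bulk(spec)
        truth[spec.dataset_id] = t
        profile = gene_percentiles(matrix, region=region)
        profiles.append(profile)
        if region == "GM":
            gm_profile = profile
        elif region == "WM":
            wm_profile = profile
    assert gm_profile is not None and wm_profile is not None
    consensus = derive_core_set(
        profiles, catalog, config, gm_profile=gm_profile, wm_profile=wm_profile
    )

    region_spec = build_paper_mirror_region(scenario, gpcr_genes, seed)
    matrix, samples, region_truth = simulate_paired_regions(region_spec)
    truth["region_pair"] = region_truth
    region = region_differential(
        matrix, samples, genes=gpcr_genes,
        fc_threshold=float(scenario["contrast"]["fc_threshold"]), paired=True,
    )

    if include_single_cell:
        sc_spec = build_paper_mirror_sc(scenario, gpcr_genes, seed)
        sc_dataset, sc_truth = simulate_single_cell(sc_spec)
        truth["single_cell"] = sc_truth
        panel = [g for g in gpcr_genes if g in sc_dataset.gene_ids]
        summary = cluster_summary(sc_dataset, panel)
        contrast = contrast_clusters(
            sc_dataset, "disease", "homeostatic", panel,
            fc_threshold=float(scenario["contrast"]["fc_threshold"]),
            alpha=float(scenario["contrast"]["alpha"]),
        )
    else:  # bulk-only runs (cheaper) still return placeholders
        sc_dataset = None  # type: ignore[assignment]
        summary = None  # type: ignore[assignment]
        contrast = None  # type: ignore[assignment]

    return PaperMirrorRun(
        profiles=profiles,
        gm_profile=gm_profile,
        wm_profile=wm_profile,
        consensus=consensus,
        region=region,
        sc_dataset=sc_dataset,
        sc_summary=summary,
        sc_contrast=contrast,
        truth=truth,
        catalog=catalog,
        scenario=scenario,
        seed=seed,
    )


def write_run_outputs(run: PaperMirrorRun, out_dir: str | Path) -> Path:
    """Write every stage output of a run into a directory tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for profile in run.profiles:
        profile.to_tsv(out / f"profile_{profile.dataset_id}.tsv")
    run.consensus.to_tsv(out / "consensus_tiers.tsv")
    (out / "consensus_summary.json").write_text(
        run.consensus.summary_json() + "\n", encoding="utf-8"
    )
    run.region.to_tsv(out / "region_diff.tsv")
    (out / "region_config.json").write_text(
        json.dumps(
            {
                "fc_threshold": run.region.fc_threshold,
                "paired": run.region.paired,
                "pseudocount": run.region.pseudocount,
            },
            indent=2,
        ) + "\n",
        encoding="utf-8",
    )
    if run.sc_contrast is not None:
        run.sc_summary.to_tsv(out / "sc_cluster_summary.tsv")
        run.sc_contrast.to_tsv(out / "sc_contrast.tsv")
    truth_dir = out / "truth"
    for name, table in run.truth.items():
        table.to_dir(truth_dir / name)
    return out


def simulate_to_dir(scenario: dict, seed: int, out_dir: str | Path,
                    catalog: Optional[GeneSetCatalog] = None) -> Path:
    """Write the raw synthetic datasets of a scenario (no analysis)."""
    from .io import write_single_cell

    catalog = catalog or load_catalog()
    gpcr_genes = catalog.genes(scenario.get("species", "human"), "gpcr")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for spec, _region in build_paper_mirror_bulk(scenario, gpcr_genes, seed):
        matrix, truth = simulate_bulk(spec)
        write_bulk_matrix(matrix, out / f"{spec.dataset_id}.tsv")
        truth.to_dir(out / "truth" / spec.dataset_id)
    region_spec = build_paper_mirror_region(scenario, gpcr_genes, seed)
    matrix, samples, truth = simulate_paired_regions(region_spec)
    write_bulk_matrix(matrix, out / "region_pair.tsv")
    write_sample_table(samples, out / "region_pair_samples.tsv")
    truth.to_dir(out / "truth" / "region_pair")
    sc_spec = build_paper_mirror_sc(scenario, gpcr_genes, seed)
    dataset, truth = simulate_single_cell(sc_spec)
    write_single_cell(dataset, out / "single_cell")
    truth.to_dir(out / "truth" / "single_cell")
    return out


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def assemble_report(out_dir: str | Path) -> Path:
    """Assemble ``report.md`` from the stage outputs in a run directory.

    At least one stage output (consensus tiers, regional screen, single-cell
    contrast) must be present. Stage tables that share no genes at all are
    treated as conflicting universes and rejected. Re-running on identical
    stage outputs yields a byte-identical report.
    """
    out = Path(out_dir)
    consensus_path = out / "consensus_tiers.tsv"
    region_path = out / "region_diff.tsv"
    contrast_path = out / "sc_contrast.tsv"
    stages = [p for p in (consensus_path, region_path, contrast_path) if p.exists()]
    if not stages:
        raise ValidationError(f"{out}: no stage outputs found to report on")

    lines = ["# Microglial GPCRome analysis report", ""]
    universes: list[set[str]] = []

    consensus = region = contrast = None
    if consensus_path.exists():
        consensus = pd.read_csv(consensus_path, sep="\t", index_col="gene")
        universes.append(set(consensus.index))
        summary = {}
        summary_path = out / "consensus_summary.json"
        if summary_path.exists():
            summary = json.loads(summary_path.read_text(encoding="utf-8"))
        cfg = summary.get("config", {})
        lines += [
            "## Core GPCR gene set",
            "",
            f"Consensus rule: tier >= {cfg.get('min_tier', 'medium')} in "
            f">= {cfg.get('min_fraction', 1.0):.0%} of "
            f"{summary.get('n_datasets', consensus.shape[1])} datasets; "
            f"rescue {'enabled' if cfg.get('rescue_enabled', True) else 'disabled'} "
            "(GM-medium / WM-high).",
            "",
            "| gene | membership | supporting datasets |",
            "|---|---|---|",
        ]
        members = consensus[consensus["consensus_member"]]
        for gene, row in members.iterrows():
            tag = "WM-rescued" if row["rescued"] else "consensus"
            lines.append(f"| {gene} | {tag} | {int(row['supporting_datasets'])} |")
        lines += ["", f"{len(members)} core genes "
                  f"({int(members['rescued'].sum())} via the WM rescue rule). "
                  "Full tier table: `consensus_tiers.tsv`.", ""]

    if region_path.exists():
        region = pd.read_csv(region_path, sep="\t", index_col="gene")
        universes.append(set(region.index))
        called = region[region["direction"] != "none"]
        lines += [
            "## Regional (WM vs GM) screen",
            "",
            f"{len(called)} genes with a >= 2-fold regional difference "
            f"out of {len(region)} tested. Full table: `region_diff.tsv`.",
            "",
            "| gene | direction | log2FC | q |",
            "|---|---|---|---|",
        ]
        for gene, row in called.iterrows():
            lines.append(
                f"| {gene} | {row['direction']} | {row['log2_fold_change']:.2f} "
                f"| {row['q']:.3g} |"
            )
        lines.append("")

    if contrast_path.exists():
        contrast = pd.read_csv(contrast_path, sep="\t", index_col="gene")
        universes.append(set(contrast.index))
        called = contrast[contrast["direction"] != "none"]
        lines += [
            "## Disease-associated vs homeostatic microglia (single cell)",
            "",
            f"{len(called)} panel genes shifted in the disease-associated "
            f"cluster. Full table: `sc_contrast.tsv`.",
            "",
            "| gene | direction | log2FC | q |",
            "|---|---|---|---|",
        ]
        for gene, row in called.iterrows():
            lines.append(
                f"| {gene} | {row['direction']} | {row['log2_fold_change']:.2f} "
                f"| {row['q']:.3g} |"
            )
        lines.append("")

    if len(universes) > 1:
        common = set.intersection(*universes)
        if not common:
            raise ValidationError(
                "stage outputs share no genes — conflicting gene universes"
            )

    report = out / "report.md"
    report.write_text("\n".join(lines).rstrip() + "\n", encoding="utf-8")
    return report
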