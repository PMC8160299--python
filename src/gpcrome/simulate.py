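"""Synthetic expression data with planted, machine-readable ground truth.

Three generators mirror the statistical structure of the study's inputs:

* bulk matrices — log-normal background expression with selected genes
  planted at exact target percentile ranks, plus mild multiplicative
  log-noise per (gene, sample);
* paired regional matrices — per-donor white-matter (WM) and grey-matter
  (GM) samples sharing a donor baseline, with multiplicative WM/GM fold
  changes planted on selected genes;
* single-cell datasets — negative-binomial counts over labeled clusters
  (a homeostatic majority, a small disease-associated cluster, monocytes,
  lymphocytes) with planted marker fold shifts, per-cell depth variation
  and a deterministic blob pseudo-embedding.

Every generator is a pure function of its spec and seed (byte-identical
artifacts for equal seeds) and returns a truth table recording what was
planted, so downstream recovery is checkable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import ExpressionMatrix, SampleTable, SingleCellDataset, ValidationError

# Default background / noise parameters. The log-normal(1.0, 1.5) background
# matches the heavy right tail of FPKM/TPM distributions. The default
# per-(gene, sample) log-noise is technical-scale jitter (sd 0.002): the
# planting contract promises that a planted midrank stays recoverable to
# within ~1 rank slot, which bounds how much independent per-gene noise the
# scenario can carry; stronger biological noise is available via the spec.
DEFAULT_MEANLOG = 1.0
DEFAULT_SDLOG = 1.5
DEFAULT_NOISE_SD = 0.002
DEFAULT_N_SAMPLES = 8


@dataclass
class TruthTable:
    """What the generator planted, for recovery checks.

    ``percentiles``: gene, target_percentile (realized grid value), planted
    mean. ``region_effects``: gene, WM/GM fold change. ``markers``: gene,
    cluster, fold change, direction (up/down relative to homeostatic).
    """

    percentiles: Optional[pd.DataFrame] = None
    region_effects: Optional[pd.DataFrame] = None
    markers: Optional[pd.DataFrame] = None

    def to_dir(self, dir_path) -> Path:
        d = Path(dir_path)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("percentiles", "region_effects", "markers"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(d / f"truth_{name}.tsv", sep="\t", index=False,
                          float_format="%.6g", lineterminator="\n")
        return d


# ---------------------------------------------------------------------------
# Bulk matrices with planted percentiles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBulkSpec:
    """Log-normal bulk dataset with genes planted at target percentiles."""

    n_genes: int = 1000
    n_samples: int = DEFAULT_N_SAMPLES
    meanlog: float = DEFAULT_MEANLOG
    sdlog: float = DEFAULT_SDLOG
    planted: Sequence[tuple[str, float]] = ()
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    dataset_id: str = "sim"
    unit: str = "FPKM"
    species: str = "human"

    def __post_init__(self) -> None:
        symbols = [g for g, _ in self.planted]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("planted gene symbols must be unique")
        for gene, pct in self.planted:
            if not (0 < pct <= 1):
                raise ValidationError(
                    f"target percentile {pct} for {gene} outside (0, 1]"
                )
        if self.n_genes <= len(symbols):
            raise ValidationError("n_genes must exceed the number of planted genes")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def plant_percentile(background_means: Sequence[float], target_percentile: float) -> float:
    """Value whose midrank/N equals ``target_percentile`` after insertion.

    The returned value lies strictly between the background order statistics
    bracketing rank ``round(target * N)`` (N = len(background) + 1), so the
    inserted gene is untied and lands exactly on that rank. Target 1.0 gives
    a value above the background maximum. Feasible targets form the grid
    k/N; off-grid targets are rounded to the nearest slot. A tie block in
    the background at the requested slot is an infeasibility error.
    """
    placed = _plant_many(np.asarray(background_means, dtype=float),
                         {"_g": float(target_percentile)})
    return placed["_g"]


def _plant_many(background: np.ndarray, targets: dict[str, float]) -> dict[str, float]:
    """Jointly place several genes at target percentile ranks.

    All ranks are taken over the final universe of N = len(background) +
    len(targets) values. Raises on rank collisions between planted genes and
    on tie-block infeasibility.
    """
    n_total = background.size + len(targets)
    ranks: dict[int, str] = {}
    for gene, pct in targets.items():
        if not (0 < pct <= 1):
            raise ValidationError(f"target percentile {pct} outside (0, 1]")
        r = int(round(pct * n_total))
        r = min(max(r, 1), n_total)
        if r in ranks:
            raise ValidationError(
                f"planted genes {ranks[r]!r} and {gene!r} imply the same "
                f"rank slot {r}/{n_total}"
            )
        ranks[r] = gene
    bg_sorted = np.sort(background)
    slots: list[Optional[float]] = []
    slot_gene: list[Optional[str]] = []
    bg_iter = iter(bg_sorted)
    for r in range(1, n_total + 1):
        if r in ranks:
            slots.append(None)
            slot_gene.append(ranks[r])
        else:
            slots.append(float(next(bg_iter)))
            slot_gene.append(None)
    placed: dict[str, float] = {}
    i = 0
    while i < n_total:
        if slots[i] is not None:
            i += 1
            continue
        j = i
        while j < n_total and slots[j] is None:
            j += 1
        run = j - i  # planted slots i..j-1
        left = slots[i - 1] if i > 0 else None
        right = slots[j] if j < n_total else None
        if left is not None and right is not None:
            if not (left < right):
                raise ValidationError(
                    f"tie block in background makes rank slots "
                    f"{i + 1}..{j} infeasible"
                )
            vals = np.linspace(left, right, run + 2)[1:-1]
        elif left is None and right is not None:
            if right <= 0:
                raise ValidationError("cannot place below a non-positive minimum")
            vals = right * (np.arange(1, run + 1) / (run + 1.0))
        elif right is None and left is not None:
            step = (abs(left) + 1.0) * 0.25
            vals = left + step * np.arange(1, run + 1)
        else:  # pragma: no cover - spec forbids all-planted universes
            raise ValidationError("cannot plant without any background values")
        for k in range(run):
            placed[slot_gene[i + k]] = float(vals[k])  # type: ignore[index]
        i = j
    return placed


def simulate_bulk(spec: SyntheticBulkSpec) -> tuple[ExpressionMatrix, TruthTable]:
    """Generate one bulk matrix; planted genes land exactly on target ranks.

    Noise-free (``noise_sd=0``) matrices recover every planted percentile
    exactly under mean-then-rank profiling; under the default jitter the
    recovered midrank stays within about one rank slot.
    """
    rng = np.random.default_rng(spec.seed)
    n_planted = len(spec.planted)
    n_bg = spec.n_genes - n_planted
    bg_means = rng.lognormal(spec.meanlog, spec.sdlog, n_bg)
    targets = dict(spec.planted)
    placed = _plant_many(bg_means, targets) if targets else {}

    gene_ids = [f"BG{i + 1:05d}" for i in range(n_bg)] + list(targets)
    means = np.concatenate([bg_means, np.array([placed[g] for g in targets])]) \
        if targets else bg_means
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_samples))
        values = means[:, None] * np.exp(noise)
    else:
        values = np.tile(means[:, None], (1, spec.n_samples))
    df = pd.DataFrame(
        values,
        index=pd.Index(gene_ids, name="gene"),
        columns=[f"{spec.dataset_id}_s{i + 1}" for i in range(spec.n_samples)],
    )
    matrix = ExpressionMatrix(
        values=df, unit=spec.unit, species=spec.species, dataset_id=spec.dataset_id
    )
    n = spec.n_genes
    truth = TruthTable(
        percentiles=pd.DataFrame(
            {
                "gene": list(targets),
                "target_percentile": [
                    min(max(int(round(p * n)), 1), n) / n for p in targets.values()
                ],
                "planted_mean": [placed[g] for g in targets],
                "dataset_id": spec.dataset_id,
            }
        )
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Paired WM/GM regional matrices
# ---------------------------------------------------------------------------

@dataclass
class SyntheticRegionSpec:
    """Paired per-donor WM and GM samples with planted regional fold changes.

    ``donor_sd`` is per-(gene, donor) biological log-noise shared by the two
    regions of a donor (it cancels in paired differences); ``base.noise_sd``
    is the per-sample measurement jitter on top.
    """

    base: SyntheticBulkSpec = field(default_factory=SyntheticBulkSpec)
    n_donors: int = 8
    region_effects: Sequence[tuple[str, float]] = ()
    donor_sd: float = 0.10
    paired: bool = True

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValidationError("paired regional simulation needs >= 2 donors")
        for gene, fc in self.region_effects:
            if fc <= 0:
                raise ValidationError(f"fold change for {gene} must be > 0")


def simulate_paired_regions(
    spec: SyntheticRegionSpec,
) -> tuple[ExpressionMatrix, SampleTable, TruthTable]:
    """Generate a donors x {WM, GM} matrix plus metadata and truth.

    Gene means come from the base bulk spec (planted percentiles included);
    each donor draws a shared baseline; WM samples multiply the planted
    region effects on top.
    """
    base_matrix, base_truth = simulate_bulk(
        SyntheticBulkSpec(**{**spec.base.__dict__, "n_samples": 1, "noise_sd": 0.0})
    )
    means = base_matrix.values.iloc[:, 0].to_numpy()
    gene_ids = base_matrix.gene_ids
    effects = np.ones(len(gene_ids))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for gene, fc in spec.region_effects:
        if gene not in idx:
            raise ValidationError(f"region-effect gene {gene!r} not in matrix")
        effects[idx[gene]] = fc

    rng = np.random.default_rng(np.random.SeedSequence([spec.base.seed, 17]))
    n_g, n_d = len(gene_ids), spec.n_donors
    donor_noise = (
        np.exp(rng.normal(0.0, spec.donor_sd, size=(n_g, n_d)))
        if spec.donor_sd > 0 else np.ones((n_g, n_d))
    )
    sd = spec.base.noise_sd

    def measured(base_vals: np.ndarray) -> np.ndarray:
        if sd > 0:
            return base_vals * np.exp(rng.normal(0.0, sd, size=base_vals.shape))
        return base_vals

    gm = measured(means[:, None] * donor_noise)
    wm = measured(means[:, None] * donor_noise * effects[:, None])

    columns, data, meta_rows = [], [], []
    for d in range(n_d):
        donor = f"donor{d + 1:02d}"
        for region, block in (("WM", wm), ("GM", gm)):
            sid = f"{spec.base.dataset_id}_{donor}_{region}"
            columns.append(sid)
            data.append(block[:, d])
            meta_rows.append(
                (sid, donor, region, "control", spec.base.species)
            )
    df = pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene"), columns=columns
    )
    matrix = ExpressionMatrix(
        values=df, unit=spec.base.unit, species=spec.base.species,
        dataset_id=spec.base.dataset_id,
    )
    samples = SampleTable(
        pd.DataFrame(
            meta_rows,
            columns=["sample_id", "donor_id", "region", "condition", "species"],
        )
    )
    truth = TruthTable(
        percentiles=base_truth.percentiles,
        region_effects=pd.DataFrame(
            {
                "gene": [g for g, _ in spec.region_effects],
                "fold_change_wm_over_gm": [fc for _, fc in spec.region_effects],
            }
        ),
    )
    return matrix, samples, truth


# ---------------------------------------------------------------------------
# Single-cell datasets with a disease-associated cluster
# ---------------------------------------------------------------------------

DEFAULT_CLUSTER_PROPORTIONS = {
    "homeostatic": 0.75,
    "disease": 0.10,
    "monocyte": 0.10,
    "lymphocyte": 0.05,
}


@dataclass
class SyntheticSCSpec:
    """Negative-binomial single-cell counts over labeled clusters.

    ``gene_means`` are baseline (homeostatic) per-gene mean counts;
    ``marker_shifts`` multiply a gene's mean within one cluster. Counts are
    Gamma-Poisson with shape ``dispersion`` (var = m + m^2/dispersion);
    per-cell depth is log-normal with sd ``depth_sdlog``. A deterministic
    cluster-blob pseudo-embedding is attached (embeddings are inputs to the
    analysis, so the generator supplies one).
    """

    n_cells: int = 1600
    cluster_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_PROPORTIONS)
    )
    gene_means: dict[str, float] = field(default_factory=dict)
    n_background_genes: int = 100
    background_meanlog: float = 0.0
    background_sdlog: float = 1.0
    dispersion: float = 2.0
    marker_shifts: Sequence[tuple[str, str, float]] = ()
    depth_sdlog: float = 0.30
    seed: int = 0
    dataset_id: str = "sc_sim"

    def __post_init__(self) -> None:
        total = sum(self.cluster_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cluster proportions sum to {total}, not 1")
        if any(v < 0 for v in self.cluster_proportions.values()):
            raise ValidationError("cluster proportions must be >= 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if any(m < 0 for m in self.gene_means.values()):
            raise ValidationError("gene means must be >= 0")
        for gene, cluster, fc in self.marker_shifts:
            if fc <= 0:
                raise ValidationError(f"marker shift for {gene} must be > 0")
            if cluster not in self.cluster_proportions:
                raise ValidationError(f"marker cluster {cluster!r} not in proportions")


def _cluster_sizes(spec: SyntheticSCSpec) -> dict[str, int]:
    names = list(spec.cluster_proportions)
    sizes = {c: int(round(spec.cluster_proportions[c] * spec.n_cells)) for c in names}
    drift = spec.n_cells - sum(sizes.values())
    sizes[names[0]] += drift
    for c, n in sizes.items():
        if n <= 0:
            raise ValidationError(
                f"cluster {c!r} has no cells at n_cells={spec.n_cells}"
            )
    return sizes


def simulate_single_cell(spec: SyntheticSCSpec) -> tuple[SingleCellDataset, TruthTable]:
    """Generate a cluster-labeled single-cell dataset plus marker truth."""
    rng = np.random.default_rng(spec.seed)
    n_bg = spec.n_background_genes
    bg_means = rng.lognormal(spec.background_meanlog, spec.background_sdlog, n_bg)
    gene_ids = list(spec.gene_means) + [f"BG{i + 1:04d}" for i in range(n_bg)]
    base = np.concatenate([np.array(list(spec.gene_means.values())), bg_means])
    n_genes = base.size

    sizes = _cluster_sizes(spec)
    clusters = list(sizes)
    shift = {c: np.ones(n_genes) for c in clusters}
    gidx = {g: i for i, g in enumerate(gene_ids)}
    for gene, cluster, fc in spec.marker_shifts:
        if gene not in gidx:
            raise ValidationError(f"marker gene {gene!r} not in gene universe")
        shift[cluster][gidx[gene]] = fc

    blocks, labels = [], []
    centers = {
        c: 6.0 * np.array([np.cos(a), np.sin(a)])
        for c, a in zip(clusters, np.linspace(0, 2 * np.pi, len(clusters), endpoint=False))
    }
    embedding_rows = []
    for cluster in clusters:
        n_c = sizes[cluster]
        mu = base * shift[cluster]
        depth = np.exp(rng.normal(0.0, spec.depth_sdlog, size=n_c))
        lam = rng.gamma(
            shape=spec.dispersion,
            scale=np.maximum(mu, 1e-12)[None, :] / spec.dispersion,
            size=(n_c, n_genes),
        ) * depth[:, None]
        counts = rng.poisson(lam)
        blocks.append(counts)
        labels.extend([cluster] * n_c)
        embedding_rows.append(
            centers[cluster][None, :] + rng.normal(0.0, 1.0, size=(n_c, 2))
        )
    counts = sp.csr_matrix(np.vstack(blocks))
    cell_ids = [f"cell{i + 1:05d}" for i in range(spec.n_cells)]
    dataset = SingleCellDataset(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cluster_labels=np.array(labels, dtype=object),
        embedding=np.vstack(embedding_rows),
        dataset_id=spec.dataset_id,
    )
    truth = TruthTable(
        markers=pd.DataFrame(
            {
                "gene": [g for g, _, _ in spec.marker_shifts],
                "cluster": [c for _, c, _ in spec.marker_shifts],
                "fold_change": [fc for _, _, fc in spec.marker_shifts],
                "direction": ["up" if fc > 1 else "down" for _, _, fc in spec.marker_shifts],
            }
        )
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# The paper-mirror scenario
# ---------------------------------------------------------------------------

def load_scenario(path: Optional[str | Path] = None) -> dict:
    """Load the scenario config (default: the shipped paper-mirror YAML)."""
    if path is None:
        text = resources.files("gpcrome").joinpath("data/paper_mirror.yaml").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def _distinct_percentiles(
    rng: np.random.Generator, n: int, lo: float, hi: float, n_genes: int,
    taken: set[int],
) -> list[float]:
    """Draw n distinct rank slots in [lo, hi] (as percentiles) avoiding ``taken``."""
    lo_r = max(1, int(np.ceil(lo * n_genes)))
    hi_r = min(n_genes, int(np.floor(hi * n_genes)))
    candidates = [r for r in range(lo_r, hi_r + 1) if r not in taken]
    if len(candidates) < n:
        raise ValidationError(
            f"not enough free rank slots in [{lo}, {hi}] for {n} genes"
        )
    chosen = rng.choice(len(candidates), size=n, replace=False)
    ranks = [candidates[i] for i in sorted(chosen)]
    taken.update(ranks)
    return [r / n_genes for r in ranks]


def build_paper_mirror_bulk(
    scenario: dict, gpcr_genes: Sequence[str], seed: int
) -> list[tuple[SyntheticBulkSpec, Optional[str]]]:
    """Bulk specs for the scenario: several whole-tissue datasets plus a
    (GM, WM) pair, with every catalog GPCR gene planted.

    Returns (spec, region_label) pairs. Core genes are planted high
    everywhere; rescue genes are planted medium in GM, high in WM and low
    elsewhere; all remaining catalog GPCR genes sit below the medium band
    with a safety margin, so the planted core set is exactly recoverable.
    """
    cfg = scenario["bulk"]
    core = list(scenario["core_genes"])
    rescue = list(scenario["rescue_genes"])
    others = [g for g in gpcr_genes if g not in core and g not in rescue]
    n_genes = int(cfg["n_genes"])
    datasets = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    names = [(f"whole{i + 1}", None) for i in range(int(cfg["n_whole_datasets"]))]
    names += [("gm", "GM"), ("wm", "WM")]
    for k, (name, region) in enumerate(names):
        taken: set[int] = set()
        planted: list[tuple[str, float]] = []
        core_p = _distinct_percentiles(
            rng, len(core), *cfg["core_percentile_range"], n_genes, taken
        )
        planted += list(zip(core, core_p))
        if region == "GM":
            band = cfg["rescue_gm_percentile_range"]
        elif region == "WM":
            band = cfg["rescue_wm_percentile_range"]
        else:
            band = cfg["rescue_other_percentile_range"]
        rescue_p = _distinct_percentiles(rng, len(rescue), *band, n_genes, taken)
        planted += list(zip(rescue, rescue_p))
        other_p = _distinct_percentiles(
            rng, len(others), *cfg["background_gpcr_percentile_range"], n_genes, taken
        )
        planted += list(zip(others, other_p))
        spec = SyntheticBulkSpec(
            n_genes=n_genes,
            n_samples=int(cfg["n_samples"]),
            planted=planted,
            noise_sd=float(cfg["noise_sd"]),
            seed=int(np.random.SeedSequence([seed, 211 + k]).generate_state(1)[0] % (2**31)),
            dataset_id=name,
            species=scenario.get("species", "human"),
        )
        datasets.append((spec, region))
    return datasets


def build_paper_mirror_region(
    scenario: dict, gpcr_genes: Sequence[str], seed: int
) -> SyntheticRegionSpec:
    """Paired-region spec: catalog genes planted as in a whole-tissue
    dataset, with the scenario's WM/GM fold changes on top."""
    cfg = scenario["bulk"]
    rcfg = scenario["region"]
    core = list(scenario["core_genes"])
    rescue = list(scenario["rescue_genes"])
    others = [g for g in gpcr_genes if g not in core and g not in rescue]
    n_genes = int(cfg["n_genes"])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 401]))
    taken: set[int] = set()
    planted = list(zip(core, _distinct_percentiles(
        rng, len(core), *cfg["core_percentile_range"], n_genes, taken)))
    planted += list(zip(rescue, _distinct_percentiles(
        rng, len(rescue), *cfg["rescue_gm_percentile_range"], n_genes, taken)))
    planted += list(zip(others, _distinct_percentiles(
        rng, len(others), *cfg["background_gpcr_percentile_range"], n_genes, taken)))
    base = SyntheticBulkSpec(
        n_genes=n_genes,
        n_samples=1,
        planted=planted,
        noise_sd=float(cfg["noise_sd"]),
        seed=int(np.random.SeedSequence([seed, 409]).generate_state(1)[0] % (2**31)),
        dataset_id="region_pair",
        species=scenario.get("species", "human"),
    )
    return SyntheticRegionSpec(
        base=base,
        n_donors=int(rcfg["n_donors"]),
        region_effects=[(g, float(fc)) for g, fc in (tuple(e) for e in rcfg["effects"])],
        donor_sd=float(rcfg["donor_sd"]),
        paired=True,
    )


def build_paper_mirror_sc(
    scenario: dict, gpcr_genes: Sequence[str], seed: int
) -> SyntheticSCSpec:
    """Single-cell spec: small disease cluster, homeostatic markers shifted
    down, the chemokine receptor shifted up."""
    cfg = scenario["single_cell"]
    gene_means = {g: float(cfg["panel_baseline_mean"]) for g in scenario["core_genes"]}
    for g in scenario["rescue_genes"]:
        gene_means[g] = float(cfg["rescue_baseline_mean"])
    for g in gpcr_genes:
        gene_means.setdefault(g, float(cfg["other_gpcr_mean"]))
    shifts = [
        (g, str(c), float(fc)) for g, c, fc in (tuple(s) for s in cfg["marker_shifts"])
    ]
    return SyntheticSCSpec(
        n_cells=int(cfg["n_cells"]),
        cluster_proportions={k: float(v) for k, v in cfg["cluster_proportions"].items()},
        gene_means=gene_means,
        n_background_genes=int(cfg["n_background_genes"]),
        dispersion=float(cfg["dispersion"]),
        marker_shifts=shifts,
        depth_sdlog=float(cfg["depth_sdlog"]),
        seed=int(np.random.SeedSequence([seed, 907]).generate_state(1)[0] % (2**31)),
        dataset_id="sc_mirror",
    )
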