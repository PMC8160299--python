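"""Cross-dataset consensus core gene set with the white-matter rescue rule.

A catalog GPCR gene joins the core set when it reaches a minimum expression
tier (default: medium) in a minimum fraction of the profiled datasets
(default: all of them). A second route — the rescue rule — admits genes that
miss the consensus but are medium-expressed in grey-matter microglia while
highly expressed in white-matter microglia, mirroring how regionally biased
receptors like CXCR4 and PTGER4 enter the microglial core signature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io import ValidationError
from .profiling import PercentileProfile, Tier
from .registry import GeneSetCatalog


@dataclass(frozen=True)
class ConsensusConfig:
    """Membership rule for the core set.

    ``min_tier``: tier a gene must reach in a dataset to support membership.
    ``min_fraction``: fraction of datasets that must support it (ceil'd).
    ``rescue_enabled``: whether the GM-medium / WM-high rescue route applies
    when a (GM, WM) profile pair is designated.
    """

    min_tier: Tier = Tier.medium
    min_fraction: float = 1.0
    rescue_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction <= 1):
            raise ValidationError(
                f"min_fraction must be in (0, 1], got {self.min_fraction}"
            )

    def required_count(self, n_datasets: int) -> int:
        return math.ceil(self.min_fraction * n_datasets - 1e-12)


@dataclass
class ConsensusResult:
    """Per-gene tier table across datasets plus core-set membership.

    ``tiers``: genes x datasets integer tier table (see :class:`Tier`).
    ``membership``: per-gene ``consensus_member``, ``rescued`` and
    ``supporting_datasets`` columns. Invariants: rescued implies member;
    member implies enough supporting datasets or rescued.
    """

    tiers: pd.DataFrame
    membership: pd.DataFrame
    config: ConsensusConfig
    species: str = "human"

    @property
    def members(self) -> list[str]:
        return list(self.membership.index[self.membership["consensus_member"]])

    @property
    def rescued(self) -> list[str]:
        return list(self.membership.index[self.membership["rescued"]])

    def to_tsv(self, path) -> None:
        out = self.tiers.copy()
        for col in out.columns:
            out[col] = [Tier(int(t)).name for t in out[col]]
        out = out.join(self.membership)
        out.index.name = "gene"
        out.to_csv(path, sep="\t", lineterminator="\n")

    def summary_json(self) -> str:
        return json.dumps(
            {
                "members": self.members,
                "rescued": self.rescued,
                "config": {
                    "min_tier": self.config.min_tier.name,
                    "min_fraction": self.config.min_fraction,
                    "rescue_enabled": self.config.rescue_enabled,
                },
                "n_datasets": int(self.tiers.shape[1]),
            },
            indent=2,
        )


def _gene_universe(
    profiles: Sequence[PercentileProfile], catalog: GeneSetCatalog
) -> list[str]:
    species = {p.species for p in profiles}
    if len(species) != 1:
        raise ValidationError(
            f"consensus profiles must share a species, got {sorted(species)}"
        )
    genes = [
        g for g in catalog.genes(species.pop(), "gpcr")
        if any(g in p.table.index for p in profiles)
    ]
    present_everywhere = [g for g in genes if all(g in p.table.index for p in profiles)]
    if not present_everywhere:
        raise ValidationError(
            "profiles have disjoint gene universes over the catalog GPCR genes"
        )
    return genes


def region_rescue(
    gm_profile: PercentileProfile,
    wm_profile: PercentileProfile,
    catalog: GeneSetCatalog,
    config: ConsensusConfig = ConsensusConfig(),
) -> list[str]:
    """Genes medium in the GM profile but high in the WM profile.

    Both profiles must carry their region label and come from the same
    species. Genes already high in GM are not rescue candidates (they enter
    via the main rule if at all).
    """
    if gm_profile.region != "GM" or wm_profile.region != "WM":
        raise ValidationError(
            f"rescue needs profiles labeled GM and WM, got "
            f"{gm_profile.region!r} and {wm_profile.region!r}"
        )
    if gm_profile.species != wm_profile.species:
        raise ValidationError("rescue profiles must be the same species")
    rescued = []
    for gene in catalog.genes(gm_profile.species, "gpcr"):
        if gene not in gm_profile.table.index or gene not in wm_profile.table.index:
            continue
        if gm_profile.tier(gene) == Tier.medium and wm_profile.tier(gene) == Tier.high:
            rescued.append(gene)
    return rescued


def derive_core_set(
    profiles: Sequence[PercentileProfile],
    catalog: GeneSetCatalog,
    config: ConsensusConfig = ConsensusConfig(),
    gm_profile: Optional[PercentileProfile] = None,
    wm_profile: Optional[PercentileProfile] = None,
) -> ConsensusResult:
    """Derive the consensus core gene set over >= 2 dataset profiles.

    A gene is a consensus member when it reaches ``config.min_tier`` in at
    least ``ceil(min_fraction * D)`` of the D datasets. If a (GM, WM) profile
    pair is designated and rescue is enabled, genes passing the rescue rule
    are added with ``rescued = True``. Output is independent of profile
    ordering; the full tier table is retained for audit.
    """
    if len(profiles) < 2:
        raise ValidationError("consensus needs at least two dataset profiles")
    ids = [p.dataset_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate dataset_ids in profiles: {ids}")
    genes = _gene_universe(profiles, catalog)
    order = sorted(range(len(profiles)), key=lambda i: ids[i])
    profiles = [profiles[i] for i in order]

    tiers = pd.DataFrame(
        {
            p.dataset_id: [
                int(p.tier(g)) if g in p.table.index else int(Tier.below_cutoff)
                for g in genes
            ]
            for p in profiles
        },
        index=pd.Index(genes, name="gene"),
    )
    support = (tiers >= int(config.min_tier)).sum(axis=1)
    required = config.required_count(len(profiles))
    member = support >= required

    rescued_genes: set[str] = set()
    if config.rescue_enabled and gm_profile is not None and wm_profile is not None:
        rescued_genes = {
            g
            for g in region_rescue(gm_profile, wm_profile, catalog, config)
            if g in tiers.index and not member.loc[g]
        }
    elif (gm_profile is None) != (wm_profile is None):
        raise ValidationError("rescue needs both a GM and a WM profile")

    membership = pd.DataFrame(
        {
            "consensus_member": member | tiers.index.isin(rescued_genes),
            "rescued": tiers.index.isin(rescued_genes),
            "supporting_datasets": support,
        },
        index=tiers.index,
    )
    species = profiles[0].species
    return ConsensusResult(
        tiers=tiers, membership=membership, config=config, species=species
    )
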