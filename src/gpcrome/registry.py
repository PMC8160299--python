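"""Curated GPCR / GPCR-signaling gene catalog.

The catalog houses the gene universe the pipeline profiles: non-sensory GPCRs
with their GRAFS family (glutamate, rhodopsin, adhesion, frizzled, secretin)
plus downstream signaling mediators (heterotrimeric G-protein alpha subunits,
GPCR kinases, arrestins), for human and mouse, with alias resolution and
cross-species symbol mapping.

The shipped snapshot (``data/gpcr_catalog.csv``) covers the microglial core
signature and every gene the analyses touch; it carries a ``version_tag`` and
its family counts are metadata of the snapshot, not a claim about the full
IUPHAR GPCRome.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

SPECIES = ("human", "mouse")
FAMILIES = ("rhodopsin", "adhesion", "glutamate", "secretin", "frizzled", "none")
CATEGORIES = ("gpcr", "g_protein", "grk", "arrestin")

#: Sentinel returned by :func:`map_ortholog` when a gene has no counterpart
#: in the target species (a biological fact, not an error).
NO_ORTHOLOG = None


class CatalogError(ValueError):
    """Malformed or inconsistent catalog content."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene in one species.

    ``family`` is a GRAFS family for GPCRs and ``"none"`` for signaling
    molecules (G proteins, GRKs, arrestins); ``ortholog_override`` names the
    counterpart symbol in the other species when plain case-normalized symbol
    equality does not hold (e.g. human MRGPRX2 <-> mouse Mrgprb2).
    """

    symbol: str
    species: str
    family: str
    category: str
    aliases: tuple[str, ...] = ()
    protein_name: Optional[str] = None
    ortholog_override: Optional[str] = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise CatalogError(f"unknown species {self.species!r} for {self.symbol}")
        if self.family not in FAMILIES:
            raise CatalogError(f"unknown family {self.family!r} for {self.symbol}")
        if self.category not in CATEGORIES:
            raise CatalogError(f"unknown category {self.category!r} for {self.symbol}")
        if (self.family == "none") != (self.category != "gpcr"):
            raise CatalogError(
                f"{self.symbol}: family must be 'none' exactly when category is "
                f"not 'gpcr' (got family={self.family}, category={self.category})"
            )


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive comparison key for gene symbols."""
    return symbol.strip().upper()


def species_case(symbol: str, species: str) -> str:
    """Display form of a symbol under a species' nomenclature convention.

    Human (HGNC): all upper case. Mouse (MGI): first letter upper, rest lower.
    """
    key = normalize_symbol(symbol)
    if species == "human":
        return key
    if species == "mouse":
        return key[:1].upper() + key[1:].lower()
    raise CatalogError(f"unknown species {species!r}")


@dataclass
class GeneSetCatalog:
    """Collection of :class:`GeneRecord` with alias-aware lookup."""

    records: list[GeneRecord]
    version_tag: str = "unversioned"
    _index: dict[tuple[str, str], GeneRecord] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self._index = {}
        primary: dict[tuple[str, str], str] = {}
        for rec in self.records:
            key = (rec.species, normalize_symbol(rec.symbol))
            if key in primary:
                raise CatalogError(
                    f"duplicate catalog entry for {rec.species} symbol {rec.symbol}"
                )
            primary[key] = rec.symbol
            self._index[key] = rec
        for rec in self.records:
            for alias in rec.aliases:
                key = (rec.species, normalize_symbol(alias))
                if key in primary and primary[key] != rec.symbol:
                    raise CatalogError(
                        f"alias {alias!r} of {rec.symbol} collides with primary "
                        f"symbol {primary[key]!r} ({rec.species})"
                    )
                existing = self._index.get(key)
                if existing is not None and existing.symbol != rec.symbol:
                    raise CatalogError(
                        f"alias {alias!r} is ambiguous between {existing.symbol} "
                        f"and {rec.symbol} ({rec.species})"
                    )
                self._index.setdefault(key, rec)

    def lookup(self, species: str, symbol: str) -> Optional[GeneRecord]:
        """Resolve a symbol or alias to its record, or None."""
        return self._index.get((species, normalize_symbol(symbol)))

    def __contains__(self, item: tuple[str, str]) -> bool:
        species, symbol = item
        return self.lookup(species, symbol) is not None

    def genes(self, species: str, category: Optional[str] = "gpcr") -> list[str]:
        """Primary symbols for one species, optionally filtered by category."""
        return [
            r.symbol
            for r in self.records
            if r.species == species and (category is None or r.category == category)
        ]

    def family_counts(self, species: str) -> dict[str, int]:
        counts = Counter(
            r.family for r in self.records if r.species == species and r.category == "gpcr"
        )
        return dict(counts)

    def load_summary(self) -> dict:
        """Per-species family and category counts of the snapshot."""
        return {
            "version_tag": self.version_tag,
            "n_records": len(self.records),
            "families": {sp: self.family_counts(sp) for sp in SPECIES},
            "categories": {
                sp: dict(Counter(r.category for r in self.records if r.species == sp))
                for sp in SPECIES
            },
        }


_CATALOG_COLUMNS = [
    "species",
    "symbol",
    "aliases",
    "family",
    "category",
    "protein_name",
    "ortholog",
]


def load_catalog(path: Optional[str | Path] = None) -> GeneSetCatalog:
    """Load a catalog from a comma-delimited file.

    ``path=None`` loads the snapshot shipped with the package. The file is
    UTF-8 CSV with a header row (columns ``species,symbol,aliases,family,
    category,protein_name,ortholog``); ``#`` lines are comments, and a comment
    of the form ``# version_tag: <tag>`` sets the snapshot tag.

    Raises :class:`CatalogError` naming the offending symbol on duplicates and
    the line number on unknown family/category tokens.
    """
    if path is None:
        ref = resources.files("gpcrome").joinpath("data/gpcr_catalog.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")

    version_tag = "unversioned"
    data_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("version_tag:"):
                version_tag = body.split(":", 1)[1].strip()
            continue
        data_lines.append((lineno, raw))
    if not data_lines:
        raise CatalogError("catalog file contains no data rows")

    header_line = data_lines[0][1]
    reader = csv.DictReader(
        [header_line] + [line for _, line in data_lines[1:]],
        restval="",
    )
    missing = set(_CATALOG_COLUMNS[:5]) - set(reader.fieldnames or ())
    if missing:
        raise CatalogError(f"catalog header missing columns: {sorted(missing)}")

    records: list[GeneRecord] = []
    seen: set[tuple[str, str]] = set()
    for (lineno, _), row in zip(data_lines[1:], reader):
        species = row["species"].strip()
        symbol = row["symbol"].strip()
        if not symbol:
            raise CatalogError(f"line {lineno}: empty gene symbol")
        key = (species, normalize_symbol(symbol))
        if key in seen:
            raise CatalogError(f"duplicate gene {symbol!r} for species {species}")
        seen.add(key)
        aliases = tuple(
            a.strip() for a in (row.get("aliases") or "").split(";") if a.strip()
        )
        try:
            rec = GeneRecord(
                symbol=symbol,
                species=species,
                family=row["family"].strip(),
                category=row["category"].strip(),
                aliases=aliases,
                protein_name=(row.get("protein_name") or "").strip() or None,
                ortholog_override=(row.get("ortholog") or "").strip() or None,
            )
        except CatalogError as exc:
            raise CatalogError(f"line {lineno}: {exc}") from None
        records.append(rec)
    return GeneSetCatalog(records=records, version_tag=version_tag)


def map_ortholog(
    symbol: str,
    from_species: str,
    to_species: str,
    catalog: GeneSetCatalog,
) -> Optional[str]:
    """Map a gene symbol across species.

    Default rule: case-normalized symbol equality, rendered in the target
    species' casing convention — human P2RY12 <-> mouse P2ry12. An explicit
    ``ortholog`` entry in the catalog overrides the default (e.g. human
    MRGPRX2 <-> mouse Mrgprb2). Returns :data:`NO_ORTHOLOG` (None) when the
    counterpart does not exist in the target species' catalog; raises if the
    source symbol itself is not in the catalog.
    """
    if from_species == to_species:
        raise CatalogError("from_species and to_species must differ")
    rec = catalog.lookup(from_species, symbol)
    if rec is None:
        raise CatalogError(f"{symbol!r} not in catalog for species {from_species}")
    if rec.ortholog_override is not None:
        target = catalog.lookup(to_species, rec.ortholog_override)
        return target.symbol if target is not None else NO_ORTHOLOG
    target = catalog.lookup(to_species, species_case(rec.symbol, to_species))
    if target is None:
        return NO_ORTHOLOG
    return target.symbol


def ortholog_pairs(
    catalog: GeneSetCatalog,
    from_species: str = "human",
    to_species: str = "mouse",
    category: Optional[str] = "gpcr",
) -> list[tuple[str, Optional[str]]]:
    """(source symbol, target symbol or None) for every source-species gene."""
    return [
        (sym, map_ortholog(sym, from_species, to_species, catalog))
        for sym in catalog.genes(from_species, category)
    ]
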