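"""Per-species CAZyme repertoires: family counts, substrate totals, uniqueness.

Aggregates gene-level CAZy annotations into a species × family count matrix,
derives per-polysaccharide gene totals through the catalog, reports families
unique to one species or exclusive to one taxonomic grouping, and merges
ortholog groupings produced by independent callers into one consistent set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import pandas as pd

from .catalog import Catalog, FamilyKey, parse_family_key, SUBSTRATES

__all__ = [
    "GeneAnnotation",
    "RepertoireMatrix",
    "OrthologGroupSet",
    "read_annotations",
    "count_families",
    "substrate_totals",
    "uniqueness_report",
    "UniquenessReport",
    "read_ortholog_groups",
    "merge_ortholog_groups",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's CAZy family assignment within a species."""

    gene_id: str
    species: str
    family: FamilyKey

    def __post_init__(self) -> None:
        if not self.gene_id or not self.species:
            raise ValueError("gene_id and species must be non-empty")
        object.__setattr__(self, "family", parse_family_key(self.family))


@dataclass
class RepertoireMatrix:
    """Species × family gene-count matrix.

    ``counts`` is a DataFrame indexed by species with canonical family-label
    columns; values are gene counts. Families are kept at the resolution of the
    annotation (a gene annotated ``GH5_7`` is counted under GH5_7, not GH5).
    ``off_catalog`` holds counts for annotated families outside the working
    catalog so nothing is silently dropped.
    """

    counts: pd.DataFrame
    off_catalog: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[FamilyKey]:
        return [parse_family_key(c) for c in self.counts.columns]


def read_annotations(path: Union[str, Path]) -> list[GeneAnnotation]:
    """Read an annotation TSV with columns species, gene_id, family."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"species", "gene_id", "family"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file {path} must have columns {sorted(required)}")
    return [
        GeneAnnotation(gene_id=r.gene_id, species=r.species, family=parse_family_key(r.family))
        for r in df.itertuples()
    ]


def _sorted_family_labels(keys: Iterable[FamilyKey]) -> list[str]:
    return [str(k) for k in sorted(set(keys), key=FamilyKey.sort_key)]


def count_families(
    annotations: Iterable[GeneAnnotation],
    catalog: Optional[Catalog] = None,
) -> RepertoireMatrix:
    """Tally genes per (species, family).

    Duplicate (species, gene_id) pairs are rejected. When a catalog is given,
    families absent from it are tallied in the ``off_catalog`` side table and
    excluded from the main matrix; without a catalog every family is in the
    main matrix and ``off_catalog`` is empty.
    """
    anns = list(annotations)
    seen: set[tuple[str, str]] = set()
    for a in anns:
        key = (a.species, a.gene_id)
        if key in seen:
            raise ValueError(f"duplicate annotation for gene {a.gene_id!r} in species {a.species!r}")
        seen.add(key)

    def in_catalog(fam: FamilyKey) -> bool:
        return catalog is None or catalog.contains(fam)

    main = [a for a in anns if in_catalog(a.family)]
    off = [a for a in anns if not in_catalog(a.family)]

    def tally(subset: list[GeneAnnotation]) -> pd.DataFrame:
        species = sorted({a.species for a in subset})
        fams = _sorted_family_labels(a.family for a in subset)
        df = pd.DataFrame(0, index=species, columns=fams, dtype=int)
        for a in subset:
            df.loc[a.species, str(a.family)] += 1
        return df

    counts = tally(main)
    # keep every species as a row even if all its genes were off-catalog
    all_species = sorted({a.species for a in anns})
    counts = counts.reindex(index=all_species, fill_value=0)
    return RepertoireMatrix(counts=counts, off_catalog=tally(off))


def substrate_totals(repertoire: RepertoireMatrix, catalog: Catalog) -> pd.DataFrame:
    """Species × substrate gene totals.

    A family mapped to k substrates contributes each of its genes to all k
    substrate totals (counted once per substrate, not fractionally split).
    """
    totals = pd.DataFrame(
        0, index=repertoire.counts.index, columns=list(SUBSTRATES), dtype=int
    )
    for fam_label in repertoire.counts.columns:
        for substrate in catalog.substrates_of(fam_label):
            totals[substrate] += repertoire.counts[fam_label]
    return totals


@dataclass
class UniquenessReport:
    """Families found in exactly one species, or confined to one grouping.

    ``species_unique`` maps family → the single carrier species;
    ``group_exclusive`` maps family → the single carrier group for families
    present in ≥2 species that all belong to one group.
    """

    species_unique: dict[FamilyKey, str]
    group_exclusive: dict[FamilyKey, str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"family": str(f), "scope": "species_unique", "carrier": s}
            for f, s in sorted(self.species_unique.items(), key=lambda kv: kv[0].sort_key())
        ] + [
            {"family": str(f), "scope": "group_exclusive", "carrier": g}
            for f, g in sorted(self.group_exclusive.items(), key=lambda kv: kv[0].sort_key())
        ]
        return pd.DataFrame(rows, columns=["family", "scope", "carrier"])


def uniqueness_report(
    repertoire: RepertoireMatrix, grouping: Mapping[str, str]
) -> UniquenessReport:
    """Detect species-unique and group-exclusive families (presence = count ≥ 1)."""
    missing = [s for s in repertoire.counts.index if s not in grouping]
    if missing:
        raise ValueError(f"grouping missing for species: {missing}")
    species_unique: dict[FamilyKey, str] = {}
    group_exclusive: dict[FamilyKey, str] = {}
    for fam_label in repertoire.counts.columns:
        present = [s for s in repertoire.counts.index if repertoire.counts.loc[s, fam_label] >= 1]
        if not present:
            continue
        key = parse_family_key(fam_label)
        if len(present) == 1:
            species_unique[key] = present[0]
            continue
        groups = {grouping[s] for s in present}
        all_groups = set(grouping[s] for s in repertoire.counts.index)
        if len(groups) == 1 and len(all_groups) > 1:
            group_exclusive[key] = next(iter(groups))
    return UniquenessReport(species_unique, group_exclusive)


@dataclass
class OrthologGroupSet:
    """Disjoint groups of ortholog gene identifiers from one caller."""

    groups: tuple[frozenset, ...]
    source: str = ""

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups if g)
        seen: set = set()
        for g in groups:
            if seen & g:
                raise ValueError(
                    f"ortholog groups from {self.source or 'input'} are not disjoint: "
                    f"{sorted(seen & g)}"
                )
            seen |= g
        self.groups = groups

    @property
    def genes(self) -> frozenset:
        out: set = set()
        for g in self.groups:
            out |= g
        return frozenset(out)


def read_ortholog_groups(path: Union[str, Path], source: str = "") -> OrthologGroupSet:
    """Read the plain-text ortholog dialect: one group per line, ids whitespace-separated."""
    groups = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        # tolerate an "GROUPNAME:" prefix as written by some callers
        if ":" in line.split()[0]:
            line = line.split(":", 1)[1]
        ids = line.split()
        if ids:
            groups.append(frozenset(ids))
    return OrthologGroupSet(groups=tuple(groups), source=source or str(path))


def merge_ortholog_groups(a: OrthologGroupSet, b: OrthologGroupSet) -> OrthologGroupSet:
    """Union two ortholog groupings: connected components of the co-grouping graph.

    Two genes end up together iff they are linked by a chain of co-memberships
    in either input. Singleton genes stay as singleton groups; every input gene
    appears exactly once in the output.
    """
    g = nx.Graph()
    for gs in (a, b):
        for group in gs.groups:
            members = sorted(group)
            g.add_nodes_from(members)
            g.add_edges_from(zip(members, members[1:]))
    merged = tuple(frozenset(c) for c in nx.connected_components(g))
    src = " + ".join(s for s in (a.source, b.source) if s) or "merged"
    return OrthologGroupSet(groups=merged, source=src)
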