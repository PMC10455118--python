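"""Curated CAZy (sub-)family → enzyme activity → plant-polysaccharide catalog.

Carbohydrate-active enzymes (CAZymes) are classified into families — glycoside
hydrolases (GH), carbohydrate esterases (CE), polysaccharide lyases (PL), and
auxiliary activities (AA) — some of which are split into subfamilies with
narrower substrate specificity (written ``GH5_7``). Feruloyl esterases (FAE)
are carried as a pseudo-family of their own so they participate uniformly in
counting and multifunctionality queries.

The packaged catalog maps each plant-biomass-degradation family to the
polysaccharide(s) it helps decompose: cellulose, xylan, xyloglucan, mannan,
pectin, starch, or inulin. Subfamily-resolved rows are distinct catalog units
(GH5_7 is a mannanase, GH5_4 an endoglucanase); bare-family queries roll
subfamilies up, and class-level censuses count families once regardless of
subfamily splits.
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

__all__ = [
    "ENZYME_CLASSES",
    "SUBSTRATES",
    "FamilyKey",
    "CatalogEntry",
    "Catalog",
    "CatalogError",
    "FamilyParseError",
    "parse_family_key",
    "load_catalog",
    "substrates_of",
    "families_for_substrate",
    "multifunctional_families",
    "class_family_counts",
]

#: CAZy enzyme classes handled here, in canonical display order.
ENZYME_CLASSES = ("GH", "CE", "PL", "AA", "FAE")

#: The plant polysaccharide vocabulary of the catalog.
SUBSTRATES = (
    "cellulose",
    "xylan",
    "xyloglucan",
    "mannan",
    "pectin",
    "starch",
    "inulin",
)

_PACKAGED_CATALOG = "cazy_pbd_catalog.tsv"

_FAMILY_RE = re.compile(r"^(GH|CE|PL|AA)([1-9]\d*)(?:_([1-9]\d*))?$")


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog content."""


class FamilyParseError(CatalogError):
    """Raised when a CAZy family label cannot be parsed."""


@dataclass(frozen=True, order=True)
class FamilyKey:
    """Canonical identifier of a CAZy (sub-)family or the FAE pseudo-family.

    ``FamilyKey("GH", 5, 7)`` renders as ``GH5_7``; ``FamilyKey("FAE")`` has
    neither family number nor subfamily.
    """

    enzyme_class: str
    family_number: Optional[int] = None
    subfamily: Optional[int] = None

    def __post_init__(self) -> None:
        if self.enzyme_class not in ENZYME_CLASSES:
            raise FamilyParseError(f"unknown enzyme class: {self.enzyme_class!r}")
        if self.enzyme_class == "FAE":
            if self.family_number is not None or self.subfamily is not None:
                raise FamilyParseError("FAE carries no family number or subfamily")
        else:
            if self.family_number is None:
                raise FamilyParseError(
                    f"{self.enzyme_class} requires a family number"
                )
        if self.subfamily is not None and self.family_number is None:
            raise FamilyParseError("subfamily requires a family number")

    @property
    def family(self) -> "FamilyKey":
        """This key with any subfamily stripped (GH5_7 → GH5)."""
        if self.subfamily is None:
            return self
        return FamilyKey(self.enzyme_class, self.family_number)

    def __str__(self) -> str:
        if self.enzyme_class == "FAE":
            return "FAE"
        s = f"{self.enzyme_class}{self.family_number}"
        if self.subfamily is not None:
            s += f"_{self.subfamily}"
        return s

    def sort_key(self) -> tuple:
        """Canonical ordering: class order, then family, then subfamily."""
        return (
            ENZYME_CLASSES.index(self.enzyme_class),
            self.family_number or 0,
            -1 if self.subfamily is None else self.subfamily,
        )


def parse_family_key(label: Union[str, FamilyKey]) -> FamilyKey:
    """Parse a CAZy family label like ``"GH5_7"``, ``"CE8"`` or ``"FAE"``.

    Round-trips: ``str(parse_family_key(s)) == s`` for canonical labels.

    Raises
    ------
    FamilyParseError
        If the label is empty, has an unknown class prefix, or a
        non-numeric/zero family or subfamily part.
    """
    if isinstance(label, FamilyKey):
        return label
    if not isinstance(label, str) or not label.strip():
        raise FamilyParseError(f"empty or non-text family label: {label!r}")
    label = label.strip()
    if label == "FAE":
        return FamilyKey("FAE")
    m = _FAMILY_RE.match(label)
    if m is None:
        raise FamilyParseError(f"malformed CAZy family label: {label!r}")
    cls, num, sub = m.groups()
    return FamilyKey(cls, int(num), int(sub) if sub is not None else None)


@dataclass(frozen=True)
class CatalogEntry:
    """One (family, activity, substrate) mapping with a free-text source note."""

    family: FamilyKey
    activity_code: str
    substrate: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise CatalogError(
                f"unknown substrate {self.substrate!r} for {self.family}; "
                f"expected one of {SUBSTRATES}"
            )
        if not self.activity_code:
            raise CatalogError(f"missing activity code for {self.family}")


@dataclass
class Catalog:
    """Validated collection of family→activity→substrate entries with indexes."""

    entries: tuple[CatalogEntry, ...]
    _by_key: dict = field(init=False, repr=False, default_factory=dict)
    _by_substrate: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise CatalogError("catalog is empty")
        seen = set()
        for e in self.entries:
            triple = (e.family, e.activity_code, e.substrate)
            if triple in seen:
                raise CatalogError(f"duplicate catalog entry: {triple}")
            seen.add(triple)
            self._by_key.setdefault(e.family, set()).add(e.substrate)
            self._by_substrate.setdefault(e.substrate, set()).add(e.family)

    @property
    def families(self) -> list[FamilyKey]:
        """All stored (sub-)family keys in canonical order."""
        return sorted(self._by_key, key=FamilyKey.sort_key)

    def substrates_of(self, family: Union[str, FamilyKey]) -> set[str]:
        """Substrates attacked by a family; unknown families yield an empty set.

        A subfamily query with no subfamily-specific entries falls back to the
        bare-family entries; a bare-family query returns the union over its own
        entries and all of its subfamilies' entries (the roll-up view).
        """
        key = parse_family_key(family)
        if key.subfamily is not None:
            exact = self._by_key.get(key)
            if exact:
                return set(exact)
            return set(self._by_key.get(key.family, ()))
        out = set(self._by_key.get(key, ()))
        for stored, subs in self._by_key.items():
            if stored.subfamily is not None and stored.family == key:
                out |= subs
        return out

    def families_for_substrate(self, substrate: str) -> set[FamilyKey]:
        """Stored (sub-)family keys mapped to a substrate (inverse index)."""
        if substrate not in SUBSTRATES:
            raise CatalogError(
                f"unknown substrate {substrate!r}; expected one of {SUBSTRATES}"
            )
        return set(self._by_substrate.get(substrate, ()))

    def multifunctional_families(self) -> list[FamilyKey]:
        """Catalog units mapped to ≥2 distinct substrates, canonically sorted.

        Computed at the stored (sub-)family resolution: subfamilies with
        distinct specificities (e.g. the GH5 endoglucanase vs mannanase
        subfamilies) are separate units and do not make their parent family
        multifunctional.
        """
        return sorted(
            (k for k, subs in self._by_key.items() if len(subs) >= 2),
            key=FamilyKey.sort_key,
        )

    def class_family_counts(self) -> dict[str, int]:
        """Distinct families per enzyme class, subfamilies rolled up.

        GH5_4 and GH5_7 count as the single family GH5; FAE counts as one
        family of its own class.
        """
        fams = {k.family for k in self._by_key}
        return {
            cls: sum(1 for f in fams if f.enzyme_class == cls)
            for cls in ENZYME_CLASSES
        }

    def contains(self, family: Union[str, FamilyKey]) -> bool:
        """True when the family (or its roll-up/fallback) has any substrate."""
        return bool(self.substrates_of(family))


def load_catalog(path: Union[str, Path, None] = None) -> Catalog:
    """Load a catalog TSV; without a path, load the packaged default.

    The dialect is UTF-8 TSV with a header row (``family``, ``activity_code``,
    ``substrate``, optional ``provenance``); ``#`` comment lines are ignored.
    """
    if path is None:
        ref = importlib.resources.files("cazkit") / "data" / _PACKAGED_CATALOG
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise CatalogError(f"catalog file has no content: {path}")
    reader = csv.DictReader(lines, delimiter="\t")
    required = {"family", "activity_code", "substrate"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise CatalogError(
            f"catalog header must contain {sorted(required)}; got {reader.fieldnames}"
        )
    entries = []
    for row in reader:
        entries.append(
            CatalogEntry(
                family=parse_family_key(row["family"]),
                activity_code=row["activity_code"].strip(),
                substrate=row["substrate"].strip(),
                provenance=(row.get("provenance") or "").strip(),
            )
        )
    return Catalog(entries=tuple(entries))


# Module-level functional aliases mirroring the Catalog methods.

def substrates_of(catalog: Catalog, family: Union[str, FamilyKey]) -> set[str]:
    return catalog.substrates_of(family)


def families_for_substrate(catalog: Catalog, substrate: str) -> set[FamilyKey]:
    return catalog.families_for_substrate(substrate)


def multifunctional_families(catalog: Catalog) -> list[FamilyKey]:
    return catalog.multifunctional_families()


def class_family_counts(catalog: Catalog) -> dict[str, int]:
    return catalog.class_family_counts()
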