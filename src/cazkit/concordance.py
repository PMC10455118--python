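"""Ordinal growth profiles and repertoire–growth concordance.

Growth on plate substrates is scored on an ordinal 0–3 scale (0 = no growth,
i.e. the same as the no-carbon control; 3 = good growth, with D-glucose as the
internal reference). Concordance between a species' genomic degradative
potential (per-substrate CAZyme gene totals) and its growth is quantified by a
tie-adjusted (midrank) Spearman correlation, and individual substrates whose
repertoire and growth disagree strongly are flagged in both directions.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
from scipy import stats

__all__ = [
    "GROWTH_LEVELS",
    "GrowthProfile",
    "ConcordanceResult",
    "DiscordantPair",
    "read_growth",
    "load_substrate_map",
    "growth_by_substrate",
    "rank_concordance",
    "flag_discordant",
]

GROWTH_LEVELS = (0, 1, 2, 3)
_REFERENCE_SOURCE = "D-glucose"
_PACKAGED_MAP = "growth_substrate_map.tsv"


@dataclass
class GrowthProfile:
    """Ordinal growth scores of one species over plate carbon sources."""

    species: str
    scores: dict[str, int]
    reference_note: str = "growth on D-glucose is the internal reference"

    def __post_init__(self) -> None:
        for source, score in self.scores.items():
            if score not in GROWTH_LEVELS:
                raise ValueError(
                    f"growth score {score!r} for {self.species}/{source} "
                    f"outside {GROWTH_LEVELS}"
                )
        if _REFERENCE_SOURCE not in self.scores:
            raise ValueError(
                f"growth profile for {self.species} lacks the {_REFERENCE_SOURCE} "
                "reference row"
            )


def read_growth(path: Union[str, Path]) -> dict[str, GrowthProfile]:
    """Read a growth TSV (species, carbon_source, score) into profiles.

    Carbon sources outside the polysaccharide catalog (monosaccharides,
    disaccharides) are kept verbatim; scores must be integers in 0–3 and every
    species needs a D-glucose reference row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"species": str, "carbon_source": str})
    required = {"species", "carbon_source", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"growth file {path} must have columns {sorted(required)}")
    profiles: dict[str, GrowthProfile] = {}
    for species, sub in df.groupby("species", sort=True):
        scores = {}
        for r in sub.itertuples():
            score = float(r.score)
            if not score.is_integer() or int(score) not in GROWTH_LEVELS:
                raise ValueError(
                    f"growth score {r.score!r} for {species}/{r.carbon_source} "
                    f"outside {GROWTH_LEVELS}"
                )
            scores[r.carbon_source] = int(score)
        profiles[species] = GrowthProfile(species=species, scores=scores)
    return profiles


def load_substrate_map(path: Union[str, Path, None] = None) -> dict[str, str]:
    """Carbon-source → polysaccharide mapping (packaged default or custom TSV)."""
    if path is None:
        ref = importlib.resources.files("cazkit") / "data" / _PACKAGED_MAP
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split("\t")
    if header[:2] != ["carbon_source", "substrate"]:
        raise ValueError("substrate map must have columns carbon_source, substrate")
    out = {}
    for ln in lines[1:]:
        source, substrate = ln.split("\t")[:2]
        out[source.strip()] = substrate.strip()
    return out


def growth_by_substrate(
    profile: GrowthProfile, substrate_map: Optional[Mapping[str, str]] = None
) -> dict[str, int]:
    """Collapse plate scores to per-polysaccharide scores.

    When several carbon sources report on one polysaccharide (e.g. apple and
    citrus pectin, or starch and maltose), the best observed growth is taken.
    """
    mapping = dict(substrate_map) if substrate_map is not None else load_substrate_map()
    out: dict[str, int] = {}
    for source, score in profile.scores.items():
        substrate = mapping.get(source)
        if substrate is None:
            continue
        out[substrate] = max(out.get(substrate, 0), score)
    return out


@dataclass(frozen=True)
class DiscordantPair:
    substrate: str
    direction: str  # repertoire_high_growth_low | repertoire_low_growth_high


@dataclass
class ConcordanceResult:
    """Per-species agreement between repertoire totals and growth."""

    species: str
    rank_correlation: Optional[float]
    n_substrates: int
    discordant_pairs: list[DiscordantPair] = field(default_factory=list)
    reason: Optional[str] = None


def rank_concordance(
    totals: pd.DataFrame,
    growth: Mapping[str, GrowthProfile],
    substrate_map: Optional[Mapping[str, str]] = None,
) -> dict[str, ConcordanceResult]:
    """Tie-adjusted Spearman correlation per species.

    ``totals`` is the species × substrate gene-count table; growth scores are
    collapsed onto the same substrate vocabulary first. Species sharing fewer
    than 3 substrates between the two tables get an absent correlation with a
    reason instead of a number.
    """
    mapping = dict(substrate_map) if substrate_map is not None else load_substrate_map()
    results: dict[str, ConcordanceResult] = {}
    for species, profile in growth.items():
        if species not in totals.index:
            results[species] = ConcordanceResult(
                species, None, 0, reason="species absent from repertoire totals"
            )
            continue
        scores = growth_by_substrate(profile, mapping)
        shared = [p for p in totals.columns if p in scores]
        if len(shared) < 3:
            results[species] = ConcordanceResult(
                species, None, len(shared),
                reason=f"only {len(shared)} substrates shared; need ≥ 3",
            )
            continue
        x = totals.loc[species, shared].to_numpy(dtype=float)
        y = [scores[p] for p in shared]
        with warnings.catch_warnings():
            # constant inputs surface as an undefined correlation (reason below)
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(x, y).statistic
        if pd.isna(rho):
            results[species] = ConcordanceResult(
                species, None, len(shared),
                reason="degenerate (constant) totals or growth scores",
            )
        else:
            results[species] = ConcordanceResult(species, float(rho), len(shared))
    return results


def flag_discordant(
    totals: pd.DataFrame,
    growth: Mapping[str, GrowthProfile],
    substrate_map: Optional[Mapping[str, str]] = None,
    high_quantile: float = 0.75,
    low_quantile: float = 0.25,
) -> dict[str, list[DiscordantPair]]:
    """Flag substrates where repertoire size and growth disagree.

    For each substrate the per-species totals define cross-species quantiles.
    A (species, substrate) is flagged ``repertoire_low_growth_high`` when the
    species' total is at or below the low quantile while growth is moderate or
    good (≥ 2), and ``repertoire_high_growth_low`` when the total is at or
    above the high quantile while growth is absent or poor (≤ 1). The two
    directions are mutually exclusive unless the quantiles coincide on a
    constant column, in which case the growth rule decides (a substrate can
    match at most one growth band).
    """
    if not (0.0 < low_quantile < high_quantile < 1.0):
        raise ValueError("need 0 < low_quantile < high_quantile < 1")
    mapping = dict(substrate_map) if substrate_map is not None else load_substrate_map()
    lo = totals.quantile(low_quantile)
    hi = totals.quantile(high_quantile)
    flags: dict[str, list[DiscordantPair]] = {}
    for species, profile in growth.items():
        pairs: list[DiscordantPair] = []
        if species in totals.index:
            scores = growth_by_substrate(profile, mapping)
            for substrate in totals.columns:
                if substrate not in scores:
                    continue
                total = totals.loc[species, substrate]
                score = scores[substrate]
                if total <= lo[substrate] and score >= 2:
                    pairs.append(DiscordantPair(substrate, "repertoire_low_growth_high"))
                elif total >= hi[substrate] and score <= 1:
                    pairs.append(DiscordantPair(substrate, "repertoire_high_growth_low"))
        flags[species] = pairs
    return flags
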