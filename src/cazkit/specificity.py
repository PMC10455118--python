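"""Sugar specificity index (SSI) and sugar-specific gene (SSG) classification.

The SSI is a tau-type expression-specificity statistic. For a gene with
per-condition expression x_1..x_n (n ≥ 2 monosaccharide conditions),

    SSI = sum_i (1 - x̂_i) / (n - 1),   x̂_i = x_i / max_i x_i.

SSI is 0 when expression is identical across conditions and 1 when expression
is confined to a single condition; it is invariant to rescaling the whole
vector. Genes with SSI strictly above the threshold (default 0.7) and a
maximum expression of at least the FPKM floor (default 10) are classified as
sugar-specific genes; each SSG's inducing sugar is the condition of its
maximum expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import Catalog, FamilyKey, SUBSTRATES
from .expression import ConditionMatrix
from .expression import _annotation_map

__all__ = [
    "SpecificityConfig",
    "SpecificityRecord",
    "ssi",
    "inducing_sugar",
    "classify",
    "records_to_frame",
    "ssg_crosstab",
]


@dataclass(frozen=True)
class SpecificityConfig:
    """Thresholds and tie-break order for SSG classification.

    ssi_threshold: strict lower bound on SSI for an SSG call (default 0.7).
    fpkm_threshold: inclusive floor on the gene's maximum FPKM (default 10).
    condition_order: order used to break exact argmax ties; ``None`` means
        the condition order of the data.
    """

    ssi_threshold: float = 0.7
    fpkm_threshold: float = 10.0
    condition_order: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ssi_threshold <= 1.0:
            raise ValueError("ssi_threshold must be in [0, 1]")
        if self.fpkm_threshold < 0:
            raise ValueError("fpkm_threshold must be ≥ 0")


@dataclass(frozen=True)
class SpecificityRecord:
    """Per-gene specificity call.

    ``ssi`` is ``None`` for all-zero genes (the index is undefined there);
    such genes are reported rather than dropped so record counts equal input
    gene counts.
    """

    gene_id: str
    ssi: Optional[float]
    max_fpkm: float
    inducing_condition: Optional[str]
    tie: bool
    is_ssg: bool


def ssi(x: Sequence[float]) -> float:
    """Sugar specificity index of one expression vector.

    Raises ValueError for vectors shorter than 2, with negative entries, or
    identically zero (the normalisation x/max is undefined).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("ssi requires a vector of length ≥ 2")
    if (arr < 0).any():
        raise ValueError("expression values must be non-negative")
    m = arr.max()
    if m == 0:
        raise ValueError("ssi is undefined for an all-zero vector")
    return float(np.sum(1.0 - arr / m) / (arr.size - 1))


def inducing_sugar(
    x: Sequence[float], condition_order: Sequence[str]
) -> tuple[Optional[str], bool]:
    """Condition of maximum expression, with tie flag.

    ``condition_order`` names the conditions positionally (same length as x)
    and doubles as the tie-break order: on exact ties the first tied condition
    in that order wins and ``tie`` is True. All-zero vectors have no inducing
    condition.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size != len(condition_order):
        raise ValueError("x and condition_order lengths differ")
    m = arr.max()
    if m == 0:
        return None, False
    winners = [c for c, v in zip(condition_order, arr) if v == m]
    return winners[0], len(winners) > 1


def classify(
    cm: ConditionMatrix, config: SpecificityConfig = SpecificityConfig()
) -> list[SpecificityRecord]:
    """Compute SSI and the SSG call for every gene of a condition matrix.

    A gene is an SSG iff SSI > ssi_threshold (strict) and its maximum FPKM is
    ≥ fpkm_threshold (inclusive). Each record carries the inducing condition
    (argmax, present whenever the gene has any expression) and a tie flag.
    """
    order = config.condition_order or tuple(cm.conditions)
    if set(order) != set(cm.conditions):
        raise ValueError("condition_order must name exactly the matrix conditions")
    # evaluate argmax in the configured tie-break order
    values = cm.values[list(order)]
    records = []
    for gene_id, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        max_fpkm = float(x.max())
        if max_fpkm == 0:
            records.append(
                SpecificityRecord(gene_id, None, 0.0, None, False, False)
            )
            continue
        s = ssi(x)
        cond, tie = inducing_sugar(x, order)
        is_ssg = s > config.ssi_threshold and max_fpkm >= config.fpkm_threshold
        records.append(SpecificityRecord(gene_id, s, max_fpkm, cond, tie, is_ssg))
    return records


def records_to_frame(records: Iterable[SpecificityRecord]) -> pd.DataFrame:
    """Tabulate specificity records (one row per gene)."""
    return pd.DataFrame(
        [
            dict(
                gene_id=r.gene_id,
                ssi=r.ssi,
                max_fpkm=r.max_fpkm,
                inducing_condition=r.inducing_condition,
                tie=r.tie,
                is_ssg=r.is_ssg,
            )
            for r in records
        ],
        columns=["gene_id", "ssi", "max_fpkm", "inducing_condition", "tie", "is_ssg"],
    )


def ssg_crosstab(
    records: Iterable[SpecificityRecord],
    annotations: Union[Iterable, Mapping[str, Union[str, FamilyKey]]],
    catalog: Catalog,
    condition_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Substrate × inducing-sugar counts of sugar-specific genes.

    Each SSG contributes one count to the cell (substrate, inducing sugar) for
    every substrate its family maps to; SSGs without an annotation or whose
    family has no catalog substrate are tallied under ``other``.
    """
    fam_of = _annotation_map(annotations)
    records = list(records)
    conditions: list[str] = list(condition_order) if condition_order else []
    if not conditions:
        for r in records:
            if r.inducing_condition and r.inducing_condition not in conditions:
                conditions.append(r.inducing_condition)
    table = pd.DataFrame(
        0, index=list(SUBSTRATES) + ["other"], columns=conditions, dtype=int
    )
    for r in records:
        if not r.is_ssg or r.inducing_condition is None:
            continue
        fam = fam_of.get(r.gene_id)
        substrates = catalog.substrates_of(fam) if fam is not None else set()
        if not substrates:
            table.loc["other", r.inducing_condition] += 1
        else:
            for p in substrates:
                table.loc[p, r.inducing_condition] += 1
    return table
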