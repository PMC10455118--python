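"""FPKM expression matrices over monosaccharide growth conditions.

Reads and validates a gene × sample FPKM matrix plus its sample metadata,
collapses replicates to per-condition means, removes genes whose expression
never reaches the detection threshold, and summarizes expression distributions
per substrate group (boxplot statistics with 1.5×IQR outliers).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import Catalog, FamilyKey, parse_family_key, SUBSTRATES
from .repertoire import GeneAnnotation

__all__ = [
    "MONOSACCHARIDE_CONDITIONS",
    "SampleMeta",
    "ExpressionMatrix",
    "ConditionMatrix",
    "ExpressionError",
    "read_expression",
    "collapse_replicates",
    "filter_low_expression",
    "group_expression_summary",
]

#: Default condition vocabulary: the nine plant-derived monosaccharides.
MONOSACCHARIDE_CONDITIONS = (
    "D-glucose",
    "D-fructose",
    "D-galactose",
    "D-mannose",
    "L-rhamnose",
    "D-xylose",
    "L-arabinose",
    "D-galacturonic acid",
    "D-glucuronic acid",
)


class ExpressionError(ValueError):
    """Raised for malformed expression input."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ExpressionError(
                f"replicate must be a positive integer (sample {self.sample_id!r})"
            )


@dataclass
class ExpressionMatrix:
    """Gene × sample FPKM matrix with per-sample metadata.

    ``values`` is indexed by gene id with one column per sample, ordered to
    match ``samples``.
    """

    values: pd.DataFrame
    samples: tuple[SampleMeta, ...]

    def __post_init__(self) -> None:
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ExpressionError("sample columns do not match metadata order")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ExpressionError(f"duplicate gene ids: {dupes}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        out = []
        for s in self.samples:
            if s.condition not in out:
                out.append(s.condition)
        return out


@dataclass
class ConditionMatrix:
    """Gene × condition mean-FPKM matrix; ``n`` conditions with n ≥ 2."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ExpressionError(
                f"need at least 2 conditions, got {self.values.shape[1]}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n(self) -> int:
        return self.values.shape[1]


def read_expression(
    matrix_path: Union[str, Path],
    meta_path: Union[str, Path],
    conditions: Sequence[str] = MONOSACCHARIDE_CONDITIONS,
) -> ExpressionMatrix:
    """Read an FPKM TSV (gene rows, sample columns) and its metadata TSV.

    The metadata must map every sample column to a (condition, replicate)
    pair; the condition set must equal the configured vocabulary, and
    (condition, replicate) pairs must be unique. Sample columns are reordered
    to metadata order.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(meta.columns):
        raise ExpressionError(f"metadata must have columns {sorted(required)}")

    samples = tuple(
        SampleMeta(str(r.sample_id), str(r.condition), int(r.replicate))
        for r in meta.itertuples()
    )
    pairs = [(s.condition, s.replicate) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise ExpressionError("duplicate (condition, replicate) pairs in metadata")
    meta_conditions = {s.condition for s in samples}
    if meta_conditions != set(conditions):
        raise ExpressionError(
            f"metadata conditions {sorted(meta_conditions)} do not equal the "
            f"configured vocabulary {sorted(set(conditions))}"
        )

    known = {s.sample_id for s in samples}
    unknown_cols = [c for c in mat.columns if c not in known]
    if unknown_cols:
        raise ExpressionError(
            f"sample column(s) missing from metadata: {unknown_cols}"
        )
    missing_cols = [s.sample_id for s in samples if s.sample_id not in mat.columns]
    if missing_cols:
        raise ExpressionError(f"metadata sample(s) missing from matrix: {missing_cols}")

    if mat.index.duplicated().any():
        dupes = mat.index[mat.index.duplicated()].tolist()
        raise ExpressionError(f"duplicate gene ids: {dupes}")

    mat = mat[[s.sample_id for s in samples]].astype(float)
    neg = np.argwhere(mat.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ExpressionError(
            f"negative FPKM {mat.iat[i, j]} for gene {mat.index[i]!r} "
            f"in sample {mat.columns[j]!r}"
        )
    return ExpressionMatrix(values=mat, samples=samples)


def collapse_replicates(matrix: ExpressionMatrix) -> ConditionMatrix:
    """Average replicates per condition (arithmetic mean on the FPKM scale)."""
    cond_of = {s.sample_id: s.condition for s in matrix.samples}
    grouped = matrix.values.T.groupby(
        matrix.values.columns.map(cond_of), sort=False
    ).mean().T
    grouped = grouped[matrix.conditions]  # preserve metadata condition order
    return ConditionMatrix(values=grouped)


def filter_low_expression(
    cm: ConditionMatrix, fpkm_threshold: float = 10.0
) -> ConditionMatrix:
    """Drop genes whose maximum over conditions is below the threshold.

    Removal is strict (max < threshold removed), so a gene whose maximum is
    exactly at the threshold is retained. Gene order is preserved.
    """
    if fpkm_threshold < 0:
        raise ExpressionError("fpkm_threshold must be ≥ 0")
    keep = cm.values.max(axis=1) >= fpkm_threshold
    return ConditionMatrix(values=cm.values.loc[keep])


def _annotation_map(
    annotations: Union[Iterable[GeneAnnotation], Mapping[str, Union[str, FamilyKey]]],
) -> dict[str, FamilyKey]:
    if isinstance(annotations, Mapping):
        return {g: parse_family_key(f) for g, f in annotations.items()}
    return {a.gene_id: a.family for a in annotations}


def group_expression_summary(
    cm: ConditionMatrix,
    annotations: Union[Iterable[GeneAnnotation], Mapping[str, Union[str, FamilyKey]]],
    catalog: Catalog,
) -> pd.DataFrame:
    """Boxplot summary of expression per (substrate, condition) gene group.

    For each substrate, the group holds the genes whose annotated family maps
    to it (genes of multifunctional families join every substrate group they
    map to). Quartiles use linear interpolation; whiskers extend to the most
    extreme values within 1.5×IQR of the quartiles; genes beyond the whiskers
    are listed as outliers. Substrates with no genes get an empty entry
    (n_genes 0) rather than an error.
    """
    fam_of = _annotation_map(annotations)
    members: dict[str, list[str]] = {p: [] for p in SUBSTRATES}
    for gene, fam in fam_of.items():
        if gene not in cm.values.index:
            continue
        for substrate in catalog.substrates_of(fam):
            members[substrate].append(gene)

    rows = []
    for substrate in SUBSTRATES:
        genes = sorted(members[substrate])
        for condition in cm.conditions:
            if not genes:
                rows.append(
                    dict(substrate=substrate, condition=condition, n_genes=0,
                         q1=np.nan, median=np.nan, q3=np.nan,
                         whisker_low=np.nan, whisker_high=np.nan, outlier_ids="")
                )
                continue
            vals = cm.values.loc[genes, condition].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            outliers = [g for g, v in zip(genes, vals) if v < lo_fence or v > hi_fence]
            rows.append(
                dict(
                    substrate=substrate,
                    condition=condition,
                    n_genes=len(genes),
                    q1=q1,
                    median=med,
                    q3=q3,
                    whisker_low=inside.min() if inside.size else np.nan,
                    whisker_high=inside.max() if inside.size else np.nan,
                    outlier_ids=",".join(outliers),
                )
            )
    return pd.DataFrame(rows)
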