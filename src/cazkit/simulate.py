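"""Synthetic FPKM matrices with planted sugar-specific genes.

The generator emulates the statistical structure the SSG classification
assumes: each gene has a log-normal expression scale e_g; a *specific* gene
expresses e_g in its (randomly drawn) inducing condition and a leaked fraction
λ·e_g in every other condition, so its noiseless SSI is exactly 1 − λ; a
*background* gene expresses e_g uniformly (noiseless SSI 0); a *silent* gene
sits uniformly below the FPKM detection floor so it exercises the
low-expression filter. Every sample value is multiplied by independent
log-normal(0, σ_n) noise. Expressed (specific and background) scales are drawn
above the detection floor so that the three classes partition genes by
detectability and label recovery tests identify specificity, not abundance.

All draws derive from a single seed through spawned substreams, so outputs are
reproducible and expression/annotation draws are independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats as _st

from .catalog import Catalog
from .expression import (
    ExpressionMatrix,
    MONOSACCHARIDE_CONDITIONS,
    SampleMeta,
)
from .repertoire import GeneAnnotation
from .specificity import SpecificityRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_annotations",
    "recovery_metrics",
    "write_bundle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-signal expression simulation.

    n_genes: total genes.
    conditions: condition names (default: the nine monosaccharides).
    n_replicates: samples per condition.
    frac_specific / frac_silent: fractions of planted sugar-specific and
        silent genes (the rest are uniform background); must sum to ≤ 1.
    leakage: λ ∈ [0, 1), non-inducing expression as a fraction of the
        inducing-condition expression; a specific gene's noiseless SSI is 1−λ.
    base_log_mean / base_log_sd: natural-log mean μ and sd σ of the per-gene
        expression scale (FPKM units after exponentiation).
    noise_log_sd: σ_n of the multiplicative log-normal per-sample noise.
    detection_floor: FPKM level separating expressed from silent genes;
        matches the default low-expression filter threshold.
    seed: master seed; all substreams derive from it.
    """

    n_genes: int = 1000
    conditions: tuple[str, ...] = MONOSACCHARIDE_CONDITIONS
    n_replicates: int = 3
    frac_specific: float = 0.1
    leakage: float = 0.1
    base_log_mean: float = 5.0
    base_log_sd: float = 1.0
    noise_log_sd: float = 0.2
    frac_silent: float = 0.1
    detection_floor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if not 0.0 <= self.frac_specific <= 1.0 or not 0.0 <= self.frac_silent <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
        if self.frac_specific + self.frac_silent > 1.0:
            raise ValueError("frac_specific + frac_silent must be ≤ 1")
        if not 0.0 <= self.leakage < 1.0:
            raise ValueError("leakage must be in [0, 1)")
        if self.base_log_sd < 0 or self.noise_log_sd < 0:
            raise ValueError("standard deviations must be ≥ 0")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth per synthetic gene.

    ``table`` is indexed by gene id with columns ``label`` (specific /
    background / silent), ``true_condition`` (specific genes only) and
    ``true_ssi_noiseless`` (1−λ for specific genes, 0 otherwise).
    """

    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def with_label(self, label: str) -> list[str]:
        return list(self.table.index[self.table["label"] == label])


def _expressed_scales(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Log-normal(μ, σ) scales left-truncated at the detection floor."""
    log_floor = np.log(cfg.detection_floor)
    if cfg.base_log_sd == 0:
        if np.exp(cfg.base_log_mean) < cfg.detection_floor:
            raise ValueError(
                "base_log_sd = 0 with exp(base_log_mean) below the detection "
                "floor leaves no admissible expressed scale"
            )
        return np.full(n, np.exp(cfg.base_log_mean))
    a = _st.norm.cdf(log_floor, loc=cfg.base_log_mean, scale=cfg.base_log_sd)
    u = rng.uniform(a, 1.0, size=n)
    return np.exp(_st.norm.ppf(u, loc=cfg.base_log_mean, scale=cfg.base_log_sd))


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate an FPKM matrix with planted specificity and its ground truth."""
    ss = np.random.SeedSequence(config.seed).spawn(2)[0]
    rng = np.random.default_rng(ss)
    n = config.n_genes
    n_specific = int(round(config.frac_specific * n))
    n_silent = int(round(config.frac_silent * n))
    if n_specific + n_silent > n:  # rounding collision at extreme fractions
        n_silent = n - n_specific
    n_background = n - n_specific - n_silent

    width = max(4, len(str(n - 1)))
    genes = [f"g{i:0{width}d}" for i in range(n)]
    labels = (
        ["specific"] * n_specific + ["background"] * n_background + ["silent"] * n_silent
    )

    conditions = list(config.conditions)
    k = len(conditions)
    mean = np.zeros((n, k))

    scales = np.empty(n)
    n_expressed = n_specific + n_background
    scales[:n_expressed] = _expressed_scales(rng, n_expressed, config)
    # silent genes: uniform pattern rescaled strictly below the detection floor
    scales[n_expressed:] = config.detection_floor * rng.uniform(0.05, 0.95, size=n_silent)

    true_condition = np.array([None] * n, dtype=object)
    cond_idx = rng.integers(0, k, size=n_specific)
    for i in range(n_specific):
        mean[i, :] = config.leakage * scales[i]
        mean[i, cond_idx[i]] = scales[i]
        true_condition[i] = conditions[cond_idx[i]]
    mean[n_specific:, :] = scales[n_specific:, None]

    samples = tuple(
        SampleMeta(f"{c.replace(' ', '_')}_r{r}", c, r)
        for c in conditions
        for r in range(1, config.n_replicates + 1)
    )
    values = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        ci = conditions.index(s.condition)
        noise = (
            np.exp(rng.normal(0.0, config.noise_log_sd, size=n))
            if config.noise_log_sd > 0
            else 1.0
        )
        values[:, j] = mean[:, ci] * noise

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples]),
        samples=samples,
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "label": labels,
                "true_condition": true_condition,
                "true_ssi_noiseless": [
                    1.0 - config.leakage if lb == "specific" else 0.0 for lb in labels
                ],
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )
    return matrix, truth


def simulate_annotations(
    config: SimulationConfig, catalog: Catalog, species: str = "synthetic"
) -> list[GeneAnnotation]:
    """Assign each synthetic gene a catalog family, drawn uniformly at random."""
    ss = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(ss)
    families = catalog.families
    width = max(4, len(str(config.n_genes - 1)))
    return [
        GeneAnnotation(
            gene_id=f"g{i:0{width}d}",
            species=species,
            family=families[rng.integers(0, len(families))],
        )
        for i in range(config.n_genes)
    ]


def recovery_metrics(
    records: Iterable[SpecificityRecord], truth: SyntheticTruth
) -> dict[str, float]:
    """Recovery of the planted labels by the SSG classification.

    sensitivity: called SSGs among planted specific genes;
    specificity: non-calls among non-specific (background + silent) genes;
    false_discovery_rate: non-specific genes among called SSGs (0 when no
    SSG is called);
    inducing_condition_accuracy: correct inducing sugar among true positives
    (NaN when there are none).
    """
    records = list(records)
    rec_genes = {r.gene_id for r in records}
    truth_genes = set(truth.genes)
    if rec_genes != truth_genes:
        raise ValueError(
            "record and truth gene sets differ: "
            f"{len(rec_genes - truth_genes)} extra, {len(truth_genes - rec_genes)} missing"
        )
    label = truth.table["label"]
    true_cond = truth.table["true_condition"]
    tp = fp = fn = tn = 0
    correct_cond = 0
    for r in records:
        is_specific = label[r.gene_id] == "specific"
        if r.is_ssg and is_specific:
            tp += 1
            if r.inducing_condition == true_cond[r.gene_id]:
                correct_cond += 1
        elif r.is_ssg:
            fp += 1
        elif is_specific:
            fn += 1
        else:
            tn += 1
    n_specific = tp + fn
    n_other = fp + tn
    n_called = tp + fp
    return {
        "sensitivity": tp / n_specific if n_specific else float("nan"),
        "specificity": tn / n_other if n_other else float("nan"),
        "false_discovery_rate": fp / n_called if n_called else 0.0,
        "inducing_condition_accuracy": correct_cond / tp if tp else float("nan"),
    }


def write_bundle(
    config: SimulationConfig, catalog: Catalog, out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Write the standard synthetic bundle (expression, metadata, annotations, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_expression(config)
    annotations = simulate_annotations(config, catalog)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
    }
    matrix.values.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")
    pd.DataFrame(
        [dict(sample_id=s.sample_id, condition=s.condition, replicate=s.replicate)
         for s in matrix.samples]
    ).to_csv(paths["metadata"], sep="\t", index=False)
    pd.DataFrame(
        [dict(species=a.species, gene_id=a.gene_id, family=str(a.family))
         for a in annotations]
    ).to_csv(paths["annotations"], sep="\t", index=False)
    truth.table.to_csv(paths["truth"], sep="\t")
    return paths
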