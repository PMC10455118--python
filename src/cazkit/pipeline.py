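"""End-to-end orchestration: repertoire → expression summaries → SSGs → concordance.

A single configuration (YAML file or dict) names the inputs per species and
the classification thresholds; `run_pipeline` executes every stage, writes one
TSV per result, and records a machine-readable manifest (package version,
thresholds, input checksums, and a gene-count ledger per filter so records in
= records out + records filtered always balances).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from . import __version__
from .catalog import load_catalog
from .concordance import (
    flag_discordant,
    load_substrate_map,
    rank_concordance,
    read_growth,
)
from .expression import (
    MONOSACCHARIDE_CONDITIONS,
    collapse_replicates,
    filter_low_expression,
    group_expression_summary,
    read_expression,
)
from .repertoire import count_families, read_annotations, substrate_totals, uniqueness_report
from .specificity import SpecificityConfig, classify, records_to_frame, ssg_crosstab

__all__ = ["PipelineConfig", "SpeciesInputs", "PipelineError", "run_pipeline"]

logger = logging.getLogger("cazkit")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and offending file."""

    def __init__(self, stage: str, detail: str, path: Optional[Union[str, Path]] = None):
        self.stage = stage
        self.path = str(path) if path is not None else None
        suffix = f" [{self.path}]" if self.path else ""
        super().__init__(f"stage {stage!r}: {detail}{suffix}")


@dataclass
class SpeciesInputs:
    name: str
    annotations: Optional[Path] = None
    expression: Optional[Path] = None
    metadata: Optional[Path] = None


@dataclass
class PipelineConfig:
    out_dir: Path
    species: list[SpeciesInputs]
    catalog: Optional[Path] = None
    growth: Optional[Path] = None
    substrate_map: Optional[Path] = None
    grouping: dict[str, str] = field(default_factory=dict)
    conditions: tuple[str, ...] = MONOSACCHARIDE_CONDITIONS
    ssi_threshold: float = 0.7
    fpkm_threshold: float = 10.0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent

        def resolve(p: Optional[str]) -> Optional[Path]:
            return (base / p).resolve() if p else None

        species = [
            SpeciesInputs(
                name=s["name"],
                annotations=resolve(s.get("annotations")),
                expression=resolve(s.get("expression")),
                metadata=resolve(s.get("metadata")),
            )
            for s in raw.get("species", [])
        ]
        return cls(
            out_dir=Path(raw.get("out_dir", "cazkit_out")),
            species=species,
            catalog=resolve(raw.get("catalog")),
            growth=resolve(raw.get("growth")),
            substrate_map=resolve(raw.get("substrate_map")),
            grouping=dict(raw.get("grouping", {})),
            conditions=tuple(raw.get("conditions", MONOSACCHARIDE_CONDITIONS)),
            ssi_threshold=float(raw.get("ssi_threshold", 0.7)),
            fpkm_threshold=float(raw.get("fpkm_threshold", 10.0)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _require(stage: str, path: Optional[Path]) -> Path:
    if path is None or not Path(path).exists():
        raise PipelineError(stage, "required input file is missing", path)
    return Path(path)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; return the output paths and key tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "cazkit_version": __version__,
        "thresholds": {
            "ssi_threshold": config.ssi_threshold,
            "fpkm_threshold": config.fpkm_threshold,
        },
        "conditions": list(config.conditions),
        "inputs": {},
        "gene_ledger": {},
    }
    outputs: dict[str, Any] = {"out_dir": out}

    try:
        catalog = load_catalog(config.catalog)
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise PipelineError("catalog", str(exc), config.catalog) from exc
    if config.catalog:
        manifest["inputs"]["catalog"] = _sha256(_require("catalog", config.catalog))

    # --- repertoire ---------------------------------------------------------
    annotations = []
    for sp in config.species:
        if sp.annotations is None:
            continue
        path = _require("annotations", sp.annotations)
        manifest["inputs"][f"annotations:{sp.name}"] = _sha256(path)
        try:
            annotations.extend(read_annotations(path))
        except Exception as exc:
            raise PipelineError("annotations", str(exc), path) from exc
    if annotations:
        rep = count_families(annotations, catalog)
        totals = substrate_totals(rep, catalog)
        rep.counts.rename_axis("species").to_csv(out / "repertoire.tsv", sep="\t")
        rep.off_catalog.rename_axis("species").to_csv(out / "off_catalog.tsv", sep="\t")
        totals.rename_axis("species").to_csv(out / "substrate_totals.tsv", sep="\t")
        outputs["repertoire"] = rep
        outputs["substrate_totals"] = totals
        manifest["gene_ledger"]["annotations_in"] = len(annotations)
        manifest["gene_ledger"]["annotations_on_catalog"] = int(rep.counts.to_numpy().sum())
        manifest["gene_ledger"]["annotations_off_catalog"] = int(
            rep.off_catalog.to_numpy().sum() if rep.off_catalog.size else 0
        )
        if config.grouping:
            report = uniqueness_report(rep, config.grouping)
            report.to_frame().to_csv(out / "uniqueness.tsv", sep="\t", index=False)
            outputs["uniqueness"] = report

    # --- expression & specificity, per species ------------------------------
    spec_cfg = SpecificityConfig(
        ssi_threshold=config.ssi_threshold, fpkm_threshold=config.fpkm_threshold
    )
    ann_by_species: dict[str, dict[str, Any]] = {}
    for a in annotations:
        ann_by_species.setdefault(a.species, {})[a.gene_id] = a.family
    for sp in config.species:
        if sp.expression is None:
            continue
        mpath = _require("expression", sp.expression)
        mepath = _require("metadata", sp.metadata)
        manifest["inputs"][f"expression:{sp.name}"] = _sha256(mpath)
        manifest["inputs"][f"metadata:{sp.name}"] = _sha256(mepath)
        try:
            em = read_expression(mpath, mepath, conditions=config.conditions)
            cm = collapse_replicates(em)
            filtered = filter_low_expression(cm, config.fpkm_threshold)
        except Exception as exc:
            raise PipelineError("expression", str(exc), mpath) from exc
        n_in, n_kept = len(cm.genes), len(filtered.genes)
        logger.info(
            "%s: %d genes in, %d kept, %d below FPKM %.3g",
            sp.name, n_in, n_kept, n_in - n_kept, config.fpkm_threshold,
        )
        manifest["gene_ledger"][f"{sp.name}:genes_in"] = n_in
        manifest["gene_ledger"][f"{sp.name}:genes_kept"] = n_kept
        manifest["gene_ledger"][f"{sp.name}:genes_filtered"] = n_in - n_kept
        assert n_in == n_kept + (n_in - n_kept)

        ann_map = ann_by_species.get(sp.name, {})
        summary = group_expression_summary(filtered, ann_map, catalog)
        summary.to_csv(out / f"{sp.name}.expression_summary.tsv", sep="\t", index=False)

        records = classify(cm, spec_cfg)
        records_to_frame(records).to_csv(
            out / f"{sp.name}.ssg_records.tsv", sep="\t", index=False
        )
        crosstab = ssg_crosstab(records, ann_map, catalog, condition_order=config.conditions)
        crosstab.rename_axis("substrate").to_csv(out / f"{sp.name}.ssg_crosstab.tsv", sep="\t")
        outputs[f"records:{sp.name}"] = records
        outputs[f"crosstab:{sp.name}"] = crosstab

    # --- concordance ---------------------------------------------------------
    if config.growth is not None:
        gpath = _require("concordance", config.growth)
        manifest["inputs"]["growth"] = _sha256(gpath)
        if "substrate_totals" not in outputs:
            raise PipelineError(
                "concordance", "growth given but no repertoire totals available", gpath
            )
        try:
            growth = read_growth(gpath)
            smap = load_substrate_map(config.substrate_map)
        except Exception as exc:
            raise PipelineError("concordance", str(exc), gpath) from exc
        totals = outputs["substrate_totals"]
        results = rank_concordance(totals, growth, smap)
        flags = flag_discordant(totals, growth, smap)
        conc_rows, disc_rows = [], []
        for species, res in sorted(results.items()):
            conc_rows.append(
                dict(species=species, rank_correlation=res.rank_correlation,
                     n_substrates=res.n_substrates, reason=res.reason or "")
            )
            for pair in flags.get(species, []):
                disc_rows.append(
                    dict(species=species, substrate=pair.substrate, direction=pair.direction)
                )
        pd.DataFrame(conc_rows).to_csv(out / "concordance.tsv", sep="\t", index=False)
        pd.DataFrame(
            disc_rows, columns=["species", "substrate", "direction"]
        ).to_csv(out / "discordant.tsv", sep="\t", index=False)
        outputs["concordance"] = results
        outputs["discordant"] = flags

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    outputs["manifest"] = manifest
    return outputs
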