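# cazkit

Comparative analysis of fungal plant-biomass-degrading CAZymes: genomic
repertoires, sugar-specific gene expression, and growth concordance.

Fungi decompose plant polysaccharides (cellulose, xylan, xyloglucan, mannan,
pectin, starch, inulin) with carbohydrate-active enzymes (CAZymes) classified
into GH, CE, PL and AA families plus feruloyl esterases (FAE). `cazkit` is for
researchers comparing species on three levels:

1. **Repertoire** — aggregate gene-level CAZy annotations into species ×
   family counts and per-polysaccharide gene totals through a curated
   family → activity → substrate catalog; detect families unique to one
   species or exclusive to one taxonomic group; merge ortholog groupings from
   independent callers (union of co-memberships, connected components).
2. **Expression specificity** — from gene × sample FPKM matrices over
   monosaccharide growth conditions, compute each gene's **sugar specificity
   index** (a tau-type statistic),

   SSI = Σᵢ (1 − x̂ᵢ) / (n − 1),  x̂ᵢ = xᵢ / maxᵢ xᵢ,

   over the n ≥ 2 conditions; call **sugar-specific genes (SSGs)** where
   SSI > 0.7 and the maximum FPKM is ≥ 10, and assign each SSG the condition
   of its maximum expression as its **inducing sugar**.
3. **Concordance** — encode ordinal growth profiles (0 = no growth … 3 = good,
   D-glucose as internal reference) and quantify agreement between
   per-substrate gene totals and growth with a tie-adjusted Spearman
   correlation, flagging substrates where a small repertoire meets good growth
   or a large repertoire meets poor growth.

A seeded synthetic-data generator plants sugar-specific genes with known
leakage λ (noiseless SSI exactly 1 − λ), background and silent genes, and
log-normal multiplicative noise, so the full pipeline is testable end to end
with recovery metrics (sensitivity, FDR, inducing-sugar accuracy).

## Worked example

```python
from cazkit import (
    SimulationConfig, classify, collapse_replicates, load_catalog,
    recovery_metrics, simulate_expression, ssi,
)

catalog = load_catalog()
print(len(catalog.multifunctional_families()))   # 10
print(catalog.class_family_counts())
# {'GH': 39, 'CE': 6, 'PL': 5, 'AA': 4, 'FAE': 1}
print(sorted(catalog.substrates_of("GH12")))     # ['cellulose', 'xyloglucan']

print(ssi([10, 5, 0, 0]))                        # 0.8333333333333334

cfg = SimulationConfig(seed=2024)  # 1000 genes, 9 sugars, 3 replicates,
                                   # λ=0.1, σ_n=0.2, 10% specific, 10% silent
matrix, truth = simulate_expression(cfg)
records = classify(collapse_replicates(matrix))
print(recovery_metrics(records, truth))
# {'sensitivity': 1.0, 'specificity': 1.0,
#  'false_discovery_rate': 0.0, 'inducing_condition_accuracy': 1.0}
```

The catalog census says the packaged mapping spans 39 GH, 6 CE, 5 PL and 4 AA
families plus FAE, ten of which attack more than one polysaccharide. The SSI
of `[10, 5, 0, 0]` is 5/6: expression is concentrated but not exclusive. The
recovery run shows that under moderate noise the SSG classification recovers
every planted sugar-specific gene with no false calls and assigns every one
its true inducing sugar.

From a shell, the same stages are available as subcommands:

```bash
cazkit simulate --seed 11 --out-dir sim/
cazkit classify --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --annotations sim/annotations.tsv --out-dir calls/
cazkit run --config pipeline.yaml
```

## Layout

- `src/cazkit/catalog.py` — family keys, packaged substrate catalog, censuses
- `src/cazkit/repertoire.py` — family counts, substrate totals, uniqueness, ortholog merge
- `src/cazkit/expression.py` — FPKM IO, replicate collapse, filtering, group summaries
- `src/cazkit/specificity.py` — SSI, SSG classification, inducing sugars, crosstabs
- `src/cazkit/concordance.py` — growth profiles, rank concordance, discordance flags
- `src/cazkit/simulate.py` — planted-signal generator and recovery metrics
- `src/cazkit/pipeline.py`, `src/cazkit/cli.py` — orchestration and CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
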