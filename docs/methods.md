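# Methods

## The catalog and its conventions

The packaged table maps 77 (family, activity, substrate) triples covering
39 GH, 6 CE, 5 PL and 4 AA families plus feruloyl esterases (FAE) onto seven
plant polysaccharides: cellulose, xylan, xyloglucan, mannan, pectin, starch,
inulin. FAE is modelled as a pseudo-family (its own enzyme class, no family
number) so it participates uniformly in counting and multifunctionality.

Two resolutions coexist deliberately:

- **Catalog units are (sub-)families.** Where subfamilies have distinct
  specificities they are separate rows — GH5_4/GH5_5/GH5_22 are
  endoglucanases (cellulose), GH5_7 a mannanase, GH5_16 a pectin hydrolase.
  Multifunctionality is judged at this resolution: a family is
  multifunctional when one catalog unit maps to ≥ 2 substrates. The packaged
  table yields exactly ten such units (GH2, GH3, GH12, GH31, GH35, GH43,
  GH51, GH54, CE16, FAE). Treating GH5 as one unit would wrongly call it
  multifunctional merely because its subfamilies divide the substrates
  between them.
- **Class censuses roll up.** Counting "how many GH families", GH5 and GH13
  each count once regardless of subfamily rows.

Family-level queries return the roll-up union (`substrates_of("GH5")` →
cellulose, mannan, pectin); a subfamily query with no subfamily-specific rows
falls back to the bare-family rows. Families mentioned with an activity but
no explicit substrate are assigned the substrate of the enzymatic context
they appear in. FAE maps to xylan and pectin: ferulate esterifies
arabinoxylan and pectic side chains, which is what makes it multifunctional.

Annotations are counted at the resolution they arrive in: a gene annotated
`GH5_7` is tallied under GH5_7. Substrate totals resolve each annotated key
through the fallback/roll-up query, and a gene of a family mapped to k
substrates contributes a full count to each of the k totals (not a 1/k
split): the totals answer "how many genes could act on this polysaccharide",
which is monotone under adding annotations. Annotated families absent from
the catalog go to a side table and never enter substrate totals. Presence for
uniqueness reports means count ≥ 1; a family is species-unique when exactly
one species carries it and group-exclusive when ≥ 2 species carry it, all in
one grouping.

Ortholog sets from two callers are merged by taking connected components of
the graph whose edges join genes co-grouped in either input. This is the
coarsest common refinement: commutative, associative, idempotent; singletons
stay singletons.

## Expression handling

Input is a gene × sample FPKM matrix plus sample metadata (condition,
replicate). The default condition vocabulary is the nine monosaccharides
(D-glucose, D-fructose, D-galactose, D-mannose, L-rhamnose, D-xylose,
L-arabinose, D-galacturonic acid, D-glucuronic acid); datasets with a
different or smaller panel pass their own vocabulary, and all downstream
statistics take the condition count n from the data (n ≥ 2). Missing values
are not permitted — quantification upstream must emit complete matrices.

Replicates are collapsed by the arithmetic mean on the FPKM scale before any
specificity computation. The mean (rather than the median) keeps the collapse
linear, matching the linear form of the specificity index; distribution
summaries are computed on replicate means for the same reason. Genes whose
maximum mean FPKM over conditions is below 10 are removed; the wording of the
rule is strict ("below"), so a maximum of exactly 10 is retained.

Per-substrate expression summaries are Tukey boxplot statistics per
(substrate, condition): quartiles with linear interpolation, whiskers at the
most extreme values within 1.5 × IQR of the quartiles, genes beyond the
fences reported as outliers. Genes of multifunctional families appear in
every substrate group they map to; an empty group is an empty summary entry,
not an error. Summaries operate on raw FPKM — any log transform is a display
concern, not part of the statistic.

## Sugar specificity index and SSG calls

For per-condition expression x₁…xₙ,

    SSI = Σᵢ (1 − x̂ᵢ) / (n − 1),   x̂ᵢ = xᵢ / maxᵢ xᵢ.

Properties relied on throughout: SSI ∈ [0, 1]; 0 iff expression is uniform;
1 iff exactly one condition is expressed; invariant to rescaling the vector;
decreasing any non-maximal entry never decreases it; and for the planted
pattern (one entry e, all others λ·e with 0 ≤ λ < 1) SSI = 1 − λ exactly.
The index is undefined for an all-zero vector; at the collection level such
genes get an absent SSI and a negative call rather than an error, so record
counts always equal input gene counts.

A gene is a sugar-specific gene (SSG) iff SSI > 0.7 (strict) and its maximum
FPKM is ≥ 10 (inclusive) — both thresholds configurable. Its inducing sugar
is the condition of maximum expression; exact ties are broken by the
configured condition order and flagged. SSI is computed per species on its
own condition matrix; there is no cross-species pooling. The SSG × substrate
crosstab counts each SSG once per substrate its family maps to, with
unannotated SSGs under "other". No significance test is attached to an SSG
call: the index is descriptive, and no permutation null is defined for it
here.

## Growth profiles and concordance

Growth on plate substrates is ordinal: 0 (no growth, i.e. indistinguishable
from the no-carbon control), 1 (poor), 2 (moderate), 3 (good), with D-glucose
required as the internal reference in every profile. The four-level scale is
a convention of this package — plate assays support only relative judgments.
A packaged, editable mapping sends plate carbon sources to the polysaccharide
they report on (beechwood xylan → xylan; guar gum → mannan; apple and citrus
pectin → pectin; soluble starch and maltose → starch; inulin and sucrose →
inulin; cellulose and cellobiose → cellulose); when several sources share a
substrate the best observed growth is taken, since any of them demonstrates
the capability.

Concordance per species is the tie-adjusted (midrank) Spearman correlation
between per-substrate gene totals and growth scores over the shared
substrates; fewer than 3 shared substrates, or a constant vector, yields an
absent result with a reason rather than a number. Discordance flags compare a
species' total for a substrate with the cross-species quantiles of that
substrate's totals: at or below the 0.25 quantile with growth ≥ 2 flags
`repertoire_low_growth_high`; at or above the 0.75 quantile with growth ≤ 1
flags `repertoire_high_growth_low`. The growth bands are disjoint, so the two
directions are mutually exclusive per (species, substrate).

## Synthetic data generator

The generator emulates the structure the SSG classification assumes, not real
RNA-seq in full. Each gene draws a scale e_g = exp(N(μ, σ²)) with defaults
μ = 5.0 (≈ 150 FPKM), σ = 1.0 — a realistic spread for expressed fungal
genes. Three classes partition the genes:

- **specific** (default 10%): pre-noise mean e_g in one uniformly drawn
  inducing condition and λ·e_g elsewhere; leakage default λ = 0.1, so the
  noiseless SSI is 0.9;
- **background** (remainder): mean e_g in every condition (noiseless SSI 0);
- **silent** (default 10%): uniform pattern rescaled strictly below the
  detection floor (10 FPKM, matching the filter default) to exercise the
  low-expression path.

Expressed-class scales are drawn from the log-normal left-truncated at the
detection floor. This is a deliberate design: the classes partition genes by
detectability, so recovery metrics measure the classification of
specificity rather than the incidental abundance of a draw, and the
noiseless closed-form recovery (every planted gene at SSI = 1 − λ, all
called at λ = 0.1, none at λ = 0.5) holds for every seed. Every sample value
is multiplied by independent exp(N(0, σ_n²)) noise, σ_n = 0.2 by default —
multiplicative log-normal dispersion is the simplest model matching FPKM's
right-skew; heavier-tailed alternatives belong behind the same interface.
Defaults: 1000 genes, the nine monosaccharide conditions, 3 replicates. One
master seed feeds spawned substreams for expression and annotation draws, so
the two are independently reproducible.

What the generator does not emulate: gene-length and library-size coupling,
count discreteness at low expression, correlated condition responses
(co-regulation), batch structure, and partial induction across related
sugars. Passing recovery tests therefore show the statistic and its
thresholds behave as designed under the stated noise model — not that real
transcriptomes are this clean.

Recovery metrics: sensitivity = called SSGs among planted specific genes;
specificity = non-calls among the rest; FDR = non-specific among calls (0
when nothing is called); inducing-condition accuracy over true positives
(undefined, NaN, when there are none).

## Numerical and engineering choices

- Tie-break for the inducing sugar: first tied condition in the configured
  order, with an explicit flag; ties are measure-zero under the noise model
  but exact in small fixtures.
- Quantiles (boxplots, discordance bands) use linear interpolation, numpy's
  default.
- Problem sizes in the shipped experiments (500 genes noiseless, 1000 genes
  stochastic, 100-instance oracle sweeps) were chosen so each suite
  completes in seconds while estimates are stable to well within the asserted
  margins.
- The pipeline writes a manifest (package version, thresholds, input
  checksums, per-stage gene ledger) so reruns are auditable; identical inputs
  give byte-identical TSVs.

## Known limitations

- The catalog is reconstructed from enzymology of the seven polysaccharides;
  it is not a dump of the CAZy database, and activities carried by families
  outside it are invisible to substrate totals.
- Substrate totals weight every gene equally; no expression or secretion
  weighting.
- The four-level growth scale and the 0.25/0.75 discordance bands are
  conventions; with few species the quantiles are coarse.
- SSI on few conditions (small n) is coarse-grained; the package enforces
  only n ≥ 2 and reports n alongside results.
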