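# heritnet

Multi-region transcriptomic inference for paternal inheritance of
cocaine-seeking behavior.

In the underlying experimental design, sires are assigned to cocaine
self-administration (CSA), yoked cocaine infusion (CY, same dose without
the operant behavior) or saline self-administration (SSA), and their male
offspring are profiled by RNA-seq in seven reward-circuitry regions (OFC,
mPFC, NAc, dStr, dHip, BLA, VTA) under drug-naive and cocaine
self-administration states. Comparing the three arms separates what the
drug itself transmits from what voluntary drug *seeking* transmits. This
package implements the full analysis chain as a tested, reusable library
for anyone running three-group, multi-region designs of this shape:

* **Differential expression** — median-of-ratios normalization, per-gene
  Welch tests for the three pairwise contrasts in every (region, state)
  cell, DEG calling under configurable p/fold-change rules, DEG count
  grids with a pervasively-changed-region flag.
* **Pattern attribution** — with x = effect(CSA−SSA), y = effect(CY−SSA)
  and x−y = effect(CSA−CY), the realizable significance/direction triples
  form exactly 12 expression patterns; genes aggregate into class A
  ("drug exposure": both vs-SSA contrasts consistent), B ("highly
  motivated seeking": significant vs SSA and vs CY, unchanged CY vs SSA)
  and C ("passive infusion": the mirror of B).
* **RRHO** — stratified rank-rank hypergeometric overlap maps between
  regional signatures, quadrant-resolved, computed in log space so
  −log10 P ≫ 50 survives.
* **Co-expression networks** — WGCNA-style soft-thresholded adjacency,
  topological overlap, deterministic module detection with eigengene
  merging, pattern and gene-set enrichment (GMT), synaptic up/down splits,
  module conservation, **module differential connectivity (MDC)** with
  sample-permutation significance, and intramodular hub ranking.
* **Regulons** — Jaccard clustering of an upstream TF→target table into
  co-regulatory groups, gene cluster fractions, hub overlay, and a seeded
  2-D embedding with a cluster-concordance score.
* **Behavior & neurochemistry** — progressive-ratio scoring and top-k
  "highly motivated" selection, exact Wilcoxon rank-sum group comparisons
  (full enumeration with midranks), relative-change summaries and
  cross-region correlation structure for analyte panels.
* **Synthetic data** — a negative-binomial simulator for the full
  3 × 2 × 7 design with planted pattern genes, group-specific co-expression
  modules (latent-factor loadings give within-module correlation =
  loading²), behavior and analyte effects, and regulon blocks — every
  pipeline claim is testable against planted truth.

## Worked example

Generate a synthetic study with planted ground truth and run every stage:

```bash
heritnet simulate --out demo --seed 7 --n-genes 800
heritnet all --config demo/config.yaml --out demo_report
```

or from Python:

```python
from heritnet.pipeline import make_synthetic_inputs, run_all
cfg = make_synthetic_inputs("demo", seed=7, n_genes=800)
summary = run_all(cfg, "demo_report")
```

The run writes per-stage TSV tables (DE calls, patterns, RRHO screen, MDC,
conservation, hubs, regulon clusters, behavior and analyte tests) plus a
content-hashed `summary.json`. For seed 7 the summary contains, among
other fields:

```
"pattern_counts":  {"A": 109, "B": 141, "C": 99, "none": 10851}
"rrho_max_pair":   {"region_a": "VTA", "region_b": "dStr", "max_neglog10p": 14.16}
"behavior_p":      {"CSA_vs_CY": 0.00063, "CSA_vs_SSA": 2.4e-05, "CY_vs_SSA": 0.68}
"analyte_min_p":   0.00794
"recovery":        {"pattern_B_recall": 0.68, ...}
```

Reading: pattern attribution finds more B genes than A or C (the generator
plants CSA-specific module structure inside the B class); the strongest
cross-region rank concordance is between dStr and VTA, the two regions the
planted B effects share; CSA offspring breakpoints separate from both
control arms while CY and SSA do not differ; the smallest analyte
Wilcoxon p (0.0079 = 2/252) is the exact floor for complete separation at
n = 5 per group; and about two-thirds of planted highly-motivated genes
are recovered at 4 animals per cell — the per-gene attribution counts on
each gene being detected in at least one region cell.

Identical config and seed reproduce the summary byte for byte.

## Layout

```
src/heritnet/
  synthetic_data.py   design grid, planted truth, NB/behavior/analyte/regulon simulators
  stats_core.py       exact tails, Fisher, Wilcoxon enumeration, BH, Pearson
  diffexpr.py         size factors, normalization, Welch DE, DEG calls and grids
  patterning.py       sign-triple enumeration, A/B/C attribution, FC consistency
  rrho.py             ranked signatures, stratified RRHO maps and screens
  coexpr_network.py   soft threshold, TOM, modules, enrichment, MDC, hubs
  regulon.py          TF clustering, fractions, hub overlay, embedding
  behavior.py         PR scores, top-k selection, intake correlation
  regionstats.py      analyte Wilcoxon panels, relative change, correlation structure
  pipeline.py / cli.py  orchestration and the `heritnet` command
```

See `docs/methods.md` for the models, assumptions, numerical choices and
known limitations.
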