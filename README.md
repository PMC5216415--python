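# splicebalance

Exon-level splicing-imbalance analysis for two-group expression studies,
built for exon-array-style data (one probe per exon, log2 intensities)
such as breast-cancer subtype vs. normal-tissue comparisons. It is aimed
at computational biologists who want to separate *splicing-driven*
transcriptional differences from ordinary whole-gene differential
expression, and to ask whether either level carries prognostic
information.

## What it computes

**Splicing index (SI).** For probe *p* of gene *g* in sample *s*,

    SI_ps = 2^x_ps / Σ_{q ∈ g} 2^x_qs

— the fraction of the gene's total linear-scale expression contributed
by that exon. SI sums to 1 over a gene's probes and is invariant to
overall gene expression, so a between-group difference in an exon's SI
reflects a shift in the gene's internal exon balance (differential
splicing), not up/down-regulation.

**Three-level differential testing.** Gene expression (GE), exon
expression (EE) and SI are each tested with an empirical-Bayes moderated
t-statistic (pooled two-sample model; per-feature variance shrunk toward
a moments-fitted prior (d0, s0²); t has d0 + df degrees of freedom),
with Benjamini–Hochberg q-values. At q < 0.001 genes are partitioned
into GE-only / SI-only / both / neither — SI-only genes are invisible to
gene-centric analysis. Permutation and uniform nulls diagnose p-value
calibration.

**Classification.** A randomized decision-tree experiment (random
feature subsets, stratified 2/3–1/3 splits, 1000 iterations) measures
the diagnostic information in each data type, including the SI of
non-differentially-expressed genes (pure splicing information).

**Enrichment.** One-sided hypergeometric (Fisher) tests of gene lists
against GMT collections with a platform background, and overlap tests
between gene lists (percent overlap relative to the reference list,
truncated to integer percent).

**Survival.** Per-feature Cox proportional-hazards screens (Efron ties,
per-SD hazard ratios, Wald tests, BH q < 0.1) at GE and SI level,
univariate or adjusted for lymphocytic infiltration (dichotomized at
15%); gene categorization by which screens pass; tertile Kaplan–Meier
stratification with Greenwood variance.

**Synthetic cohorts.** A generator plants known truth — whole-gene fold
changes, total-conserving exon-proportion shifts, survival drivers, a
lymphocytic confounder — so every stage is testable end to end without
external data.

## Worked example

```python
import splicebalance as sb
from splicebalance.expression import summarize_gene_expression, compute_splicing_index

cfg = sb.CohortConfig(
    n_genes=200, groups={"basal": 40, "NBT": 9}, affected_group="basal",
    frac_de_only=0.05, frac_si_only=0.05, frac_both=0.05,
    de_log2fc_range=(1.5, 2.5), si_delta_range=(0.3, 0.5), seed=7,
)
cohort = sb.generate_cohort(cfg)

ge_matrix = summarize_gene_expression(cohort.matrix, cohort.annotation, "linear_sum")
si_matrix = compute_splicing_index(cohort.matrix, cohort.annotation)

groups = cohort.samples["group"]
ge = sb.moderated_t_test(ge_matrix, groups, group_order=("basal", "NBT"))
si = sb.moderated_t_test(si_matrix, groups, group_order=("basal", "NBT"))
calls = sb.call_genes(ge, si, cohort.annotation, q_threshold=0.001)
print(sb.partition_summary(calls))
```

```
          count  fraction_all  fraction_perturbed
category
GE_only      10         0.050            0.322581
SI_only      11         0.055            0.354839
both         10         0.050            0.322581
neither     169         0.845                 NaN
```

The cohort planted 10 genes per effect class among 200: the calls
recover all 10 expression-only genes, all 10 dual-level genes, and the
10 splicing-only genes plus one false positive — 11 genes whose exon
balance differs between tumours and normal tissue with no whole-gene
expression change. `fraction_perturbed` is each category's share of the
31 perturbed genes.

The same pipeline is scriptable from the shell:

```sh
splicebalance simulate --config cohort.yaml --out data/ --seed 7
splicebalance si --matrix data/expression.tsv --annot data/annotation.tsv --out si.tsv
splicebalance run --config pipeline.yaml --out report/
```

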