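# regenscreen

Comparative-transcriptomics tools for limb regeneration studies in *Xenopus*
(and similar development-vs-regeneration designs). The package answers two
questions a regeneration biologist asks of bulk and single-cell RNA-seq data:

1. **Which genes are expressed regeneration-specifically?** Given a count
   matrix over a 12-condition design — development vs regeneration × distal
   (limb bud / blastema) vs proximal (stump) × timepoints, in replicate — a
   three-step screen keeps genes differential within the matched
   ("corresponding") regeneration/development sample pairs, then those higher
   in the blastema than the stump, and finally scores each survivor for
   regeneration specificity.
2. **Does a perturbation shift the blastema toward the developmental state?**
   Given a two-population single-cell contrast (developing limb-bud cells vs
   blastema cells) and a perturbation-vs-control bulk contrast (e.g. a
   transgene induced in the froglet blastema), the concordance fraction
   measures how often the perturbation moves a gene in the developmental
   direction.

## The statistics at the core

**Regeneration-specificity score.** For gene $g$, with replicate-mean TPM
$\bar{x}_c(g)$ per condition $c$, the score counts won comparisons over the
distal conditions:

$$S(g) = \sum_{r \in \{\mathrm{regD}_1,\mathrm{regD}_2\}} \; \sum_{d \in \{\mathrm{devD}_1..\mathrm{devD}_4\}} \mathbf{1}\left[\bar{x}_r(g) > \bar{x}_d(g)\right] \in \{0,\dots,8\}.$$

Ranking is by score, ties broken by the worst-case margin
$\min_r(\bar{x}_r - \max_d \bar{x}_d)$, then gene id.

**Differential expression.** Counts are modelled as negative binomial with
$\mathrm{Var}(X) = \mu + \phi\mu^2$. Libraries are equalized by
median-of-ratios size factors, a common dispersion $\hat\phi$ is pooled
across genes by within-group method of moments, and each gene is tested
two-sidedly on the exact conditional distribution of its group-B sum given
the total (which depends only on $\phi$). Benjamini–Hochberg adjustment
controls the FDR. A Welch t-test on $\log_2(\mathrm{TPM}+1)$ is available as
an alternative engine.

**Shift concordance.** Reference DEGs come from the single-cell contrast
under marker criteria (BH FDR < 0.01, fold change > 2, expressed in ≥ 10 % of
cells in each population; Wilcoxon rank-sum on CPM). Perturbation DEGs come
from the bulk contrast at FDR < 0.01. For the common genes,

$$\widehat{C} = \frac{\#\{g : \mathrm{sign}(\mathrm{log_2FC}^{\mathrm{dev/blastema}}_g) = \mathrm{sign}(\mathrm{log_2FC}^{\mathrm{Tg/ctrl}}_g)\}}{\#\,\text{common genes}}.$$

Seeded synthetic-data generators (`simulate_bulk`, `simulate_sc`,
`simulate_shift_pair`) produce datasets with this exact statistical structure
and planted ground truth, so every stage is testable without external data.

## Worked example

```python
from regenscreen import (BulkSimParams, RegenerationSpecificityScreen,
                         DevelopmentalShiftModel, ShiftSimParams,
                         simulate_bulk, simulate_shift_pair, default_design)

design = default_design()
counts, samples, truth = simulate_bulk(design, BulkSimParams(n_genes=2000, seed=1))
results = RegenerationSpecificityScreen(counts, samples, design).fit(top=10)
print(results.summary())
```

```
Regeneration-specificity screen
===============================
genes tested:            2000
screen 1 (corresponding pairs, p < 0.05): 328
screen 2 (distal > proximal in regeneration):   49
max attainable score:    8

top 10 genes by score (rank, gene, score, margin):
     1  gene_0632        score=8  margin=3.56e+04
     2  gene_1319        score=8  margin=7.46e+03
     ...
```

Screen 1 keeps 328 of 2000 genes (differential in at least one corresponding
pair at p < 0.05), screen 2 keeps the 49 that are also distally biased during
regeneration, and the top-ranked genes all reach the maximal score of 8 —
their mean TPM is higher in both regeneration stages than in every
development stage. With the default simulator, the 20 planted
regeneration-specific genes dominate these top ranks.

```python
data = simulate_shift_pair(ShiftSimParams(n_common_genes=800, n_null_genes=300,
                                          n_cells_per_population=300, seed=1))
shift = DevelopmentalShiftModel(data.sc_counts, data.cell_labels, data.bulk_counts,
                                data.tg_columns, data.control_columns)
print(shift.fit(n_cells=300, seed=1).summary())
```

```
Developmental-shift analysis
============================
reference DEGs (single-cell markers): 799
perturbation DEGs (Tg vs control):    803
common genes:                         798
concordant (shift toward development): 638
concordance fraction:                 0.799
```

The generator planted a concordance rate of 0.8; the pipeline recovers 0.799
from the 798 genes common to both DEG sets.

A command-line interface mirrors the library
(`regenscreen simulate|normalize|de|screen|shift|project`); every stochastic
subcommand requires `--seed` and writes a `run_summary.json` sufficient to
reproduce the run byte-for-byte.

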