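# Methods

## Study design and containers

The bulk design has 12 conditions: development × {distal, proximal} × four
stages (devD1–devD4, devP1–devP4) and regeneration × {distal, proximal} × two
stages (regD1, regD2, regP1, regP2), each sequenced in replicate (default 3).
Each regeneration sample is matched to the developmental sample of most
similar tissue stage and shape: the *corresponding pairs* regD1/devD1,
regD2/devD2, regP1/devP3 and regP2/devP4. The proximal pairs are matched by
tissue similarity, not by timepoint index, so the pairing is carried
explicitly in the `StudyDesign` object rather than inferred from indices.

Counts are integer gene × column matrices; expression matrices carry their
unit (`tpm`, `cpm`, `log2_tpm_plus1`, `zscore`) so that stages can check
their inputs. Homeolog aggregation (summing .L/.S subgenome copies of the
allotetraploid *X. laevis* genome) takes a user-supplied two-column map and
is never inferred from id suffixes: suffix conventions vary across genome
versions, and silent misgrouping would corrupt every downstream stage.
Aggregation conserves the matrix grand total exactly.

## Normalization

TPM divides counts by gene length (nt), then scales each column so it sums to
10^6; CPM is the same with unit lengths. All-zero columns remain zero and
trigger a warning rather than an error — empty libraries occur in single-cell
data and should not abort a run. The log/z transform is log2(x+1) followed by
a per-gene z-score over a designated column set, using the population
(n-denominator) standard deviation; constant genes map to all-zero rows. The
population convention matches how expression heatmaps are usually z-scored;
the n vs n−1 choice is immaterial scientifically but is fixed so outputs are
bit-stable and testable.

## Differential expression

The default engine is an exact conditional negative-binomial test with
variance function Var(X) = μ + φμ², chosen because its φ → 0 limit (Poisson)
and its conditional structure are both independently verifiable:

1. **Size factors** — median of ratios against the per-gene geometric-mean
   reference, computed over genes with all-positive counts; when fewer than
   50 such genes exist the code falls back to total-count scaling normalized
   to the geometric-mean total (a defined degenerate-input path for tiny or
   very sparse matrices).
2. **Common dispersion** — pooled method of moments over within-group
   deviations, so genuinely differential genes do not inflate the estimate;
   scaled counts contribute Var(k/s) ≈ μ/s + φμ², hence a mean-inverse-size-
   factor correction; the estimate is floored at 10⁻⁴.
3. **Exact test** — group sums of n i.i.d. NB(μ, φ) replicates are
   NB(nμ, φ/n) with the *same* success probability 1/(1+φμ) under the null,
   so the conditional law of the group-B sum given the total is free of μ:
   P(S_b = s | t) ∝ C(s+r_b−1, s)·C(t−s+r_a−1, t−s) with r_g = n_g/φ. The
   two-sided p-value is the complement of the strictly-more-likely mass
   (minimum-likelihood method), so an observation at the conditional mode has
   p = 1 exactly. Probability ties are detected with a relative tolerance of
   10⁻⁷, above the gammaln round-off reached at large totals.

Group sums are equalized by size factors and rounded to the nearest integer
before conditioning. Genes with zero counts in every column are excluded from
the BH family and reported with p = fdr = 1. Log fold changes use normalized
group means with pseudocount 0.5, which bounds the ratio at zero counts.
Empirically (see the acceptance suite) the null rejection fraction at
α = 0.05 sits in 0.03–0.05 for dispersions 0.01–0.5 at 3 vs 3 replicates; the
residual conservatism comes from discreteness at low-count genes, which is a
property of any exact test on small totals.

A Welch t-test on log2(TPM+1) (CPM without lengths) is available as the `t`
engine where speed matters more than count-level modelling.

## The three-step screen

* **Screen 1** tests each corresponding pair (development vs regeneration)
  and keeps genes with p < α (default 0.05, raw p) in at least one pair. The
  union rule is the weakest reading consistent with "differential within each
  corresponding pair" producing a genome-scale survivor set; a strict
  `all`-pairs rule is available as an option.
* **Screen 2** tests the stage-matched regeneration contrasts regD1 vs regP1
  and regD2 vs regP2 and keeps screen-1 genes with p < α *and* a higher
  normalized distal mean in at least one stage (`both` available).
* **Screen 3** scores each survivor: one point per (regeneration-distal,
  development-distal) comparison won on replicate-mean TPM with *strict*
  inequality — exact ties score nothing, which makes the all-equal case
  well-defined at 0. The maximum is 2 × 4 = 8 under the default design.
  Ranks order by score, then by the worst-case TPM margin
  min_r(mean_r − max_d mean_d), then lexicographically, so output files are
  deterministic. An optional `significant` scoring mode demands p < α per
  comparison instead of a raw mean inequality.

Raw p (not FDR) is used in screens 1–2 by design; both screens expose the
threshold. The screens nest by construction: scored ⊆ screen2 ⊆ screen1.
Note the rank tie-break uses absolute TPM margins, so among equal-scored
genes the highly expressed ones rank first; this is intentional (a large
absolute margin is stronger evidence than a large ratio at the noise floor).

## Shift analysis

Reference DEGs come from a two-population single-cell contrast: Wilcoxon
rank-sum (normal approximation with tie correction) on CPM per gene, BH over
genes with any expression, fold change (mean CPM_ref + 1)/(mean CPM_con + 1),
and percent-expressed computed on raw counts. A gene passes with FDR < 0.01,
natural-scale fold change > 2 in either direction, and ≥ 10 % of cells
expressing it in **both** populations — the stricter literal reading of
"each cell population"; the common tool convention (either population) is a
flag. The pseudocount of 1 on mean CPM bounds fold changes for dropout-heavy
genes.

Population z-profiles subsample n cells per population (default 1000) without
replacement under a stated seed, z-score log2(CPM+1) per gene across the
pooled subsample, and average within populations; the identity
n_ref·z̄_ref + n_con·z̄_con = 0 holds per gene by construction and is asserted
in tests.

The perturbation arm reuses the package's exact NB test at FDR < 0.01; the
engine is pluggable because the scientific quantity here is the
intersection-and-concordance statistic, not the DE engine. A common gene is
concordant when the sign of its development-over-blastema fold change equals
the sign of its perturbation-over-control fold change; the headline fraction
uses sign agreement only — the claim being quantified is directional, and
magnitude weighting would conflate effect size with direction. An empty
common set yields a null fraction with a warning rather than an error.
Cell-level quality control and multiplet removal are assumed done upstream.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
the biology of any particular dataset:

* **Bulk** — per-gene baseline weights log-uniform over 1–10⁴ (≈ 4 decades of
  dynamic range), lognormal library sizes (mean 10⁶, CV 0.1), NB counts with
  φ = 0.1; planted classes: regeneration-specific genes (fold 8 in regD1/2
  only), distal-shared genes (fold 4 in all distal columns of both
  processes), proximal genes (fold 4 in proximal columns). Gene lengths are
  log-uniform over 300–10 000 nt so TPM is exercised.
* **Single cell** — two populations, lognormal capture depth (mean 2 000,
  CV 0.3), NB with φ = 0.1, optional extra Bernoulli dropout; markers are
  elevated fold 4 in the reference population.
* **Shift pair** — a set of common genes differential in both the single-cell
  and the bulk contrast; each gene's single-cell direction is a fair coin and
  its perturbation direction agrees with probability equal to the planted
  concordance rate (default 0.8). Background null genes (default 1000) fill
  out the BH family.

Planted genes draw their baselines from the moderately expressed range
(weights 50–5 000 bulk, 50–1 000 single cell): their ground-truth labels
assert that they *are* differential/detectable, which cannot hold for genes
at the sequencing detection floor. Null genes span the full range, so
false-positive behaviour is still exercised at low counts. Dispersion and
depth defaults are package choices typical of bulk RNA-seq and droplet
single-cell data, respectively.

All generators are pure functions of (params, seed): one root seed sequence
per dataset with deterministic per-column children, so output is bitwise
reproducible and independent of generation order. What the simulations do
not emulate: batch effects, gene–gene correlation, multi-lineage single-cell
structure, length biases within a library, ambient RNA. Passing tests
therefore demonstrate correctness of the computations under the assumed
model, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

The test suite runs the screens at 5 000 genes × 36 samples over 10 seeds and
the shift recovery at 3 000 genes × 1 200 cells over 10 seeds — sizes chosen
so the full statistical behaviour (calibration bands, recovery rates) is
measurable with tight Monte-Carlo error while the whole suite stays fast on a
single CPU. PCA uses the deterministic full-SVD solver with a fixed sign
convention (largest-magnitude loading positive per component). TPM/CPM column
sums are validated to 10⁻⁹ relative; z-identities to 10⁻⁹ absolute; BH equals
an independent quadratic-time oracle exactly.

## Known limitations

* The exact test uses a single pooled dispersion per contrast; no tagwise or
  trended shrinkage, and no GLM designs with covariates.
* The conditional test's integer equalization rounds scaled group sums; at
  extremely unequal library sizes this approximation is cruder.
* The Wilcoxon marker test uses the asymptotic normal approximation, which is
  what its power and calibration were validated under; exact small-sample
  p-values are not implemented (populations below 20 cells trigger a
  warning).
* The concordance fraction treats genes as independent; its binomial-style
  uncertainty understates the truth when DEGs are co-regulated.
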