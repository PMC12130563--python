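# Methods

This note documents the models, procedures and numerical choices behind the
package. It covers the consensus cell-classification procedure, the
signature-extraction and feature-selection statistics, the multi-model
integration framework, and — in most detail — what the synthetic-data
generator emulates and what it does not, because every quantitative claim
the test suite makes is a claim about data from that generator.

## The consensus classification procedure

The goal is to call individual neutrophils "high-risk" or "low-risk" from a
pair of transcriptional signatures without trusting any single gene-set
scoring statistic. The procedure is:

1. **Signatures.** Case-vs-control differential expression on the
   depth-normalised single-cell matrix (two-sided Wilcoxon rank-sum with
   tie-corrected normal approximation, Benjamini–Hochberg adjustment).
   Genes with log2 fold change > 0.25 and adjusted p < 0.05 form
   *signature1* (up in cases); genes below −0.25 at the same alpha form
   *signature2*. Both inequalities are strict. Fold change is computed on
   de-logged depth-normalised means with a pseudocount of 1 (the Seurat
   convention; this choice matters only near the threshold).
2. **Scoring.** Each cell is scored for each signature by every scorer in a
   registry of k single-sample gene-set statistics (default k = 19, giving
   38 scores per cell).
3. **Binarisation.** Each scorer's per-cell scores are binarised at their
   median over *all* scored cells (conditions pooled): for signature1,
   strictly above the median → 1, otherwise 0; for signature2 the coding is
   inverted, so every bit points toward the high-risk phenotype. Ties at
   the median fall to the "otherwise" branch.
4. **Consensus.** The 2k bits are summed. A cell is *high* only at the
   unanimous total 2k, *low* only at 0, and *filtered* otherwise. Filtered
   cells are kept in every output with their label, because proportion
   analyses need denominators.

Unanimity makes the call deliberately conservative: any scorer that
disagrees vetoes the call. The monotonicity consequence — enlarging the
registry can only shrink the high/low sets — is asserted in the tests.

## The scorer registry

The registry holds eight core statistics spanning the families in common
use for per-cell signature scoring, all implemented here on normalised
log1p expression:

| statistic | idea |
|---|---|
| `mean_z` | mean of per-gene z-scores across cells |
| `rank_auc` | area under the signature-recovery curve in the top x% of the cell's expression ranking (AUCell-like) |
| `rank_sum` | normalised Mann–Whitney U of signature genes vs the rest within the cell (UCell-like) |
| `mean_rank_centered` | centred mean within-cell rank (singscore-like) |
| `running_sum` | weighted running-sum enrichment with weight exponent α (ssGSEA-like) |
| `svd_proj` | projection on the first singular vector of the standardised signature submatrix (PLAGE-like), sign-oriented along mean signature expression |
| `binned_ctrl` | signature mean minus the mean of expression-bin-matched control genes (module-score-like); control pools drawn once per scorer from a name-derived seed, so results are deterministic and cell-order independent |
| `dropout_rank` | mean signature rank among the cell's expressed genes, zeros contributing nothing |

Parameter variants (recovery-curve depth 5/10/25/50%, α ∈ {0, 0.25, 0.5, 1},
control-bin counts, winsorised z-scores, rank-space SVD) extend the registry
to at most 20 uniquely named scorers; `build_registry(k)` returns the first
k deterministically, and the consensus logic is agnostic to which statistics
populate it. Within-cell ties are broken by average rank in rank statistics
and by stable gene order in the running sum.

## Pseudotime and feature selection

A learned dynamical model is out of scope here; the differentiation axis is
the first principal axis of the normalised expression matrix (deterministic
full SVD, no randomised solver), oriented so that the mean position of
consensus-high cells exceeds that of consensus-low cells, then min–max
rescaled to [0, 1]. The orientation rule makes the axis identifiable; an
input without both high and low cells is an error, not a guess.

Genes are screened by Pearson correlation with pseudotime with a two-sided
t-distribution p-value. The selection rule is **signed** r > 0.6 with
p < 0.05 by default — strongly negatively correlated genes are not selected
unless the absolute-value flag is set. Constant genes are reported with an
undefined r and excluded. The final feature set is the intersection of the
correlation-passing genes of both single-cell datasets with the
differentially expressed genes (|log2FC| > 1, adjusted p < 0.05) of both
bulk cohorts, in alphabetical order.

## Multi-model integration

Cohort 1 is split 70/30 (stratified, seeded) into training and test sets;
cohort 2 is the external validation set. The grid is every classifier alone
plus every coherent selector→classifier pair — 7 selectors (none, lasso,
elastic net, stepwise forward/backward/both, univariate rank-sum filter) ×
9 classifiers (plain/ridge/lasso logistic, LDA, Gaussian naive Bayes, kNN,
random forest, linear SVM, gradient boosting), excluding the two pairs
where a sparse-logistic selector feeds the identical embedded-sparse
classifier: 61 combinations, with the size logged rather than claimed.

Selectors and hyperparameter tuning (3-fold cross-validation over penalty
paths, k for kNN, C for the SVM) see the training partition only. Stepwise
selection is driven by AIC over repeated logistic fits; to keep those fits
well-posed when the feature count approaches the training-set size, the
stepwise search operates on a univariate rank-sum pre-screen of at most
min(15, n_train/3) genes, and likelihood saturation under perfect
separation is treated as log-likelihood 0. A selector that returns no genes
yields a flagged result with mean AUC pinned at 0.5.

Models are ranked by the mean of test and validation AUC only (training AUC
is reported, never used for selection), ties broken by fewer genes, then
name. Per-gene *model frequency* counts the models whose final gene set
contains the gene; for sparse linear classifiers the final gene set is the
support of the fitted coefficients. AUC is the rank-based (Mann–Whitney)
statistic with midrank tie handling.

The only batch handling in scope is per-cohort centring (subtracting each
gene's within-cohort mean) before model fitting.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
planted ground truth for every recovery claim.

**Single cell.** Two conditions (hypertensive control "HBP" and microbleed
case "MB") of 1,000 neutrophils each over 500 genes by default. Counts are
negative binomial via a gamma–Poisson mixture with shared dispersion 0.05
and per-cell lognormal library factors (σ = 0.3). A fraction (default 0.5)
of case cells is flagged high-risk; these occupy the top of a per-cell
differentiation latent in [0, 1] (high-risk cells uniform on [0.6, 1], all
others on [0, 0.6]). Planted effects at effect size `effect_log2fc` (default 1):

- 25 signature-up genes: mean × 2^effect in high-risk cells;
- 25 signature-down genes: mean ÷ 2^effect in high-risk cells;
- 15 monotone genes: mean multiplied by 1 + (8^effect − 1)·latent, linear
  in the latent.

Setting the effect to 0 switches off all three structures at once, giving
an exact null. Baselines are lognormal(1, 1) for background genes, uniform
(5, 15) counts for signature genes and (10, 20) for monotone genes. These
scales were chosen together so that each planted structure realises its
definition at realistic sequencing depth: marker genes must be expressed
enough for a 2× shift to be detectable per cell, monotone genes must rise
enough above counting noise that "strongly pseudotime-correlated" (r > 0.6)
is true of them, and — the binding constraint — the *compositional mass* of
the monotone ramp must stay small next to the background transcriptome.
Because library-size normalisation is zero-sum, a heavy monotone ramp
dilutes every other gene in high-latent cells; past roughly a −0.25 log2FC
of dilution that artefact floods signature2 with background genes and
degrades the consensus. The defaults keep dilution near −0.1 log2FC, which
leaks at most a handful of background genes into signature2.

**Bulk.** Two cohorts of 65 samples over 64 features by default, Gaussian
with noise SD 1 around uniform(0.2, 0.8) baselines. Ten informative genes
are shifted by 2.5 in cases — a strong biomarker effect (closed-form
binormal AUC ≈ 0.96 per feature) chosen so the planted genes survive the
|log2FC| > 1 cut *within both cohorts* even though cohort 2's constant
additive batch offset (0.5) inflates its baselines and therefore shrinks
its fold changes. In the end-to-end pipeline the bulk feature space is the
single-cell gene universe and the informative genes are drawn from the
single-cell monotone set, so the trajectory × DEG intersection is non-empty
by construction.

**What the generator does not emulate.** One cell type only (no lineage
mixture or compositional shifts between conditions), no doublets or ambient
RNA, shared dispersion across genes, Gaussian bulk features rather than
count-derived ones, a strictly additive batch effect, and a high-risk flag
that is deterministic in the latent. Passing tests therefore demonstrate
that the procedures recover the structure they are defined to recover under
their own assumptions — not that those assumptions hold in any particular
patient dataset.

## Problem sizes and numerical choices

Default test and reproduction runs use 2,000 cells × 500 genes per
single-cell dataset and 130 bulk samples × 64 features, sizes at which
every stage is exact rather than subsampled and a full run completes in
well under a minute for the single-cell chain and a few minutes for the
61-model grid. Other fixed choices: depth normalisation to 10,000 counts
before log1p with zero-count cells rejected as errors; genes expressed in
fewer than 3 cells per group skipped in single-cell DE; groups smaller than
3 cells falling back to the exact rank-sum test with a warning; strict
inequalities at every published threshold; medians over pooled conditions;
SVD sign fixed by correlation with mean signature expression; seeds
propagated explicitly everywhere (the "mouse" replicate uses seed + 1000,
the bulk cohorts seed + 2000).

## Known limitations

- The registry's statistics are this package's own; any consensus result
  depends on the registry composition, which is therefore logged.
- The model-grid composition (61 combinations) is a documented choice, not
  a canonical set; grid size is reported alongside every frequency.
- Pseudotime is a linear axis; strongly nonlinear trajectories would need a
  different embedding, though the downstream selection rule would be
  unchanged.
- With unanimity over 38 bits, the filtered fraction grows with registry
  size; k is configurable where that trade-off matters.
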