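# Methods

## Quantification model

Threshold cycles (Ct) are the measurement scale throughout. For each sample
the normalizing factor is the arithmetic mean Ct of the configured
housekeeping panel (five genes for the discovery array, B2M and RPLP0 for
the replication assays), and

    delta_ct(f, s) = Ct(f, s) − mean_ref_Ct(s),
    expr(f, s)     = 2^−delta_ct(f, s).

Technical duplicate wells are averaged on the Ct scale before anything
else, since cycles are what the instrument measures and errors are
approximately additive there. Undetermined wells stay missing; no
imputation is performed, and a feature missing in more than half of either
group of a comparison is dropped from that comparison (configurable). QC
excludes a sample when its target missingness exceeds 0.5 or a genomic-DNA
control amplifies below Ct 35; replicate pairs disagreeing by more than one
cycle are flagged but kept. These thresholds are package defaults chosen to
be conservative — studies report such exclusions without publishing rules —
and are all config keys. Pre-amplification versus direct RT is treated as
metadata only; no efficiency (Pfaffl-style) correction is attempted.

## Differential expression

Models are fitted per feature on `−delta_ct` (log2 expression), so the
group coefficient is the log2 fold change itself; that is the only scale on
which a linear model, 2^−ΔCt normalization and reported log2FCs are
mutually consistent. Discovery-style comparisons add sex as an additive
covariate and call significance at nominal p < 0.05; replication-style
comparisons are group-only and call BH-adjusted p < 0.05. Both are
per-comparison options; the shipped comparison lists
(`lncq/configs/*_comparisons.yaml`) encode these defaults.

Variance moderation follows the scaled-F empirical-Bayes model: residual
variances `s²_g` with `d_g` df are assumed drawn around a common prior
`s₀²` with `d₀` prior df. The prior is estimated by matching the first two
moments of `log s²_g` (digamma/trigamma inversion; the trigamma inverse is
solved by Newton iteration to 1e−8). When the observed spread of `log s²`
does not exceed its sampling component, `d₀` is reported infinite and every
posterior variance equals `s₀²`. The moderated statistic is

    t_g = beta_g / sqrt(s̃²_g · v_g),   s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g),

on `d₀ + d_g` df capped at the pooled residual df across features (the
capped convention of the reference implementation this module is
oracle-tested against). Note one consequence of the moment-matching
formula: if all `s²` are numerically identical, the returned `s₀²` is the
common value times `exp(log(d/2) − ψ(d/2))`, not the common value itself —
zero spread is outside the model. Features with `s² = 0` are retained;
moderation with `s₀² > 0` keeps t finite. The log-odds B-statistic is an
optional output with prior differentially-expressed proportion 0.01; its
coefficient-prior variance is estimated from the top tail of the moderated
t-statistics by the method of moments, and it is secondary to the p-values.

PCA is column-centered (unscaled, matching the convention of prcomp-style
defaults) SVD with samples as observations; scaling is a flag. The sex
screen fits a sex coefficient with group as covariate and flags
BH-significant features for exclusion from candidate selection; covariate
screens (eosinophil/neutrophil fractions, FEV1) use Spearman rank
correlation with BH adjustment.

## Biomarker evaluation

Classifiers are Gaussian naive Bayes on the normalized expression
`2^−ΔCt` (a log-scale flag exists for sensitivity analysis). Class priors
are empirical frequencies; class-conditional variances use the
maximum-likelihood estimator floored at `1e−9 ×` the pooled variance so
constant features keep finite densities. Prediction calls the positive
class when its posterior strictly exceeds 0.5; an exact tie goes to the
negative class (documented, tested). Leave-one-out cross-validation trains
on all other samples — a training fold reduced to a single sample of one
class is still fitted (its variance is the floor), while a fold losing a
class entirely is recorded as an error rather than skipped — and each fold
contributes one confusion-matrix cell. Weighted accuracy, the mean of
sensitivity and specificity, is the headline score because group sizes are
strongly unbalanced (e.g. 95 vs 9). Three panel variants are evaluated per
comparison: each feature alone, the full panel, and the reduced panel of
that comparison's significant features (identical to the full panel when
everything is significant; omitted with a warning when nothing is).

A caveat the tests make explicit: LOO weighted accuracy under permuted
labels is heavy-tailed at small n — with 20 samples per group and a
strongly bimodal feature, ~20% of permutations fall outside [0.3, 0.7].
Null-calibration checks are therefore run at study-cohort group sizes
(e.g. 25 vs 9), where the permutation distribution concentrates.

## Function prediction

The heterogeneous network has lncRNA and gene nodes and four undirected
edge types: lncRNA–lncRNA and lncRNA–gene transcriptional similarity
(|Spearman rho| ≥ 0.5 over shared samples, weight |rho|; threshold is a
config key), validated lncRNA-target edges and gene–gene PPI edges (weight
1 or as listed). Duplicate edges across types keep the maximum weight with
all types recorded; isolated nodes are retained. Per-type weight
multipliers exist for sensitivity analysis but default to 1 — the available
problem statement does not quantify relative edge importance, so no
rescaling is invented.

Random walk with restart iterates `p ← (1−r)Wp + re` with W the
column-normalized weighted adjacency, e uniform over the seeds, restart
r = 0.5 (conventional midpoint; config key), tolerance 1e−10 in L1, at
most 10 000 iterations; dangling nodes teleport to e. Scores are stationary
visiting probabilities and sum to one; the iterative result is tested
against the dense linear solve `p = r(I − (1−r)W)⁻¹e` on every fixture up
to 200 nodes.

For each seed lncRNA the propagated scores are restricted to gene nodes,
renormalized, and fed to GSEA: genes ranked by score (descending,
lexicographic id tie-break), hits increment the running sum by
`score^w / Σ_hits score^w` with w = 1, misses decrement by `1/(N − n_set)`,
ES is the signed maximum deviation. The null is ES over random same-size
gene draws (gene-label permutation — phenotype permutation has no meaning
for a single score vector), 1000 permutations by default; NES divides ES by
the mean |null ES| of matching sign, the nominal p is the matching-sign
tail fraction with a +1 pseudo-count, and FDR compares each NES against the
pooled null NES of all sets (ratio of null and observed tail fractions,
capped at 1). Sets are size-filtered to [5, 500] against the scored
universe; FDR < 0.1 flags a predicted function. A seed disconnected from
all genes yields an explicit "no prediction" record.

One behaviour worth knowing: with w = 1 and propagated mass concentrated on
a handful of genes, any null set containing one top gene saturates near
ES = 1, so FDR discriminates poorly on degenerate star-shaped networks;
with realistic background connectivity (PPI density ≈ 0.05–0.1) the planted
module separates cleanly (FDR ≈ 0 vs > 0.01 for random sets).

## Synthetic data: what it emulates and what it does not

Cohort designs reproduce the target study layouts exactly: discovery
4 adult groups × 6 (control, mild asthma, severe asthma, COPD; 9/24 male)
and replication 16/11/7/95/9/25 (childhood control, childhood asthma, adult
control, adult asthma, COPD, allergic rhinitis; 73/163 male), with
per-group allergic fractions taken from the study tables. The discovery
panel fills a 96-well array (84 targets including sex-dimorphic XIST and
NAV2-AS5 analogs, 5 housekeeping, 1 gDNA, 3 RT, 3 PPC wells); the
replication panel is the six lncRNAs plus B2M/RPLP0, generated in
duplicate.

Ct values are Gaussian on the cycle scale (log-normal expression), noise
sd 0.8 cycles by default — a realistic blood-qPCR combined biological and
technical spread; effects enter with a minus sign on Ct so a planted log2FC
equals the downstream −ΔCt group difference by construction. Planted
replication effects mirror the magnitude pattern of the study's reported
fold changes (rhinitis elevated ~0.7–1.2 log2 units on all six lncRNAs;
HNRNPU/RP11-325K4.3/JPX elevated ~0.9–1.0 in children); reference genes
draw around Ct 20 with sd 0.5. These reference-scale constants are fixture
conventions, not estimates of any real distribution — raw Ct distributions
for the study are unpublished. Draws outside [0, 40] are clipped and
counted; optional dropout (default 0) produces missing wells. Not
simulated: amplification curves, primer efficiencies, plate spatial
effects, RNA-quality covariates, inter-plate calibration. Passing tests
therefore demonstrate correctness of the computational pipeline under an
idealized error model, not robustness to assay artefacts.

Network fixtures plant a co-expressed lncRNA–gene module (shared latent
signal plus Gaussian noise), list the planted pairs first among validated
targets, and draw PPI edges as independent Bernoulli over gene pairs.

## Reproducibility and problem sizes

Every generator and stochastic stage is a pure function of its inputs and a
seed; the pipeline derives per-stage seeds from one global seed by hashing
the stage name (CRC32, kept below 2³¹), so a (config, seed) pair
reproduces every table bit-identically. The test suite and acceptance
script use deliberately desk-scale problem sizes — 200 simulated cohorts of
30 per group for recovery coverage, 2000 features for prior recovery, 100
permutations for classifier calibration, 20 seeded runs × 51 sets × 200
permutations for enrichment recovery — chosen as the smallest sizes at
which the Monte Carlo assertions are stable.

## Known limitations

No efficiency-corrected quantification; no mixed-effects or
repeated-measures modelling; no ROC/AUC or k-fold alternatives to LOO; the
moderation has no trend/robust variants; propagation is undirected and
unsigned. The reduced-panel definition depends on the significance calls of
the same data, as in the study design it follows, and is therefore not an
unbiased estimate of panel performance on new cohorts.
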