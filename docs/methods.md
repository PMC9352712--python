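# Methods

## Problem and model

CRISPR/Cas9 knockout screens read out gene essentiality from the dropout of
guide counts, but the double-strand break (DSB) itself carries a fitness
cost. In TP53 wild-type cells the p53 response amplifies this cost, and the
amplification depends on the chromatin and sequence context of the cut
site. The package models this with an isogenic-pair design — the same cell
line wild-type (wt) and knocked out (ko) for TP53, screened in parallel
across treatment arms ("pseudo-replicates") and time points — and asks, per
guide, whether depletion in wt relative to ko tracks features of the locus
rather than the function of the gene.

The central statistical object is a negative-binomial (NB2) regression of
raw guide counts:

    counts ~ feature * TP53_status + D2 + offset(log total non-targeting counts)

with log link, treatment coding (reference levels: feature absent, genotype
ko), a gene-essentiality covariate D2 (RNAi-derived dependency score, so
fitness effects of the gene knockout itself are absorbed) and a fixed
per-sample exposure offset that uses non-targeting guides as a
selection-free depth estimate. The coefficient of interest is the
`feature:TP53wt` interaction: the extra natural-log depletion of
feature-carrying loci specific to wt cells, i.e. the p53-dependent
component of cut toxicity. Dispersion is a single per-model NB2 alpha
(var = mu + alpha·mu², theta = 1/alpha) estimated by maximum likelihood
from a Poisson warm start with a method-of-moments alpha initialisation;
convergence failures fall back to a Poisson GLM and are flagged
(`poisson_fallback`). Wald tests give per-term p-values; FDR control is
Benjamini–Hochberg by default, with a Storey q-value option that estimates
the null proportion on a lambda grid and falls back to BH below 100 tests.

Supporting model variants: wt-only fits (`counts ~ feature + D2 + offset`,
the feature effect per se), pairwise conditioning (a second feature, with
or without its own TP53 interaction, to separate correlated chromatin
features), status-only and D2-only baselines, and cell-line-panel models
`counts ~ TP53*HR + D2 + tissue + offset` and `counts ~ feature*HR + D2 +
tissue + offset` (treatment-coded tissue, breast as reference; offsets from
non-essential-gene read totals).

## Locus classification

Per-guide log2 fold changes (LFC) between matched wt (pseudo-treatment) and
ko (pseudo-control) samples are computed on median-of-ratios-normalised
counts with a pseudocount (default 1.0, configurable; the optional
`remove-0` flag drops guides with zero control counts). A guide is a
**target locus** when LFC < −0.5 in *every* (pseudo-replicate × later time
point) comparison — by default 3 × 3 = 9, with the baseline time point
excluded. **Non-selected loci** have |LFC| < 0.5 everywhere. **Background
loci** are the remaining guides in genes that contain at least one target;
they are not additionally LFC-filtered (an `exclude_positive` flag can
remove consistently enriched guides; off by default). Target guides in
TP53-pathway genes (top interactors), in genes from enriched GO terms, or
in paralog-rich families (symbol prefix OR/USP/FAM followed by a digit,
with an override list) are removed with per-filter provenance. The
off-target filter removes targets with any exact secondary genomic match or
a total CFD score (sum over top-5 predicted off-targets; scores are inputs)
above the 95th percentile of the non-selected loci, computed with linear
interpolation between order statistics (numpy default, type 7).

## Sequence covariates

- **Microhomology / MMEJ candidacy**: exhaustive enumeration of identical
  arm pairs flanking the blunt cut, arm length 5–15 bp, each arm's
  cut-proximal end within 15 bp of the break, one arm strictly 5′ and one
  strictly 3′ (arms flank the break; they never span it). Arms containing N
  never match; both maximal and contained arms are reported and
  deduplicated by (sequence, offsets). `cut_index` counts the bases 5′ of
  the cut.
- **PAM context**: the 4-mer formed by the 1-bp upstream base plus the NGG
  PAM, in protospacer orientation (minus-strand genomic-orientation input
  is reverse-complemented), collapsed to classes like `C-NGG`.
- **CpG**: count of CG dimers in the context window (CG cannot overlap
  itself, so the 5′→3′ scan equals the plain substring count).
- **Motifs**: exact IUPAC-consensus matching on both strands, counting
  matches whose span intersects a window centred on the cut
  (half-widths 8/25/50 for 16/50/100-bp searches), counts capped at 5 per
  locus; motifs present in fewer than 10% (inclusive) of the target ∪
  background universe are dropped. Both a capped-count and a binary
  presence encoding are available (count is the default).

## Covariate binning

Chromatin-mark abundances: zeros are bin 0; positive territory is split at
its genome-weight median into bins 1 and 2 (equal weight each side; when
true genomic territory weights are unavailable, weights default to equal
per-guide weight, preserving the 50/50 semantics). Values tied with the
split go to the lower bin. Bin-1 guides are masked out of single-feature
regressions so the contrast is absence vs clear abundance. Copy-number bins
1–7 binarise to high (5–7) vs low (1–4); replication timing to early (6) vs
late (1–5) with bin-0 guides dropped; gene lengths split at the median into
short/long after removing genes > 200 kb; DSB distance to the 5′ gene end
is scaled to [0, 1]. All data-derived split points are serialised with the
feature table.

## Copy-number calibration and example score

CN gain is a well-established driver of non-specific cut toxicity, so the
CN interaction coefficient serves as a unit: with mean CN scores 0.7
(reference) and 2.0 (high), one CN step is a 2.9-fold ploidy change, and a
feature coefficient beta_f corresponds to `2.9 · beta_f / beta_cn`-fold
ploidy by cross-multiplication. Summaries print 1 decimal for fold-ploidy
and 2 for `exp(beta)` count fold changes; full precision is kept
internally. The example p53-toxicity score is a pure linear function of the
covariate vector with weights defaulting to negated interaction
coefficients averaged across pseudo-replicates (higher score = more
predicted toxicity); it is a documented reconstruction of a ranking
heuristic, not a trained classifier.

## Gene-level screening statistics

Gene scores default to the median per-gene of guide LFCs when external
model-based selection coefficients are not supplied. The essential /
non-essential benchmark is the AUROC of mean normalised counts per gene,
computed as the normalised Mann–Whitney U (ties count ½). Conditional
essentiality uses Z-standardised scores per condition; a 2-D Gaussian
mixture (EM, seeded k-means initialisation, 1–4 components, BIC selection)
separates selected from non-selected genes; a gene is a conditional hit
when |z_control| < 2, z_treatment < −2 and the control−treatment difference
is below −2 SD of its own per-gene distribution (the SD of the difference,
ddof = 1; a pooled option exists). Residual comparison fits OLS
z_treatment ~ z_control per genotype and reports per-gene residual
differences (ko − wt). The permutation null reshuffles hit labels within
each of the 12 (6 ko + 6 wt) comparisons, preserving per-comparison hit
counts, and counts iterations with ≥2 genes hit in ≥4/6 ko and ≤0/6 wt
comparisons.

## Panel mode

Across a cell-line panel, each guide's TP53 effect size is Cohen's d with
pooled SD, wt minus mutant (negative = worse fitness in wt = more p53
toxicity), with a two-sided t-test and BH FDR; this reconstructs the ANOVA
effect size of the gdsctools package without its MSI/medium covariates.
Panel target loci have d < −0.4 (strict); low-toxicity controls lie
strictly inside (−0.04, 0.04). `prepare_hr_design` assembles the
long-format table for the TP53×HR and feature×HR models, dropping lines
with missing status and computing offsets from non-essential-gene totals.

## Synthetic screens

The generator emulates the isogenic-pair design: `n_genes ×
sgrnas_per_gene` gene-targeting guides plus non-targeting controls; 2
genotypes × 3 pseudo-replicates × 4 time points (t0 baseline); counts
NB(mean, theta) with

    log mu = baseline + depth_j + s(t)·[beta_D2·D2 + Σ beta_f·x_f + Σ beta_fxTP53·x_f·1(wt)]

Defaults are the study-scale conditions used throughout the tests:
baseline mean 500 counts/guide (500× coverage), theta = 10, per-sample log
depth jitter SD 0.1. Offsets on the returned matrix are recomputed as log
total non-targeting counts, exactly as the models consume them.

Two time-scaling modes are provided because two different questions need
them. In `step` mode (default) s(t) is 0 at baseline and 1 afterwards, so
the planted interaction is exactly the estimand of the pooled regression —
this is the mode for estimator-calibration experiments (recovery, type-I
error, CI coverage), where the generative model must lie inside the fitted
family. In `linear` mode s(t) is the time index (1/2/3 at the later
points), emulating cumulative dropout over the time course — this is the
mode for locus-calling experiments, where consistency of depletion across
later time points is the signal being thresholded. A single pooled
coefficient fitted to linear-mode data estimates a count-weighted average
of the time-scaled effects (≈1.8× the planted value in the default
design), which is a property of the estimand, not an estimator defect.

Chromatin abundances are zero-inflated censored normals: a latent Gaussian
vector with cross-mark correlation is shifted and clipped at zero so that
`1 − fraction(f)` of guides carry abundance 0 (default fraction 0.5, so
bin 0 and bins 1/2 are both populated). Configured correlations refer to
the final abundances; the latent correlation is calibrated by numerically
inverting the censoring attenuation (Gauss–Hermite quadrature + Brent root
finding). Binary flags are Bernoulli; D2 scores and gene lengths are drawn
per gene and shared by that gene's guides. When context sequences are
generated, the protospacer is laid into a 201-nt window so the cut falls
3 bp 5′ of the NGG PAM; with `mh_fraction` set, exactly that fraction of
guides is made an MMEJ candidate by planting an arm copied from upstream of
the cut just past the PAM, and chance microhomologies are scrubbed from the
remaining guides by resampling flanks outside the protospacer/PAM (guides
whose chance arm pair is pinned inside the fixed bases are redrawn).

What the generator does *not* emulate: off-target cutting, lentiviral MOI
and infection bottlenecks, PCR jackpotting, guide-efficiency variation, and
batch structure beyond a per-sample depth factor. Passing tests therefore
demonstrate correctness of the estimators and calling rules under the
stated NB model, not robustness to those real-data artefacts.

## Numerical choices and edge cases

- NB optimiser: statsmodels `NegativeBinomial` MLE, 200 iterations max,
  Poisson warm start, MoM alpha start clipped to [1e-4, 10]; rank-deficient
  designs are returned flagged (`rank_deficient`) rather than fitted.
- Count-scaling invariance: multiplying all counts and exp(offset) by c
  leaves coefficients exactly unchanged under the Poisson family
  (`family="poisson"`); under NB2 maximum likelihood the scaled data leave
  the family and the coefficient moves by O(1e-3) — documented, tested at
  both tolerances.
- Percentiles: linear interpolation (type 7) everywhere.
- Weighted median (chromatin split): smallest value whose cumulative
  weight reaches half the total; ties at the split go to the lower bin.
- Gene-length median ties go to "short".
- Degenerate inputs are rejected with actionable messages: constant
  features, constant Z-scores, empty reference/non-selected sets,
  zero-count normalisation references, out-of-range cut indices, log-means
  above 30.
- Determinism: every stochastic routine takes an explicit seed; the CLI
  stamps each run directory with a manifest (seed + config hash), and
  reruns are byte-identical.

## Problem sizes used in the shipped experiments

Replicate-simulation experiments use 5,000 guides (1,250 genes × 4) per
screen for coefficient recovery (100 replicates), 1,000 guides for the
500-fit null-calibration and 300-fit CI-coverage runs, and 5,000 guides
with a 5% carrier fraction for locus-calling recall; oracle comparisons
use 1,000 random 201-nt windows. These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping a full run of
the suite and the reproduction script in the low minutes on one core.

## Known limitations

- Single dispersion per model (no per-guide dispersion shrinkage as in
  DESeq-style estimators); adequate at these depths, but heavy-tailed real
  screens may need robust alternatives.
- Wald inference; no profile-likelihood or resampling intervals.
- The locus-calling AND rule across nine comparisons is deliberately
  strict; under the default study conditions (theta = 10, 500× depth) its
  per-guide recall for a planted interaction of −1 is ≈0.78, i.e. the rule
  trades recall for a near-pure target set (precision ≈1 in the shipped
  experiments).
- The example toxicity score is linear with synthetic-fit default weights;
  it ranks, it does not classify.
- gdsctools-style effect sizes are reconstructed without covariates; panel
  statuses and tissue labels are inputs, never inferred.
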