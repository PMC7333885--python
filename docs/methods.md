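# Methods

This note documents the statistical procedures implemented in
`mirfingerprint`, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the package's known limitations.

## Study design the package targets

A two-stage case/control biomarker study on plasma extracellular-vesicle
miRNA: a discovery screen on an NGS count matrix (miRNAs × samples,
UMI-corrected counts), followed by qPCR relative quantitation of a selected
panel (~34 targets) on two independent cohorts of 10 cases and 10 controls
each. The final deliverable is the *fingerprint*: the set of miRNAs
significant with a consistent direction in both cohorts. Replication across
cohorts — not within-cohort multiple-testing correction — is the primary
error control of the qPCR stage; under the global null the expected number
of false members with two cohorts at α = 0.05 is ≈ 34·α_eff²·½ ≈ 0.03
(α_eff = 0.043 is the exact test's attainable level at n = 10 vs 10, see
below).

## Stage 1 — NGS screen

**TPM and abundance filtering.** TPM(i,j) = count·10⁶/library size. Genes
are kept when their abundance reaches a threshold (default 1 TPM). "Reaches"
is interpreted as *mean TPM across samples ≥ threshold*; a stricter
every-sample rule is selectable (`rule="all-samples"`), since instrument
reports do not always state which convention a "call rate" uses.

**TMM normalization.** Per sample vs a reference sample (the one whose
upper-quartile count fraction is closest to the mean), gene-wise
M = log2 ratio and A = average log2 abundance of the count fractions are
computed on genes expressed in both samples; the most extreme 30 % of M and
5 % of A values (rank-based, `floor(n·trim)` from each end) are discarded;
the surviving M values are averaged with inverse-variance weights from the
delta-method binomial variance (1/y − 1/N terms); the resulting log2 factors
are centred so factors have geometric mean 1. Factors multiply library
sizes. The trim fractions are the method's published defaults. Note the
precision weights mix a sample term and a reference term, so multiplying a
column by a constant changes factors only to second order (tested at
|Δf| < 0.01); M, A and the trim are exactly scale-free.

**Common dispersion.** The negative-binomial dispersion φ (variance
μ + φμ²) is estimated by *conditional* maximum likelihood on counts
rescaled to the geometric-mean library size: within each group the
likelihood of the counts conditional on the gene's group total is free of
the gene mean, so one φ is estimable across thousands of genes at n = 10.
This is a deliberate simplification of quantile-adjusted conditional
likelihood: the rescaling uses plain geometric-mean library equalization
with rounding rather than quantile-matched pseudo-counts. Simulation
recovery is within ±0.02 of the truth at 500 genes for φ ∈ [0, 0.4].

**Exact test.** For each gene, group sums of the equalized counts are
treated as NB with mean nᵍ·μ and dispersion φ/nᵍ; conditioning on the total
gives a one-dimensional split distribution, and the two-sided p sums the
probabilities of all splits at most as probable as the observed one
(minimum-likelihood convention; a tail-doubling variant is available via
`method="doubling"`). At φ = 0 this is exactly the conditional binomial
test. Type-I calibration on null NB simulations is 5 % ± 1 % at 2000 genes.

**FDR.** Benjamini–Hochberg q-values (step-up with monotonicity) are
reported alongside raw p; candidate selection for the qPCR panel uses raw
p < 0.05 unioned with a detected-genes literature whitelist, mirroring how
panels are chosen in practice.

## Stage 2 — qPCR

**QC.** The haemolysis statistic H = Ct(miR-23a-3p) − Ct(miR-451a) flags a
sample when H > 7.0 cycles (strict). The field convention states this check
as a "ratio > 7"; since expression ratios on the linear scale correspond to
Ct differences, H is implemented as the Ct difference with threshold 7.0
cycles — the established form of this statistic. Spike-in assays flag a
sample when any deviates from the plate median by more than 1.5 cycles.
No-template controls fail an assay when a sample amplifies within 5 cycles
of the NTC (a silent NTC passes). **Flagging never excludes**: exclusion is
an explicit option (`exclude_flagged`), off by default, matching the
practice of retaining borderline haemolysis samples.

**Reference-gene selection.** Candidates are ranked by a NormFinder-style
stability value computed on the Ct scale: after subtracting each sample's
mean across candidates (removing loading effects), ρ_i = mean over groups of
(|d_ig| + s_ig/√n_g), where d_ig is the gene's intergroup bias and s_ig its
within-group sd. Lower ρ is more stable; ties break by gene id; with one
group ρ reduces to the standard error. This simplified estimator drops the
published model's shrinkage of d and bias-corrected variance components — it
preserves the ranking behaviour (a 5×-noise gene ranks last in ≥ 95 % of
seeds) while being exactly testable against a hand computation. The panel
size starts at the top 3 (geometric-mean normalization needs ≥ 3) and grows
while V(n, n+1) ≥ 0.05, where V is the sd across samples of
NF_n − NF_{n+1} and NF_n is the mean of the top-n genes' −Ct values. The
0.05 threshold follows the stepwise-inclusion convention of the target
study design; the geNorm literature default 0.15 is selectable, as is
`start_n=2`.

**ΔΔCt chain.** refCt is the arithmetic mean of the selected references'
Cts (the log2 of the geometric mean of their linear expressions); the
calibrator is the *control-group mean ΔCt within the cohort* (so control E
has geometric mean exactly 1, and control medians cluster near 1 — the
pattern seen in published tables); E = 2^−ΔΔCt. Fold change defaults to
mean(E case)/mean(E control); median-ratio and ΔΔCt-of-means bases are
implemented and recorded in output metadata, because published fold
regulations generally cannot be reproduced from printed group medians and
the provider's basis is typically unstated. FR = FC if FC ≥ 1 else −1/FC,
with FC = 1 mapped to FR = 1 and direction "none".

**Testing.** Per target, a two-tailed Mann–Whitney U test on per-sample E.
U counts case-over-control pairs (ties as ½). The exact null pmf of U is
computed by the classic rank-arrangement recurrence and used whenever the
data are tie-free and both n ≤ 25; exact p = 2·min(P(U≤u), P(U≥u)) capped
at 1. Otherwise the tie-corrected normal approximation applies, without
continuity correction. Z is reported with the control-minus-case sign
convention (upregulated ⇒ negative Z), matching the reporting convention of
the studies this design follows. At n = 10 vs 10 the approximation matches
the exact p within 0.01 throughout the decision region (p ≤ 0.1); mid-range
the discreteness gap reaches 0.034, which is why `mode="auto"` prefers the
exact path. The exact test's attainable level just below 0.05 makes its
true type-I rate 0.0433 at 10 vs 10.

**Replication gate.** A target is a member iff p < α in every cohort and
the direction (sign of FR) is identical in every cohort. Non-members are
annotated with the first failing criterion (not-significant / replication /
direction). Lowering α can only shrink the membership; cohort order is
irrelevant. A BH-adjusted variant (`adjust=True`) exists for sensitivity
analyses.

## Synthetic data

`simulate_qpcr_cohort` draws
Ct(i,j) = base_i + shift_j − log2(FC_i)·[case j] + ε on the Ct scale:
additive Gaussian noise — the standard qPCR noise model; assay baselines
uniform on 18–28 cycles (within the 20–30 window typical of plasma EV
panels); per-sample loading shifts N(0, 1.0 cycles) applied to every
non-spike-in assay; spike-ins at a fixed 20 ± 0.15 cycles independent of
loading; haemolysis as a 5-cycle Ct drop on miR-451a in 5 % of samples
(exactly 1 of 20, the single-flagged-sample scenario); miR-23a-3p and
miR-451a baselines pinned at 22 and 19 cycles so the noise-free H is 3
cycles. Default effect sizes are the eight published per-cohort fold
regulations of the fingerprint miRNAs (1.2…4.2 up, −1.7…−7.0 down) on a
34-target panel whose other 26 targets are null, plus 4 stable
reference candidates; target noise sd defaults to 0.25 cycles, which makes
the weakest effect (FR 1.2) borderline at n = 10 vs 10 — deliberately, as
that is how such effects present in practice. One RNG stream per (seed,
cohort) keeps cohorts independent replicates. `simulate_counts` draws
log-normal gene abundances scaled by library size (default 10⁵ — scaled
down from sequencing-scale totals to keep simulations fast; all rate
properties are library-size-free), multiplies DE genes by the fold change
in cases, and samples NB(μ, φ) (Poisson at φ = 0).

What the generator does **not** emulate: amplification-efficiency
differences between assays (no Pfaffl correction exists downstream either),
inter-plate calibration, missing/late Cts from low-abundance targets,
count-matrix composition bias beyond library size (so TMM factors on
simulated data are near 1), and any correlation structure between miRNAs.
Passing recovery tests therefore show the *estimators* are correct under
the stated model, not that real plasma data meet that model.

## Numerical choices and degenerate inputs

- Exact MWU pmf cached per (n1, n2); DP is O(n1·n2²·U) — negligible ≤ 25.
- NB split probabilities in log space, normalized by logsumexp; the
  "at most as probable" comparison uses a 1e-10 log-tolerance to make ties
  between symmetric splits robust to rounding.
- Dispersion optimized on log φ in [1e-6, 20] (bounded Brent); estimates at
  the lower boundary report φ = 0.
- All-tied Mann–Whitney data: p = 1, Z = 0, method "degenerate". All-zero
  count rows: p = 1. All-zero samples: error naming the sample.
- Stability ties break lexicographically by gene id; rank is 1-based.
- Missing reference Cts exclude the sample from quantification with a
  warning; missing target Cts drop the sample for that target only.
- Reference selection runs per cohort (each experiment is an independent
  plate with its own Ct scale). Reference/target overlap is permitted with
  a warning, since panels sometimes nominate a measured target as a
  housekeeping gene.

## Problem sizes in tests

Calibration checks use 10 × 2000 null targets (per-cohort type-I error),
200 two-cohort null studies of 34 targets (replication gate), 20 seeds for
the V(3,4) recovery, 50 seeds for fold-change recovery at f ∈ {1.4, 2, 4},
and 100 seeds for ranking robustness — sizes chosen so binomial/MC sampling
error is small against each stated tolerance.

## Known limitations

- The NB screen approximates quantile-adjusted conditional likelihood with
  geometric-mean equalization plus rounding; at strongly unequal library
  sizes the rounding perturbs very-low-count genes most.
- The stability estimator is NormFinder-*style*; its ρ values are not
  numerically comparable to the published tool's, only the ranking is.
- No amplification-efficiency correction; the 2^−ΔΔCt model assumes 100 %
  efficiency for every assay.
- The normal-approximation path has no continuity correction (documented
  above); use exact mode at small n, which `auto` does.
- Single-plate assumption: no inter-plate calibrators.
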