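# Methods

This package reconstructs, as tested code, an analysis chain for
longitudinal nasal-mucosa expression profiling of acute respiratory illness
(ARI, the "common cold") across four clinical groups — Healthy, allergic
rhinitis (AllrgRhin), asthma without exacerbation (AsmNoEx) and asthma with
exacerbation (AsmEx) — sampled at an asymptomatic baseline (BL) and on
illness days 2 (D2) and 6 (D6). Illness is treated as three stages: peak
(BL→D2), reduction (D2→D6) and resolution (D6→BL). Because the matching
clinical microarray data are not required, every stage is exercised on a
synthetic cohort generator that plants known gene programmes, so each
claim the test suite makes is checked against ground truth.

## Synthetic cohort model

Per gene g and sample (subject s, group j, time t):

    y_gst = mu_g + delta_g(j, t) + b_gs + e_gst

with baseline mean `mu_g ~ U(4, 14)` log2 units (typical array intensity
range), residual `e ~ N(0, sigma^2)` with `sigma = 0.5` log2 units, and a
subject-level random intercept `b ~ N(0, sigma_b^2)` with
`sigma_b^2 = rho/(1-rho) * sigma^2`, so repeat visits of a subject have
equicorrelation `rho = 0.3` — exactly the covariance the inference stage
assumes. Planted programmes `delta`:

* **core-D2** (60 genes): +1.5 log2 at D2 in all groups — the shared innate
  antiviral response at the peak of symptoms;
* **shared-D6** (70 genes): +1.5 log2 at D6 in Healthy, AllrgRhin and
  AsmNoEx — the mucosal-repair programme that exacerbating asthmatics fail
  to mount;
* **distinct-D6** (90 genes): −1.5 log2 at D6 in AsmEx only — the
  exacerbation-specific signature.

Defaults: 4 groups × 8 subjects × 3 visits, 5,000 genes, no missing
visits; missing visits, when enabled, drop a whole subject-visit sample.
A single `SeedSequence` keyed by the seed spawns one child stream per
stage, so any stage regenerates bit-identically.

What the generator does *not* emulate: probe-level array artifacts
(background, control probes, quality weights), heavy-tailed or
intensity-dependent noise, correlated gene programmes beyond the planted
blocks, virus genotypes, or subject dropout correlated with severity.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own model assumptions, not robustness to real
microarray pathology.

Clinical diaries are generated alongside: a 7-day baseline week and a
10-day illness window of daily symptom scores, albuterol puffs and PEF,
plus per-visit FEV1. Subjects planted as exacerbating meet criterion 2 of
the adjudicator by construction (symptoms +12 points for 3 days, margins
≥1 point clear of the +10 threshold, plus one objective change rotating
among the albuterol, FEV1 and PEF branches); planted negatives stay ≥5
points inside every threshold, so the adjudicator's agreement is a sharp
contract, not a statistical one.

## Differential expression

A cell-means linear model over the 12 group × timepoint cells is fit per
gene by generalized least squares under block equicorrelation: visits of
one subject share a single consensus correlation, subjects are
independent. One Cholesky whitening of the 96 × 96 correlation matrix is
shared by all genes. With rho = 0 the fit reduces exactly to OLS (tested
to 1e-12).

**Consensus correlation.** Per gene, residuals about the cell means are
decomposed into between- and within-subject mean squares pooled over
groups (method of moments; only subjects with ≥2 retained visits
contribute, and the pooled degrees of freedom subtract the cell-mean
constraints so E[MSW] = sigma^2 in the balanced case). The intraclass
estimate `(MSB − MSW) / (MSB + (n0 − 1) MSW)` is clamped to
(−0.95, 0.99); the consensus is the 15% two-sided trimmed mean on the
atanh scale, back-transformed. Tests recover rho = 0.3 within ±0.05 from
2,000 genes and agree with REML (limma `duplicateCorrelation`, run through
Rscript as an independent oracle) within 0.08.

**Moderation.** Residual variances are shrunk through the scaled-F
hierarchy: the prior (d0, s0²) is moment-matched from the mean and excess
variance of `log s_g^2` via the digamma/trigamma identities (trigamma
inverted by Newton iteration); the posterior variance is
`(d0 s0^2 + d s^2)/(d0 + d)` and the moderated t is referred to t on
d0 + d degrees of freedom. When the log-variance dispersion is at or below
its sampling minimum, d0 is capped at 1e6 and s0² is the geometric mean of
the observed variances, so identical variances shrink to themselves. The
whole path reproduces limma's `eBayes` (t to 1e-5 relative, d0 within 5%)
on shared inputs. A B statistic (log posterior odds) is reported with a
fixed prior DE proportion of 0.01 and a fixed prior variance ratio of 10;
it is never used for selection.

**Selection.** Family-wise error is controlled per contrast with Holm's
step-down adjustment (family = all genes of one contrast); a
Benjamini–Hochberg column is emitted alongside. The three time-point
contrasts (D2−BL, D6−D2, D6−BL) are time main effects averaged with equal
weight over groups. Because a programme confined to one of four groups is
diluted fourfold in the averaged contrast (for the planted distinct-D6
effect: |b| = 0.375, SE ≈ 0.125, t ≈ 3 — hopeless against a Holm threshold
of |t| ≈ 4.4 over 5,000 genes), the selection union additionally includes
the twelve within-group time contrasts; without them no group-specific
signature could ever reach the PCA stage. The ARI gene set is the union of
Holm < 0.05 genes over all these contrasts, with no fold-change cutoff.
Under the global null the raw p < 0.05 fraction is 0.05 ± 0.01 and the
observed family-wise error over 200 replicate families is ≤ 0.07 (families
of 300 genes at 4 subjects/group — sizes chosen to keep the replicate
study desk-scale; the error rate is size-free).

## PCA signatures

PCA is computed on covariance matrices (genes centred, never scaled) via
SVD of the centred sample × gene matrix, so 2,456-gene/16-sample blocks
pose no problem; variance explained is relative to total gene variance.
PC1 sign is intrinsically arbitrary: it is fixed per transition so the
symptomatic reference time point (D2 for peak and reduction, D6 for
resolution) has non-negative mean score; component signs below PC1 are
canonicalised by largest-|loading|. Separation of the two time-point
clusters along PC1 is tested by paired t (complete subject pairing) or
Mann–Whitney U (otherwise).

Per group and focal time point, the signature profile is the top
N = 100 genes by PC1 loading — most positive when the focal samples' mean
score is positive, most negative otherwise; ties break lexicographically
by gene id, and a focal mean within 1e-9 of zero defaults to positive with
a warning. Profiles of the four groups are intersected into the full Venn
region table; classes: `core` (all groups), `distinct:<g>` (exactly one),
`shared:<subset>` (any strict subset of ≥2). The full region table
subsumes any particular enumeration of pairwise/3-way comparisons.

**Known limitation (deliberate, documented):** with the default synthetic
conditions the ARI universe is ~220 genes, the same order as N = 100. Two
consequences follow. (1) In the AsmEx reduction PCA, the 60 core genes
(falling from D2) and 90 distinct genes (falling into D6) carry
identical-magnitude centred patterns, so at most 100 of ~150 equally
loaded genes fit one profile. (2) The other groups' profiles, with only 60
true declining genes each, fill their remaining slots from the same small
pool and absorb distinct genes into `shared:*` classes. Measured
distinct-D6 recovery is therefore ~14% even though the `distinct:AsmEx`
calls that are made are 100% planted (purity 1.0, tested). Core-D2
recovery at the peak is 100% with zero leakage into distinct classes.
Both effects vanish as the gene universe grows relative to N (the original
design ranked 2,456 genes for the same N = 100); they are properties of
the profile-size convention, not bugs, and N is configurable.

## Kinetics and clustering

Mean log2 trajectories per (group, timepoint) cell are min–max scaled per
gene across all cells jointly, so each non-constant gene attains exactly
0 and 1; constant genes map to 0.5 and are flagged (keeps kinetics tables
drawable instead of erroring). Log2 fold changes between time points use
subject-matched differences when pairing is complete, cell means
otherwise, and are antisymmetric under transition reversal. Hierarchical
clustering is UPGMA on Euclidean distances, written from scratch for
deterministic tie-breaking (smallest cluster-id pair) with the unweighted
Lance–Williams update; merge heights match both a brute-force O(n³)
recomputation and `scipy.cluster.hierarchy.linkage` to 1e-9. Clustering
rows are genes with per-group fold-change vectors concatenated.

## Clinical statistics

The exacerbation adjudicator implements the a-priori definition: either
care-seeking / corticosteroid escalation, or a symptom-score rise ≥10
points over the baseline-week daily mean on ≥2 illness days *plus* at
least one objective change (≥4 puffs/day over the baseline mean on ≥2
days; FEV1 at an illness visit ≤90% of baseline; PEF on ≥2 days ≤80% of
the best baseline-week value). Twice-daily diary entries are averaged to
daily values before thresholding, which makes the "≥2 days" counts well
defined; all comparisons are inclusive, exactly as the thresholds are
printed. Non-asthmatic subjects are trivially negative with a note, and a
full per-day evidence trace is returned.

Rank statistics are implemented in-package with scipy as the
cross-checking oracle, not the implementation: Friedman's test uses
within-block midranks with the tie-corrected quadratic form
`(k−1) Σ(R_j − n(k+1)/2)² / (Σ r² − nk(k+1)²/4)`; Mann–Whitney U is exact
by a dynamic programme over tie groups of the pooled sample for n ≤ 8 per
side (two-sided p sums both tails of the permutation distribution of U)
and tie-corrected normal with continuity correction beyond; Spearman is
the Pearson correlation of midranks with exact permutation p for n ≤ 7.
qPCR abundances are normalised as `2^-(Ct_target − mean(Ct_GAPDH,
Ct_PPIA))` — averaging reference Cts equals normalising to the geometric
mean of the two housekeeping abundances — and fold changes are ratios of
normalised values.

## Pipeline, I/O, determinism

All tables are plain TSV with "%.10g" floats; writing then reading is the
identity, and rerunning any stage with the same configuration and seed is
byte-identical (the run manifest and log carry timestamps and are the
documented exception). The config file is flat `key = value`; unknown keys
fail fast. An empty ARI selection (e.g. alpha = 1e-12 on null data) skips
the downstream stages with an explicit "skipped" status instead of
erroring. A GEO series-matrix parser (with accession validation before any
network access) provides an optional import path for the archived data;
no test touches the network.

## Numerical choices

* Per-gene ICC clamp (−0.95, 0.99): keeps atanh finite and the GLS
  correlation matrix positive definite.
* Trigamma inversion: Newton from `x0 = 0.5 + 1/y`, 50-iteration cap,
  relative tolerance 1e-10.
* Exact-test cutoffs (U: n ≤ 8 per side; Spearman: n ≤ 7) chosen so the
  enumerations stay instantaneous while covering the study's group sizes.
* Moderated-t p-values with capped d0 = 1e6 are numerically the normal
  tail, which is the intended limit.
* PCA components beyond min(n−1, p) are truncated; variance-explained
  proportions are nonincreasing and sum to ≤ 1.

## Problem sizes used in validation

The validation suite and the reproduction script use the default cohort
(5,000 genes, 32 subjects, ~2 s per run), a 2,000-gene null cohort for
correlation recovery, 200 replicate 300-gene null cohorts for the
family-wise error study, 1,000 random vectors for the Holm oracle, all
2 ≤ n1, n2 ≤ 6 sample-size pairs (with and without ties) for the exact
Mann–Whitney oracle, and five random 10 × 4 matrices for the UPGMA oracle.
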