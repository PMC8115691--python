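# Methods

This note documents the statistical models implemented in `asbkit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Problem setting

ChIP-seq reads covering a heterozygous SNV split between the two alleles.
Under no allele-specific binding (ASB) and a copy-balanced locus, the
reference-read count is binomial with p = 1/2. Two confounders break this
null: local copy-number variation and aneuploidy shift the expected allelic
ratio away from 1:1 segment-wise, and reference-mapping bias inflates
reference reads globally. The pipeline therefore (i) estimates the
segment-wise **background allelic dosage** (BAD — major:minor copy-number
ratio) directly from the SNV calls, with no genomic-control track, and
(ii) tests imbalance against count backgrounds *fitted to the data*, which
absorb the mapping bias, before (iii) aggregating evidence across datasets.

## Eligibility filters

A call enters the analysis when it is a biallelic heterozygous SNV
(genotype 0/1), has ≥ 5 reads on *each* allele, appears in a whitelist of
known common SNPs, and lies on a chromosome retaining ≥ 100 eligible calls.
The whitelist excludes de novo point mutations, whose allelic fractions
track clonal composition rather than copy number or binding. The per-allele
read floor (5) reappears as the truncation bound of every distribution
below; using one constant in both places keeps the models consistent with
the data they see.

## BAD calling

For each SNV, the statistic is x = min(C_ref, C_alt) with coverage
n = C_ref + C_alt. Given BAD = b, C_ref follows an equal-weight mixture of
Binom(n, 1/(b+1)) and Binom(n, b/(b+1)) — the two possible phasings of the
het site onto the major haplotype — truncated to 5 ≤ k ≤ n − 5 and
renormalised. The two components are mirror images under k ↦ n − k, so
they share one truncated normaliser, and
P(min = x) = f_p(x) + f_p(n − x) (a single term when x = n − x).
A coverage of n < 10 leaves an empty truncated support and is rejected.

Admissible BAD values form the discrete grid
{1, 4/3, 3/2, 2, 5/2, 3, 4, 5, 6} (total copy number of a locus rarely
exceeds 7) with a uniform prior.

**Preprocessing.** Chromosomes are split wherever neighbouring SNVs lie
more than `gap_bp` apart (default 1 Mb) — such gaps flag deletions,
centromeres and loss-of-heterozygosity regions where BAD cannot be
followed. Regions left with < 3 SNVs are excluded and reported.

**Segmentation.** Changepoints between consecutive SNVs maximise

    Σ_segments log [ Σ_b prior(b) Π_i P_b(x_i) ]  −  (#changepoints) × penalty

by dynamic programming over prefix sums of the per-SNV, per-BAD
log-likelihood matrix (log-sum-exp throughout, O(n²·|grid|)); the optimum
is global, segments must contain ≥ 3 SNVs, and boundaries sit at midpoints
between flanking SNVs. Each segment is assigned the maximum-posterior BAD,
ties breaking toward the smaller value (fewer implied copies).

**Changepoint penalty.** The default of 10 (log-likelihood units) was
calibrated on simulated data: on homogeneous diploid regions the largest
spurious single-split gain observed was ≈ 0.3 (the marginal likelihood
itself penalises overfitting), while true BAD-1→2 boundaries flanked by 50
SNVs at coverage 40 gain 19–33. The default sits far from both, making the
caller insensitive to the exact value over roughly an order of magnitude;
it is exposed as a config knob for unusually sparse or noisy inputs.

**Evaluation.** Against a ground-truth markup, the map is scored by
SNV-level Kendall τ_b between predicted and true BAD (recurrent SNVs
counted once, SNVs outside the truth ignored), plus per-BAD one-vs-rest
ROC/PR curves obtained by thresholding the classifier score
S = L(BAD = x) − max_{y≠x} L(BAD = y), which is positive exactly when the
segment's assigned BAD (uniform prior) equals the queried one.

## ASB scoring

For every cell (BAD, fixed allele, fixed count m ≤ `max_m`, default 200),
the count X on the other allele across all SNVs of all datasets in that
cell is modelled as

    X ~ (1 − w) NB(r, p) + w NB(r, 1 − p),    p = 1/(BAD + 1),

NB(r, p) counting successes before r failures with success probability p,
truncated to X ≥ 5 via A = 1 − P(X < 5). p is fixed by the BAD and never
fitted; r > 0 and w ∈ [0, 1] are estimated by L-BFGS-B from the initial
point (r = m, w = 0.5). Goodness of fit is the RMSEA index over count bins
pooled right-to-left until each holds expected mass ≥ 5 (the rightmost bin
absorbs the infinite tail), with df = bins − 3 and
RMSEA = sqrt(max(0, χ²/df − 1)/(N − 1)). Cells with RMSEA > 0.05,
undefined RMSEA, fewer than `min_obs` (default 50) observations, m beyond
`max_m`, or failed optimisation fall back to r = m, w = 1 — a null whose
mean is m·BAD, deliberately penalising significance where the background
could not be learned. The binning rule is this package's choice; RMSEA
itself does not prescribe one. `min_obs` = 50 reflects that a two-parameter
fit plus a χ²-based gate is meaningless on a handful of counts; `max_m`
caps the cells at coverages where data are too sparse to populate them.

One-tailed P values are P(X ≥ c | X ≥ 5), computed from the exact mixture
survival function — for c = 5 the P value is 1 by construction. Effect
sizes are ES = log2(c / E[X | X ≥ 5]) with the truncated expectation
computed in closed form from the component means minus the sub-threshold
mass. At BAD = 1 and moderate counts this approaches log2(C_ref/C_alt);
at BAD > 1 it lands between log2(c·BAD/m) and log2(c/(BAD·m)) according to
the fitted haplotype weights.

Fitting r freely is what absorbs reference-mapping bias: on biased data the
fitted r for reference-count cells exceeds that of alternative-count cells
at the same m, shifting both backgrounds toward what the reads actually do.

## Aggregation

SNPs are grouped per TF (across cell types) and per cell type (across
TFs); observations sharing position but differing in alternative allele are
distinct candidates. A group is a candidate when its best dataset reaches
total coverage ≥ 20. P values are combined with the logit method:
T = −Σ ln(p_i/(1−p_i)) referred to T/c ~ t(5k+4),
c = sqrt(k π² (5k+2) / (3(5k+4))). Inputs equal to 1 carry no directional
information and are excluded (all excluded ⇒ combined P = 1); exact zeros
are clamped to 1e−300, never excluded. The scaled-t reference is an
approximation; for a single P value the round trip deviates by < 0.02
absolute over [0.001, 0.999], which the tests pin down. The method cancels
symmetric evidence ({0.01, 0.99} → 0.5) — the property that motivates it
over Fisher's — and is less extreme-value-sensitive than Stouffer's.
Natural logarithms are used in both the statistic and the effect-size
weights (−ln p); weights only need relative scale, so the base is a
convention, documented here once.

BH correction is applied within each (group, allele); an SNP is an ASB when
min(FDR_ref, FDR_alt) ≤ 0.05. Aggregated effect sizes are −ln(p)-weighted
means over datasets with p < 1, undefined when every p = 1.

## Motif annotation

PWMs are position-wise additive log-odds matrices (HOCOMOCO-style text;
non-negative matrices are treated as counts/frequencies and converted
against the background with a pseudo-weight of one count). Hit P values —
P(random background window scores ≥ s) — are exact on a discretised score
grid (step 1e−3, configurable): the score distribution is built by
convolving one motif position at a time, and all window scoring uses the
same quantised weights, so the distribution and the queries can never
disagree at bin edges.

For each SNP, every motif-length window covering it is scored on both
strands with both alleles substituted; the window maximising the better
allele score is fixed (ties: forward strand, then leftmost), and both
allele P values are taken there. The fold change is
FC = log2(pval_ref/pval_alt), positive when the alternative allele has the
stronger hit. Classification: `no_hit` when min(pval) > 0.0005; `weak`
when |FC| < 2, min(FDR) > 0.05, or the FDRs tie; otherwise `concordant`
when the ASB-preferred allele (smaller FDR) is the stronger-motif allele
(smaller motif P value), `discordant` otherwise. Where the two alleles'
individually-best windows differ, the shared best window is used — the
comparison is only meaningful at one fixed position.

## Synthetic data

The generator emulates the pipeline's data model end to end: a genome
partitioned into constant-BAD segments (default two 10 Mb chromosomes,
segments drawn from BAD {1, 2, 3}); SNVs placed by a Poisson process
(default one per 10 kb — the realistic density of well-covered common het
sites in pooled ChIP-seq calls); per-dataset totals drawn negative-
binomially (mean 40, dispersion 0.3); allelic splits beta-binomial with
intra-class correlation 0.02 so that downstream fits are exercised
slightly off-model, as with real reads; haplotype phasing drawn once per
cell type (one cell line per series); an optional multiplicative
reference-bias factor on the reference odds (default 1 — bias is switched
on explicitly where a test needs it); and planted ASB effects (default 5%
of SNVs, +1 log2 odds, random preferred allele) assigned per (SNV, TF).
The default design is 2 TFs × 2 cell types × 2 replicate datasets. Motif
cases plant consensus matches where one allele weakens the site, with ASB
direction either matching (concordant) or opposing (discordant) the
stronger-motif allele, plus scrambled no-hit contexts. Output files are
the pipeline's real input formats (single-sample VCF with GT/AD, metadata
TSV, whitelist, truth BED, PWM text, case table), byte-identical under a
fixed seed.

What it does *not* emulate: read-level artifacts (duplicates, mismatch-
dependent mapping, base quality), correlated biases across SNVs, subclonal
copy-number states off the BAD grid, and linkage between neighbouring
SNVs. Passing recovery tests on this generator therefore demonstrates
correctness of the estimators under the stated model (and mild
overdispersion), not performance on any particular real dataset.

## Numerical choices and test problem sizes

All likelihood arithmetic is in log space with log-sum-exp; mixture tail
and expectation sums use exact survival functions rather than truncated
series. TSV outputs are written at 6 significant digits, making repeated
runs byte-identical. Exact-enumeration oracles back the three hand-rolled
primitives: rational-arithmetic enumeration of the truncated binomial
(all n ≤ 60), exhaustive changepoint search (regions ≤ 12 SNVs, 200 random
instances), and 4^L enumeration of PWM score distributions (L ≤ 6).
Recovery suites use desk-scale problems chosen to keep the full test run
in a few minutes while leaving comfortable statistical margins: BAD
recovery on six segments × 120 SNVs at coverage 35 over 10 seeds; mixture
recovery on 5000 draws; calibration on 10 000 null P values; FDR control
over 20 replicates of 150 SNPs × 2 datasets; end-to-end determinism on a
20 Mb, 8-dataset bundle run twice.

## Known limitations

- The changepoint objective reconstructs the stated components (truncated
  binomial likelihood, uniform discrete prior, marginal likelihood,
  maximum posterior) with an explicit per-changepoint penalty; other
  implementations may use a different penalty constant, shifting exactly
  where borderline splits land.
- Under allelic overdispersion, neighbouring grid BADs (1 vs 4/3) become
  nearly indistinguishable, and very long homogeneous diploid segments can
  drift one grid step; this mirrors the intrinsic resolution of the grid
  rather than a failure of the optimiser.
- Each dataset's BAD map comes from its (cell type, series) group; SNVs in
  excluded regions (gaps, tiny regions, sparse chromosomes) receive no ASB
  calls at all rather than a default BAD.
- The NB mixture is fitted per fixed count m with no smoothing across m;
  sparse cells fall back to the conservative null rather than borrowing
  strength. Beta-binomial alternatives are out of scope.
- Aggregation treats datasets as independent; shared donors or technical
  replicates violate this and make combined P values optimistic, as in any
  meta-analytic combination.
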