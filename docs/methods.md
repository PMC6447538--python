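# Methods

This note documents the models, procedures, defaults and design choices
behind `hypertad`, and what the synthetic-data tests do and do not show
about real data.

## Scientific setting

High-hyperdiploid (HeH) leukemia carries nonrandom whole-chromosome gains.
Two linked questions drive the toolkit: (i) how the extra chromosomes dose
RNA and, more weakly, protein expression (cis effects on the gained
chromosome, trans effects elsewhere), and (ii) whether chromatin
architecture — specifically the insulation of TAD boundaries, maintained
by CTCF and cohesin — is weakened in this subtype, dysregulating genes
near boundaries. Every analysis stage is exercised on simulated cohorts
with planted truth, because the corresponding patient data are access
controlled.

## Hi-C model and processing

**Contact matrices.** Per-chromosome, symmetric, binned (0-based half-open
bins; bin *i* covers `[i·b, (i+1)·b)`), with a per-bin exclusion mask and
balancing weights. Text interchange: BED3+id bin table and upper-triangle
`bin1 bin2 count` pixels.

**Low-coverage filtering (MAD-max, default 2).** With `m` the marginal
totals of nonzero unmasked bins, a bin is removed iff
`(median(log m) − log m) / MAD(log m) > 2`, one-sided: only low-coverage
bins go, because the cutoff targets dropout artifacts. Two choices were
genuinely open and are fixed here: the statistic uses **log** marginals,
and MAD is the **consistency-scaled** robust sigma (1.4826 × raw MAD); an
unscaled MAD makes "2 MADs" only ≈1.35 σ and removes far more than
dropouts. The decision is single-pass on the input marginals. It is
idempotent in the regime it targets — masked bins contribute negligibly to
the surviving marginals — which is where the test suite checks it; a
literal fixed-point iteration is not used because on matrices whose
marginal spread is dominated by structure (e.g. bias-free simulated
matrices) it cascades until everything is masked. For the same reason the
simulated pipelines skip this filter: the generator plants no coverage
bias, so there is nothing for it to remove (the CLI exposes `--madmax 0`).

**Short-range artifacts.** The main diagonal and ±1 off-diagonals are
zeroed (same-bin and adjacent-bin ligation products).

**Balancing.** `ice`: iterative proportional fitting until the coefficient
of variation of unmasked marginals falls below `tol` (default 1e-5, max
200 iterations; non-convergence returns best weights with a flag), then
normalized so the mean unmasked balanced marginal is 1. `caicb`: ICE per
chromosome, then for each genomic-distance band the chromosome's mean
balanced contact is rescaled to the cross-chromosome mean of that band.
Per-chromosome ICE with unit-marginal normalization already removes any
whole-chromosome multiplicative (copy-number) bias; the band adjustment
additionally equalizes distance-decay shape across chromosomes, which is
the property an aneuploid genome needs before chromosomes are compared.
This band-rescaling formulation is this package's operational definition
of chromosome-adjusted correction.

## TAD architecture

**Directionality index.** For each bin, A and B are the balanced contact
sums to the upstream/downstream window (default 500 kb; a window sweep is
exposed but 500 kb is the default working point), E = (A+B)/2, and
`DI = sign(B−A)·((A−E)²/E + (B−E)²/E)`, zero when A = B or A + B = 0.
Standardization to z-scores is genome-wide by default (per-chromosome via
`scope="chrom"`). Boundary rule: a switch from ≤ −t to ≥ +t within ≤ g
bins (defaults t = 0.5, g = 2) places a boundary on the bin edge between
the last negative and first positive bin; strength is the z jump. This
deterministic rule replaces an HMM-based caller: it needs no fitted
emission parameters, and planted-truth recovery validates it (≥ 95 % of
fully insulating boundaries within ±1 bin at ≥ 50 counts per
near-diagonal pixel — in practice 100 % in the acceptance runs).

**Insulation.** Mean balanced contact in the square of `s = square/b` bins
upstream × downstream of each bin (defaults: 250 kb square, 125 kb delta
span at 25 kb bins), log2-normalized by the genome-wide median (so the
median of finite scores is 0 by construction). The delta at bin *i* is
the mean score over `(i, i+span]` minus `[i−span, i)`; boundaries sit at
upward zero-crossings whose swing (max after − min before within the
span) reaches 0.1 log2 units, the swing being the strength. The
insulation caller is deliberately permissive at this default; downstream
matching filters by strength.

**Boundary profiles.** Median z-DI or insulation score in ±500 kb around
aligned boundary positions, medianed per offset. Profile amplitude
(max − min) is monotone in planted boundary strength; the acceptance
suite checks strict monotonicity across strengths 1.0 / 0.75 / 0.5 / 0.25.

**Compartments.** At 500 kb: observed/expected by distance, correlation
matrix, leading eigenvector (dense symmetric eigendecomposition), sign
oriented to a gene-density track; A = positive.

## Boundary comparison

Boundaries from different samples within ±100 kb are the same boundary
(greedy one-to-one nearest-neighbor matching; ties by distance then
leftmost). A matched boundary with strength below `weak_threshold` is
*weak*; unmatched reference boundaries are *lost*. Recurrent
subgroup-specific loss: weak/lost in ≥ 2 samples of one group and — by
default (`strict=True`) — present in every sample of the other group; the
lax variant drops the second condition since the original criterion can
be read either way.

The strong/weak/lost trichotomy replaces a visual contact-map inspection
with an insulation proxy: *lost* if no upward delta zero-crossing with
swing ≥ `b_lost` lies within ±100 kb, *weak* below `b_weak`, else
*strong*. The thresholds were calibrated once on simulated matrices at
the default depth (swing distributions at planted strengths 0, 0.1, 0.15,
0.25, 0.5, 1.0): noise-only swings stay below ≈ 0.08 while fully
insulating boundaries swing above ≈ 1.5, giving `b_lost = 0.08`,
`b_weak = 0.5`.

Direction enrichment near lost boundaries: among significant DE features
(BH ≤ 0.05) with TSS within 1 Mb of any lost boundary (point-to-TSS
distance), the down/up split is tested against the genome-wide DE down
fraction with a 1-df goodness-of-fit chi-square, no continuity
correction. On the reported counts — 98 down of 134 against 2222/4645 —
this yields χ² = 34.4, P = 4.6e-9, which is how the null was pinned down.

## Dosage effects

Normalized copy number per chromosome = cohort average of
(Σ copyᵢ·lengthᵢ / chromosome length) / normal ploidy; ploidy is 2 for
autosomes, 1 or 2 for sex chromosomes, undefined otherwise (chromosome
excluded). Segment gaps are imputed at normal ploidy with a log message
rather than an error, because SNP-array segment exports routinely omit
normal regions. Per-feature Cohen's d uses the pooled-sd form; the
per-chromosome value is the unweighted mean of feature d (a weighted
variant exists). OLS of per-chromosome d on normalized copy number;
*affected* = d strictly > 0.3.

CNA genes: copy number deviating from the per-gene modal value in
strictly more than 3 samples (the reference state is operationalized as
the mode). The cis/trans map computes Spearman correlations between each
CNA gene's copy vector and every feature via rank-standardized matrix
products, with t-approximation p-values and BH over all tested pairs;
constant vectors are excluded from the family; cis = same gene
identifier.

## Expression analytics

- Expressed genes: CPM strictly > 1 in strictly > 80 % of samples of at
  least one group.
- Differential expression: Welch t on log-scale values with BH control.
  This supplies exactly what downstream stages consume (log2 fold change,
  adjusted p, direction) without a count-model dependency; it has
  somewhat less power than moderated count models (closed-form power at
  the planted-shift test conditions is ≈ 0.8, and the test asserts
  sensitivity ≥ 0.7 at observed FDR ≤ 0.1).
- Iterative empirical controls (10 iterations, control threshold BH
  p > 0.9, k = 2 factors): start from per-sample median-normalized data;
  controls are null-looking features; factors are the leading right
  singular vectors of the group-mean-centered control submatrix —
  centering makes them exactly orthogonal to the group contrast, so the
  biology is protected — regressed out of the full matrix; controls are
  re-derived each iteration. A factor is only removed when its singular
  value exceeds the Marchenko–Pastur expectation for iid noise of the
  same shape (robust σ, 5 % margin); on structureless data no factor
  clears the bar and the matrix passes through unchanged. `k = 0`
  degenerates to median normalization.
- mRNA–protein correlation: per-gene Spearman across samples (≥ 6 paired
  finite values), BH over genes; complex co-regulation compares
  within-complex pairs to random pairs (Mann–Whitney); subtype-partial
  correlation residualizes both vectors on the subtype indicator before
  ranking, guarding against pooled-group (Simpson) artifacts.
- CMS: per-case mean of 1–3 metaphase scores, group mean = mean of case
  means (pooling all metaphases is available via a flag; both variants
  are exercised), one-sided Mann–Whitney with the first group as the
  putatively lower one.

## Synthetic-data generator

A single integer seed feeds named substreams (hic / expression /
annotations / cms / cohort), so adding a generator never shifts existing
draws; fixed seed ⇒ byte-identical outputs.

**Hi-C.** Expected contact
`depth · (1+|i−j|)^(−α) · m(i,j)`, with m = `enrichment` within a domain
and `1 + (enrichment−1)(1−s_min)` across boundaries, `s_min` the weakest
crossed boundary strength; counts are Poisson, symmetric. Defaults:
depth 60, α = 1, enrichment 3 — giving ≈ 60 counts at the nearest used
diagonal, a deeply sequenced 25 kb map. Domain edges must lie on the bin
grid. No per-bin visibility bias is planted; consequences for the
coverage filter are noted above.

**Expression.** Log2-scale. RNA = baseline (N(5,1) per gene) +
dosage_exponent·log2(copy/ploidy) + TAD factor (per-domain per-sample
N(0, 0.25), only in subtypes with coupling on) + batch term (per-gene
loading N(0, 0.2) × per-batch score) + N(0, 0.5) noise. Protein =
attenuation × (RNA signal without its noise) + complex factor
(per-complex per-sample N(0, 0.3) over 20 complexes of 5) + independent
N(0, 0.5) noise. Defaults chosen once as a plausible regime: attenuation
0.5 encodes "dosage effects weaker at the protein layer"; TAD factor sd
0.25 gives modest within-domain co-expression, and the TAD-coupling
readout is run at coupling sd = noise sd, the condition under which the
same/different-TAD gap is assessed. Copy numbers are whole-chromosome
integers (the hyperdiploid karyotype); segment-level events are supported
in the file format but not generated. Noise is Gaussian on the log scale
— downstream statistics are rank-based, so the family is not critical.

**Annotations.** CTCF/RAD21 peaks at every boundary (±10 kb jitter) plus
Poisson background (default 5/Mb); ChIA-PET interactions join the two
edges of each domain with PET counts uniform in [10, 50]; a configurable
fraction (default 0.7) appears identically in both assays.

**CMS.** Score = 1 + Binomial(2, p) per metaphase with p set per case so
case means center on the group mean (case-level sd 0.15); group means
1.8 vs 2.1 with 37 vs 33 cases of 20 metaphases reproduce the reported
cohort structure.

## Problem sizes used in tests and the acceptance script

- Boundary recovery: 3 chromosomes × 20 Mb at 25 kb (20 boundaries),
  depth 60.
- Strength monotonicity: same genome, strengths 1.0/0.75/0.5/0.25,
  profiles at planted positions.
- Dosage recovery: 12 chromosomes × 10 Mb, 4 disomic / 4 gained in half
  the HeH samples / 4 gained in all, 20 vs 20 samples, 1200 genes. Twelve
  regression points keep the protein/RNA slope-ratio estimate stable;
  the ratio runs slightly above the planted attenuation (≈ 0.54 vs 0.5)
  because partially gained chromosomes inflate the RNA pooled sd more
  than the protein one — a property the patient design shares.
- cis/trans: 6 chromosomes, 300 features, 20 CNA genes, 20 null seeds;
  planted regulator adds one log2 unit per extra copy to 50 features.
- TAD coupling: 6 chromosomes, 600 genes, coupling on in one subtype
  only; ≥ 2000 gene pairs per readout.
- Rank-test calibration: 1000 null replicates per test, size asserted
  within 3 binomial standard errors of α = 0.05.

## What passing tests do and do not show

The generator plants exactly the structures the pipeline looks for, with
Poisson/Gaussian noise and none of the confounders of real data: no
mappability or GC bias (hence the coverage filter is validated separately
on planted dropouts), no translocations or segmental CNAs, no nested or
overlapping TAD hierarchy beyond two reference sets, no count
overdispersion, and protein attenuation uniform across genes rather than
pathway-dependent. Recovery rates and calibration measured here are
therefore upper bounds on real-data performance; the value of the tests
is that they verify the implementations compute the quantities they
claim, at the stated operating points.

## Known limitations

- The insulation boundary caller overcalls at its default swing
  threshold; consumers should filter by strength (matching does).
- caICB here is a band-rescaling reconstruction, not a re-derivation of
  the original correction algorithm.
- The Welch DE test trades power for simplicity relative to moderated
  count models.
- `classify_boundary_change` thresholds are calibrated to the default
  simulation depth; other depths need recalibration.
- Cross-chromosome (trans) Hi-C contacts are out of scope throughout.
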