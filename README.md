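# hypertad

Analysis toolkit for studying how whole-chromosome gains in high-hyperdiploid
(HeH) leukemia propagate to gene expression — dosage effects on the RNA and
protein layers — and how they relate to chromatin architecture: weakened
insulation at the boundaries of topologically associating domains (TADs).

It is written for computational biologists who want a tested, reusable
version of this analysis chain that runs end to end on synthetic cohorts
with planted ground truth, so every stage is verifiable without access to
controlled patient data.

## What it computes

**Hi-C / TAD architecture**

- Contact-matrix handling: COO + BED text I/O, one-sided MAD-max
  low-coverage bin filtering, removal of same/adjacent-bin artifacts, and
  balancing by ICE or by chromosome-adjusted ICE (per-distance-band
  rescaling that removes whole-chromosome copy-number bias).
- Directionality index per bin: with upstream and downstream contact sums
  A and B over a 500 kb window and E = (A+B)/2,

      DI = sign(B − A) · ((A−E)²/E + (B−E)²/E),

  standardized genome-wide; boundaries called at −t → +t sign switches.
- Insulation score: mean balanced contact in a 250 kb square sliding along
  the diagonal, log2-normalized to the genome-wide median; boundaries at
  upward zero-crossings of the 125 kb delta, with the local swing as
  boundary strength.
- A/B compartments from the leading eigenvector of the observed/expected
  correlation matrix at 500 kb, oriented by a gene-density track.
- Cross-sample boundary matching (±100 kb), recurrent subgroup-specific
  boundary loss (weak/lost in ≥ 2 samples of one group), CTCF/RAD21 peak
  support (±50 kb), and a chi-square test for the down/up direction split
  of differentially expressed genes within 1 Mb of lost boundaries.

**Dosage effects**

- Normalized copy number per chromosome: the cohort average of the
  length-weighted mean segment copy divided by normal ploidy.
- Per-feature Cohen's d between subtypes, aggregated per chromosome and
  regressed on normalized copy number (chromosomes with d > 0.3 flagged);
  the protein layer shows the attenuated version of the RNA slope.
- A cis/trans map: Spearman correlation of every copy-number-variable
  gene against every expression feature, BH-controlled over all pairs.

**Expression analytics**

- CPM > 1 in > 80 % of one group expressed-gene filter; Welch + BH
  differential expression; iterative empirical-control normalization
  (controls = features with BH p > 0.9, unwanted factors from the SVD of
  the group-centered control submatrix, 10 iterations).
- mRNA–protein Spearman correlation per gene with summary statistics,
  protein-complex co-regulation vs random pairs, subtype-partial
  correlation, stratum comparisons (Wilcoxon / Kruskal–Wallis).
- TAD gene-pair correlation: pairs classed same-TAD / different-TAD by
  consensus of two reference TAD sets (plus 10,000 random 1 Mb domains),
  with LOESS coefficient-vs-distance curves.
- Chromosome morphology score (CMS) comparison: per-case mean of 1–3
  metaphase scores, one-sided Mann–Whitney between subtypes.

**Synthetic data** (`hypertad.simulate`) generates every input with planted
truth: Poisson Hi-C matrices with distance decay, block-TAD enrichment and
per-boundary insulation strengths; a two-subtype expression cohort with
whole-chromosome dosage (attenuated at the protein layer), switchable
TAD-coupling factors, batch factors and complex co-regulation; CTCF/RAD21
peaks and ChIA-PET interactions anchored at domain edges; and CMS tables.

## Worked example

```python
import numpy as np
import hypertad as ht

genome = ht.default_genome(n_chromosomes=2, chrom_length=20_000_000, bin_size=25_000)
tads = ht.regular_tads(genome, domain_size=2_000_000, strength=1.0)
matrices, truth = ht.simulate_hic(genome, tads, depth=60, seed=1)
matrices = {c: ht.remove_short_range(m) for c, m in matrices.items()}
matrices = ht.balance_genome(matrices, method="caicb")
profile = ht.insulation_score(matrices)          # 250 kb square, 125 kb span
boundaries, domains = ht.call_boundaries(profile, sample="demo")
hits = sum(
    np.min(np.abs(boundaries.positions(c) - p)) <= 25_000
    for c in genome.names for p in truth.boundaries(c)
)
print(f"planted boundaries: {sum(len(truth.boundaries(c)) for c in genome.names)}")
print(f"called boundaries:  {len(boundaries.table)}")
print(f"recovered within one bin: {hits}")

cms = ht.simulate_cms(n_per_group=(37, 33), group_means=(1.8, 2.1), seed=1)
res = ht.compare_cms(cms)
print(f"group mean CMS: { {k: round(v, 2) for k, v in res['group_means'].items()} }")
print(f"one-sided Mann-Whitney p = {res['pvalue']:.2e}")
```

prints

```
planted boundaries: 18
called boundaries:  40
recovered within one bin: 18
group mean CMS: {'HeH': 1.78, 'ETV6_RUNX1': 2.1}
one-sided Mann-Whitney p = 1.82e-07
```

All 18 planted boundaries are recovered within one 25 kb bin (the
insulation caller also emits weaker noise-level calls, which carry small
strength scores and are filtered out by strength in downstream matching);
the morphology cohort reproduces its prescribed group means and a clearly
significant one-sided test.

A thin CLI mirrors the library:
`hypertad simulate hic|expression|annotations|cms`, `hypertad hic balance`,
`hypertad tads call`, `hypertad boundaries match`, `hypertad dosage eq1`,
`hypertad expr de|cms` — run any of them with `--help`.

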