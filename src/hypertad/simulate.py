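"""Synthetic cohort generators with planted ground truth.

Every downstream stage of the pipeline can be exercised against these
generators without external data:

* :func:`simulate_hic` — distance-decay contact matrices with block-TAD
  enrichment and tunable per-boundary insulation strength.
* :func:`simulate_expression` — a two-subtype cohort with whole-chromosome
  dosage on the RNA layer (attenuated on the protein layer), TAD-level
  co-expression factors that can be switched off per subtype, batch
  factors and complex-membership co-regulation.
* :func:`simulate_annotations` — CTCF/RAD21 peaks at planted boundaries
  plus background, and domain-edge ChIA-PET interactions with a shared
  consensus fraction.
* :func:`simulate_cms` — ordinal chromosome-morphology scores whose case
  means center on prescribed group means.

All generators derive their randomness from a single integer seed routed
through named substreams, so adding a generator never shifts the draws of
an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosage import CopyNumberProfile
from .enrichment import InteractionSet, PeakSet
from .expression import CmsTable, ExpressionMatrix
from .genome import Chromosome, GenomeSpec, TadTruth, make_gene_annotation
from .hic import ContactMatrix

HEH, CONTROL = "HeH-like", "control"

_STREAMS = {"hic": 11, "expression": 12, "annotations": 13, "cms": 14,
            "cohort": 15}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def default_genome(
    n_chromosomes: int = 3, chrom_length: int = 20_000_000, bin_size: int = 25_000
) -> GenomeSpec:
    """A small diploid genome for simulation studies."""
    chroms = [
        Chromosome(name=f"chr{i + 1}", length=chrom_length, ploidy=2)
        for i in range(n_chromosomes)
    ]
    return GenomeSpec(chromosomes=chroms, bin_size=bin_size)


def regular_tads(
    genome: GenomeSpec, domain_size: int = 1_000_000,
    strength: float | np.ndarray = 1.0,
) -> TadTruth:
    """Tile each chromosome with equal-size domains at a common (or
    per-boundary) planted strength."""
    domains = {}
    strengths = {}
    for c in genome.chromosomes:
        edges = list(range(0, c.length, domain_size)) + [c.length]
        edges = sorted(set(edges))
        doms = [(a, b) for a, b in zip(edges, edges[1:])]
        domains[c.name] = doms
        n_internal = len(doms) - 1
        s = np.broadcast_to(np.asarray(strength, dtype=float), (n_internal,)).copy()
        strengths[c.name] = s
    return TadTruth(domains=domains, boundary_strengths=strengths)


@dataclass
class CohortTruth:
    """Planted cohort structure: subtype labels, per-sample per-chromosome
    integer copy numbers, dosage exponent, TAD-coupling per subtype,
    batch labels, and the protein attenuation factor."""

    subtypes: pd.Series  # sample -> HeH-like | control
    copy_numbers: pd.DataFrame  # samples x chromosomes (integer)
    dosage_exponent: float = 1.0
    tad_coupling: dict[str, bool] = field(
        default_factory=lambda: {HEH: True, CONTROL: True}
    )
    batches: pd.Series | None = None
    attenuation: float = 0.5

    def __post_init__(self) -> None:
        bad = set(self.subtypes.unique()) - {HEH, CONTROL}
        if bad:
            raise ValueError(f"unknown subtypes: {sorted(bad)}")
        cn = self.copy_numbers
        if ((cn < 0) | (cn % 1 != 0)).any().any():
            raise ValueError("copy numbers must be non-negative integers")
        if self.batches is None:
            n = len(self.subtypes)
            self.batches = pd.Series(
                (np.arange(n) % 2), index=self.subtypes.index, name="batch"
            )


def make_cohort(
    genome: GenomeSpec,
    n_heh: int = 20,
    n_control: int = 20,
    gain_fractions: dict[str, float] | None = None,
    seed: int = 0,
    dosage_exponent: float = 1.0,
    attenuation: float = 0.5,
    tad_coupling: dict[str, bool] | None = None,
) -> CohortTruth:
    """Build a HeH-like vs control cohort with whole-chromosome trisomies.

    ``gain_fractions``: chromosome -> fraction of HeH-like samples carrying
    an extra copy (default: every chromosome gained in every HeH sample).
    Controls always carry normal ploidy.
    """
    rng = _rng(seed, "cohort")
    samples = [f"HeH_{i + 1}" for i in range(n_heh)] + [
        f"CTRL_{i + 1}" for i in range(n_control)
    ]
    subtypes = pd.Series(
        [HEH] * n_heh + [CONTROL] * n_control, index=samples, name="subtype"
    )
    if gain_fractions is None:
        gain_fractions = {c.name: 1.0 for c in genome.chromosomes}
    cn = pd.DataFrame(index=samples, columns=genome.names, dtype=int)
    for c in genome.chromosomes:
        ploidy = c.ploidy if c.ploidy is not None else 2
        cn[c.name] = ploidy
        frac = gain_fractions.get(c.name, 0.0)
        if frac > 0:
            n_gain = int(round(frac * n_heh))
            gained = rng.choice(n_heh, size=n_gain, replace=False)
            cn.iloc[gained, cn.columns.get_loc(c.name)] = ploidy + 1
    return CohortTruth(
        subtypes=subtypes,
        copy_numbers=cn,
        dosage_exponent=dosage_exponent,
        attenuation=attenuation,
        tad_coupling=tad_coupling or {HEH: True, CONTROL: True},
    )


def _domain_multipliers(
    n_domains: int, strengths: np.ndarray, enrichment: float
) -> np.ndarray:
    """Domain-by-domain contact multiplier: ``enrichment`` on the diagonal,
    and for cross-boundary pairs ``1 + (enrichment - 1) * (1 - s_min)``
    with ``s_min`` the weakest crossed boundary."""
    m = np.ones((n_domains, n_domains))
    np.fill_diagonal(m, enrichment)
    for a in range(n_domains):
        smin = np.inf
        for b in range(a + 1, n_domains):
            smin = min(smin, strengths[b - 1])
            val = 1.0 + (enrichment - 1.0) * (1.0 - smin)
            m[a, b] = m[b, a] = val
    return m


def expected_contacts(
    genome: GenomeSpec, tads: TadTruth, chrom: str,
    depth: float, decay_exponent: float, tad_enrichment: float,
) -> np.ndarray:
    """Closed-form expected contact matrix for one chromosome."""
    bs = genome.bin_size
    n = genome.n_bins(chrom)
    doms = tads.domains[chrom]
    for (s, e) in doms:
        if s % bs or (e % bs and e != genome.length(chrom)):
            raise ValueError(
                f"domain [{s},{e}) on {chrom} does not align with the "
                f"{bs} bp bin grid"
            )
    dom_of = np.empty(n, dtype=int)
    for k, (s, e) in enumerate(doms):
        dom_of[s // bs: -(-e // bs)] = k
    m = _domain_multipliers(
        len(doms), tads.boundary_strengths[chrom], tad_enrichment
    )
    idx = np.arange(n)
    dist = np.abs(np.subtract.outer(idx, idx))
    return depth * (1.0 + dist) ** (-decay_exponent) * m[np.ix_(dom_of, dom_of)]


def simulate_hic(
    genome: GenomeSpec,
    tads: TadTruth,
    depth: float = 60.0,
    decay_exponent: float = 1.0,
    tad_enrichment: float = 3.0,
    seed: int = 0,
) -> tuple[dict[str, ContactMatrix], TadTruth]:
    """Poisson contact matrices with planted TADs; returns the matrices
    and the truth echo."""
    if depth <= 0 or decay_exponent <= 0:
        raise ValueError("depth and decay_exponent must be positive")
    if tad_enrichment <= 1:
        raise ValueError("tad_enrichment must exceed 1")
    rng = _rng(seed, "hic")
    out = {}
    for chrom in tads.domains:
        if chrom not in genome.names:
            raise ValueError(f"chromosome {chrom} not in genome")
        mu = expected_contacts(
            genome, tads, chrom, depth, decay_exponent, tad_enrichment
        )
        n = mu.shape[0]
        upper = rng.poisson(np.triu(mu))
        counts = np.triu(upper) + np.triu(upper, k=1).T
        out[chrom] = ContactMatrix(
            chrom=chrom, bin_size=genome.bin_size, counts=counts.astype(float)
        )
    return out, tads


@dataclass
class SimulatedExpression:
    rna: ExpressionMatrix
    protein: ExpressionMatrix
    copy_number: CopyNumberProfile
    genes: pd.DataFrame
    gene_domain: pd.Series  # gene -> (chrom, domain index) or NaN
    complex_map: pd.Series  # gene -> complex id (members only)
    dosage_exponents: pd.Series


def simulate_expression(
    genome: GenomeSpec,
    cohort: CohortTruth,
    tads: TadTruth,
    n_genes: int = 600,
    noise_sd: float = 0.5,
    seed: int = 0,
    tad_factor_sd: float = 0.25,
    batch_sd: float = 0.2,
    complex_sd: float = 0.3,
    n_complexes: int = 20,
    complex_size: int = 5,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.0,
) -> SimulatedExpression:
    """Two-layer expression cohort on the log2 scale.

    RNA value = baseline + dosage_exponent * log2(copy / ploidy)
    + TAD factor (coupled subtypes only) + batch factor + noise;
    protein value = attenuation * (RNA signal without its noise)
    + complex factor + independent noise.
    """
    for chrom in cohort.copy_numbers.columns:
        if chrom not in genome.names:
            raise ValueError(f"cohort chromosome {chrom} missing from genome")
    rng = _rng(seed, "expression")
    lengths = np.array([c.length for c in genome.chromosomes], dtype=float)
    per_chrom = np.maximum(
        2, np.round(n_genes * lengths / lengths.sum()).astype(int)
    )
    if n_genes < 2 * len(genome.chromosomes):
        raise ValueError("need at least 2 genes per chromosome")

    rows = []
    gid = 0
    for c, n_c in zip(genome.chromosomes, per_chrom):
        starts = np.sort(rng.integers(0, max(c.length - 50_000, 1), size=n_c))
        for s in starts:
            length = int(rng.integers(5_000, 50_000))
            end = min(s + length, c.length)
            strand = "+" if rng.random() < 0.5 else "-"
            tss = s if strand == "+" else end - 1
            rows.append(
                {"gene": f"G{gid:05d}", "chrom": c.name, "start": int(s),
                 "end": int(end), "strand": strand, "tss": int(tss)}
            )
            gid += 1
    genes = make_gene_annotation(pd.DataFrame(rows))
    n_g = len(genes)
    samples = list(cohort.subtypes.index)
    n_s = len(samples)

    # gene -> planted domain (by TSS)
    gene_domain = pd.Series(index=genes["gene"], dtype=object)
    dom_key = {}
    for i, g in genes.iterrows():
        for k, (s, e) in enumerate(tads.domains.get(g["chrom"], [])):
            if s <= g["tss"] < e:
                gene_domain[g["gene"]] = (g["chrom"], k)
                dom_key.setdefault((g["chrom"], k), []).append(g["gene"])
                break

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_g)
    dexp = np.full(n_g, cohort.dosage_exponent)

    ploidy = np.array(
        [genome.ploidy(c) if genome.ploidy(c) is not None else np.nan
         for c in cohort.copy_numbers.columns]
    )
    chrom_idx = {c: k for k, c in enumerate(cohort.copy_numbers.columns)}
    gene_chrom_idx = genes["chrom"].map(chrom_idx).to_numpy()
    copy = cohort.copy_numbers.loc[samples].to_numpy(dtype=float)  # s x chrom
    with np.errstate(invalid="ignore", divide="ignore"):
        log_dose = np.log2(copy / ploidy[None, :])
    log_dose = np.nan_to_num(log_dose)
    dosage_term = dexp[:, None] * log_dose[:, gene_chrom_idx].T  # genes x samples

    # TAD factors: per (domain, sample), applied only to coupled subtypes
    tad_term = np.zeros((n_g, n_s))
    coupled = np.array(
        [cohort.tad_coupling.get(cohort.subtypes[s], False) for s in samples]
    )
    gene_pos = {g: i for i, g in enumerate(genes["gene"])}
    for key, members in dom_key.items():
        f = rng.normal(0.0, tad_factor_sd, size=n_s)
        f[~coupled] = 0.0
        for g in members:
            tad_term[gene_pos[g], :] += f

    # batch factors: per-gene loading times per-batch score
    batches = cohort.batches.loc[samples].to_numpy()
    uniq_batches = np.unique(batches)
    batch_scores = rng.normal(0.0, 1.0, size=len(uniq_batches))
    loadings = rng.normal(0.0, batch_sd, size=n_g)
    batch_term = loadings[:, None] * batch_scores[
        np.searchsorted(uniq_batches, batches)
    ][None, :]

    rna_signal = baseline[:, None] + dosage_term + tad_term + batch_term
    rna_noise = rng.normal(0.0, noise_sd, size=(n_g, n_s))
    rna_values = rna_signal + rna_noise

    # complexes: disjoint random gene groups
    perm = rng.permutation(n_g)
    complex_map = {}
    complex_term = np.zeros((n_g, n_s))
    for cid in range(n_complexes):
        members = perm[cid * complex_size: (cid + 1) * complex_size]
        if len(members) < 2:
            break
        f = rng.normal(0.0, complex_sd, size=n_s)
        for m in members:
            complex_map[genes["gene"].iloc[m]] = f"complex_{cid}"
            complex_term[m, :] += f

    protein_noise = rng.normal(0.0, noise_sd, size=(n_g, n_s))
    protein_values = cohort.attenuation * rna_signal + complex_term + protein_noise

    groups = cohort.subtypes.copy()
    rna = ExpressionMatrix(
        layer="rna",
        values=pd.DataFrame(rna_values, index=genes["gene"], columns=samples),
        groups=groups, batches=cohort.batches,
    )
    protein = ExpressionMatrix(
        layer="protein",
        values=pd.DataFrame(protein_values, index=genes["gene"], columns=samples),
        groups=groups, batches=cohort.batches,
    )
    seg_rows = []
    for s in samples:
        for c in genome.chromosomes:
            seg_rows.append(
                {"sample": s, "chrom": c.name, "start": 0, "end": c.length,
                 "copy": int(cohort.copy_numbers.loc[s, c.name])}
            )
    profile = CopyNumberProfile(segments=pd.DataFrame(seg_rows))
    return SimulatedExpression(
        rna=rna, protein=protein, copy_number=profile, genes=genes,
        gene_domain=gene_domain,
        complex_map=pd.Series(complex_map, dtype=object),
        dosage_exponents=pd.Series(dexp, index=genes["gene"]),
    )


def simulate_annotations(
    genome: GenomeSpec,
    tads: TadTruth,
    peak_rate: float = 5.0,
    pet_range: tuple[int, int] = (10, 50),
    seed: int = 0,
    shared_fraction: float = 0.7,
    boundary_jitter: int = 10_000,
    peak_width: int = 500,
    anchor_width: int = 1_000,
) -> tuple[PeakSet, PeakSet, InteractionSet, InteractionSet]:
    """CTCF and RAD21 peaks at every planted boundary (within +/-10 kb)
    plus Poisson background at ``peak_rate`` per Mb, and ChIA-PET
    interactions linking domain edges, a ``shared_fraction`` of which
    appear identically in both assays."""
    if peak_rate < 0:
        raise ValueError("peak_rate must be >= 0")
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = _rng(seed, "annotations")

    def peaks_for(label: str) -> PeakSet:
        rows = []
        for chrom in tads.domains:
            length = genome.length(chrom)
            for pos in tads.boundaries(chrom):
                center = int(
                    np.clip(pos + rng.integers(-boundary_jitter, boundary_jitter + 1),
                            peak_width, length - peak_width)
                )
                rows.append({"chrom": chrom, "start": center - peak_width // 2,
                             "end": center + peak_width // 2})
            n_bg = rng.poisson(peak_rate * length / 1e6)
            for _ in range(n_bg):
                s = int(rng.integers(0, length - peak_width))
                rows.append({"chrom": chrom, "start": s, "end": s + peak_width})
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        return PeakSet(intervals=df, source=label)

    ctcf = peaks_for("CTCF")
    rad21 = peaks_for("RAD21")

    lo, hi = pet_range
    rows_a, rows_b = [], []
    for chrom, doms in tads.domains.items():
        for (s, e) in doms:
            rec = {
                "chrom1": chrom, "start1": s, "end1": s + anchor_width,
                "chrom2": chrom, "start2": max(e - anchor_width, s + anchor_width),
                "end2": e,
                "pet": int(rng.integers(lo, hi + 1)),
            }
            u = rng.random()
            if u < shared_fraction:
                rows_a.append(rec)
                rows_b.append(dict(rec))
            elif rng.random() < 0.5:
                rows_a.append(rec)
            else:
                rows_b.append(rec)
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "pet"]
    return (
        ctcf, rad21,
        InteractionSet(table=pd.DataFrame(rows_a, columns=cols)),
        InteractionSet(table=pd.DataFrame(rows_b, columns=cols)),
    )


def simulate_cms(
    n_per_group: tuple[int, int] = (37, 33),
    group_means: tuple[float, float] = (1.8, 2.1),
    metaphases_per_case: int = 20,
    seed: int = 0,
    group_labels: tuple[str, str] = ("HeH", "ETV6_RUNX1"),
    case_sd: float = 0.15,
) -> CmsTable:
    """Integer morphology scores in {1, 2, 3} per metaphase, drawn so case
    means center on the prescribed group means (score = 1 + Binomial(2, p)
    with p set per case)."""
    for m in group_means:
        if not 1.0 <= m <= 3.0:
            raise ValueError(f"group mean {m} outside [1, 3]")
    rng = _rng(seed, "cms")
    rows = []
    for g, (n_cases, mean, label) in enumerate(
        zip(n_per_group, group_means, group_labels)
    ):
        for c in range(n_cases):
            target = float(np.clip(rng.normal(mean, case_sd), 1.0, 3.0))
            p = (target - 1.0) / 2.0
            scores = 1 + rng.binomial(2, p, size=metaphases_per_case)
            for k, s in enumerate(scores):
                rows.append(
                    {"case_id": f"{label}_{c + 1}", "group": label,
                     "metaphase_index": k, "score": int(s)}
                )
    return CmsTable(table=pd.DataFrame(rows))
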