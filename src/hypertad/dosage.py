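"""Aneuploidy dosage effects: normalized per-chromosome copy number,
Cohen's d effect sizes and their regression on copy number, and the
cis/trans copy-number-to-expression correlation map.

The normalized copy number of a chromosome is the cohort average of the
length-weighted mean segment copy divided by the chromosome's normal
ploidy (2 for autosomes; 1 or 2 for sex chromosomes; undefined where no
normal ploidy exists, e.g. Y in females).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec
from .stats import bh_adjust, spearman_matrix

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "copy"]


@dataclass
class CopyNumberProfile:
    """Per-sample copy-number segments with projections to genes and
    chromosomes."""

    segments: pd.DataFrame  # sample, chrom, start, end, copy

    def __post_init__(self) -> None:
        missing = [c for c in SEG_COLUMNS if c not in self.segments.columns]
        if missing:
            raise ValueError(f"segment table missing columns: {missing}")
        seg = self.segments.sort_values(["sample", "chrom", "start"]).reset_index(
            drop=True
        )
        if (seg["copy"] < 0).any():
            raise ValueError("copy numbers must be >= 0")
        for (sample, chrom), sub in seg.groupby(["sample", "chrom"]):
            ends = sub["end"].to_numpy()[:-1]
            starts = sub["start"].to_numpy()[1:]
            if (starts < ends).any():
                raise ValueError(f"overlapping segments for {sample}/{chrom}")
        self.segments = seg

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.segments["sample"]))

    def sample_chromosome_copy(self, genome: GenomeSpec) -> pd.DataFrame:
        """Length-weighted mean copy per (sample, chromosome); gaps in
        segment coverage are imputed at normal ploidy (logged)."""
        rows = {}
        for sample in self.samples:
            sub = self.segments[self.segments["sample"] == sample]
            rows[sample] = {}
            for chrom in genome.names:
                length = genome.length(chrom)
                ploidy = genome.ploidy(chrom)
                segs = sub[sub["chrom"] == chrom]
                covered = int((segs["end"].clip(upper=length)
                               - segs["start"].clip(lower=0)).sum())
                weighted = float(
                    (segs["copy"]
                     * (segs["end"].clip(upper=length) - segs["start"].clip(lower=0))
                     ).sum()
                )
                gap = length - covered
                if gap > 0:
                    if ploidy is None:
                        rows[sample][chrom] = np.nan
                        continue
                    if covered > 0:
                        logger.info(
                            "%s/%s: %d bp uncovered, imputed at ploidy %d",
                            sample, chrom, gap, ploidy,
                        )
                    weighted += ploidy * gap
                rows[sample][chrom] = weighted / length
        return pd.DataFrame(rows).T  # samples x chromosomes

    def gene_copy(self, genes: pd.DataFrame) -> pd.DataFrame:
        """Copy number at each gene's TSS per sample (genes x samples);
        uncovered TSS positions get NaN (caller may impute)."""
        out = pd.DataFrame(
            np.nan, index=genes["gene"], columns=self.samples, dtype=float
        )
        for sample in self.samples:
            sub = self.segments[self.segments["sample"] == sample]
            for chrom, segs in sub.groupby("chrom"):
                g = genes[genes["chrom"] == chrom]
                if not len(g):
                    continue
                starts = segs["start"].to_numpy()
                ends = segs["end"].to_numpy()
                copies = segs["copy"].to_numpy(dtype=float)
                tss = g["tss"].to_numpy()
                idx = np.searchsorted(starts, tss, side="right") - 1
                valid = (idx >= 0) & (tss < ends[np.clip(idx, 0, None)])
                vals = np.full(len(tss), np.nan)
                vals[valid] = copies[idx[valid]]
                out.loc[g["gene"].to_numpy(), sample] = vals
        return out


def normalized_copy_number(
    profile: CopyNumberProfile, genome: GenomeSpec
) -> pd.Series:
    """Cohort-averaged, ploidy-normalized copy number per chromosome.

    Chromosomes whose normal ploidy is undefined come back NaN and are
    excluded from downstream regression.
    """
    per_sample = profile.sample_chromosome_copy(genome)
    out = {}
    for chrom in genome.names:
        ploidy = genome.ploidy(chrom)
        if ploidy is None:
            out[chrom] = np.nan
            continue
        out[chrom] = float((per_sample[chrom] / ploidy).mean())
    return pd.Series(out)


def cohens_d(
    values: pd.DataFrame, groups: pd.Series
) -> pd.Series:
    """Per-feature Cohen's d between two groups (group1 minus group2,
    pooled standard deviation). Features with zero pooled sd get NaN."""
    groups = groups.reindex(values.columns)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = values.loc[:, groups == labels[0]].to_numpy(dtype=float)
    b = values.loc[:, groups == labels[1]].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")
    s1 = a.var(axis=1, ddof=1)
    s2 = b.var(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (a.mean(axis=1) - b.mean(axis=1)) / pooled
    d[pooled == 0] = np.nan
    return pd.Series(d, index=values.index)


def chromosome_effect_sizes(
    per_feature_d: pd.Series, genes: pd.DataFrame, weighted: bool = False
) -> pd.Series:
    """Aggregate per-feature d to per-chromosome values (unweighted mean
    by default)."""
    chrom_of = genes.set_index("gene")["chrom"]
    d = per_feature_d.dropna()
    chroms = chrom_of.reindex(d.index)
    return d.groupby(chroms).mean() if not weighted else d.groupby(chroms).agg(
        lambda v: np.average(v)
    )


@dataclass
class EffectSizeRegression:
    slope: float
    intercept: float
    r_squared: float
    affected: list[str]  # chromosomes with d > 0.3


def regress_effect_size(
    per_chromosome_d: pd.Series,
    normalized_copy: pd.Series,
    affected_threshold: float = 0.3,
) -> EffectSizeRegression:
    """OLS of per-chromosome Cohen's d on normalized copy number; a
    chromosome is 'affected' when its d strictly exceeds the threshold."""
    joint = pd.concat(
        [per_chromosome_d.rename("d"), normalized_copy.rename("ncn")], axis=1
    ).dropna()
    if len(joint) < 3:
        raise ValueError("need at least 3 informative chromosomes")
    res = stats.linregress(joint["ncn"], joint["d"])
    affected = joint.index[joint["d"] > affected_threshold].tolist()
    return EffectSizeRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        affected=affected,
    )


def select_cna_genes(
    gene_copy: pd.DataFrame, min_variant_cases: int = 3
) -> pd.Index:
    """Genes whose copy number deviates from the per-gene modal value in
    strictly more than ``min_variant_cases`` samples."""
    vals = gene_copy.to_numpy(dtype=float)
    keep = np.zeros(len(gene_copy), dtype=bool)
    for i, row in enumerate(vals):
        finite = row[np.isfinite(row)]
        if len(finite) == 0:
            continue
        mode = stats.mode(finite, keepdims=False).mode
        keep[i] = (finite != mode).sum() > min_variant_cases
    return gene_copy.index[keep]


@dataclass
class CisTransMap:
    rho: pd.DataFrame  # CNA genes x features
    adj_pvalue: pd.DataFrame
    cis_mask: pd.DataFrame  # True where CNA gene == feature
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.adj_pvalue <= self.alpha

    def trans_significant_fraction(self) -> float:
        """Fraction of tested trans pairs that are significant."""
        trans = ~self.cis_mask.to_numpy()
        tested = trans & np.isfinite(self.adj_pvalue.to_numpy())
        if tested.sum() == 0:
            return np.nan
        sig = (self.adj_pvalue.to_numpy() <= self.alpha) & tested
        return float(sig.sum() / tested.sum())


def cis_trans_map(
    gene_copy: pd.DataFrame,
    expression: pd.DataFrame,
    cna_genes: pd.Index,
    alpha: float = 0.05,
) -> CisTransMap:
    """Spearman correlation between every CNA gene's copy vector and every
    expression feature, BH-adjusted over all tested pairs.

    Pairs involving a constant vector are undefined (NaN) and excluded
    from the BH family; cis pairs are those where the CNA gene and the
    feature share an identifier.
    """
    if len(cna_genes) == 0:
        raise ValueError("cna_genes is empty")
    samples = gene_copy.columns.intersection(expression.columns)
    if len(samples) < 6:
        raise ValueError("need at least 6 shared samples")
    copy = gene_copy.loc[cna_genes, samples].to_numpy(dtype=float)
    expr = expression.loc[:, samples].to_numpy(dtype=float)
    rho, p = spearman_matrix(copy, expr)
    adj = bh_adjust(p.ravel()).reshape(p.shape)
    cis = np.equal.outer(
        np.asarray(cna_genes, dtype=object), np.asarray(expression.index, dtype=object)
    )
    return CisTransMap(
        rho=pd.DataFrame(rho, index=cna_genes, columns=expression.index),
        adj_pvalue=pd.DataFrame(adj, index=cna_genes, columns=expression.index),
        cis_mask=pd.DataFrame(cis, index=cna_genes, columns=expression.index),
        alpha=alpha,
    )
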