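"""CTCF-binding-site and ChIA-PET loop-anchor enrichment among
differentially expressed genes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import hypergeom_sf_at_least


@dataclass
class PeakSet:
    """Genomic intervals (0-based half-open) from a peak caller."""

    intervals: pd.DataFrame  # chrom, start, end
    source: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        iv = self.intervals
        if len(iv) and (iv["start"] >= iv["end"]).any():
            raise ValueError("peaks must have start < end")
        if not iv[["chrom", "start"]].equals(
            iv[["chrom", "start"]].sort_values(["chrom", "start"]).reset_index(drop=True)
        ):
            warnings.warn("unsorted peak set; sorting internally")
        self.intervals = iv.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class InteractionSet:
    """Paired-anchor interactions with PET-count support (BEDPE-style)."""

    table: pd.DataFrame  # chrom1,start1,end1,chrom2,start2,end2,pet

    def __post_init__(self) -> None:
        required = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "pet"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"interaction table missing columns: {missing}")
        t = self.table
        if len(t) and ((t["pet"] <= 0) | (t["pet"] % 1 != 0)).any():
            raise ValueError("PET counts must be positive integers")
        self.table = t.reset_index(drop=True)

    def anchors(self) -> pd.DataFrame:
        """All anchor intervals (both sides), one per row."""
        a = self.table[["chrom1", "start1", "end1"]].rename(
            columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
        )
        b = self.table[["chrom2", "start2", "end2"]].rename(
            columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
        )
        return pd.concat([a, b], ignore_index=True)


def _count_overlaps(
    query_start: np.ndarray, query_end: np.ndarray,
    iv_starts: np.ndarray, iv_ends_sorted: np.ndarray,
) -> np.ndarray:
    """Number of intervals overlapping each half-open query.

    ``iv_starts`` sorted ascending; ``iv_ends_sorted`` are the interval
    ends sorted independently (counting argument: overlaps = #(start <
    qend) - #(end <= qstart))."""
    n_start_before = np.searchsorted(iv_starts, query_end, side="left")
    n_end_before = np.searchsorted(iv_ends_sorted, query_start, side="right")
    return n_start_before - n_end_before


def count_ctcf_sites(
    genes: pd.DataFrame, peaks: PeakSet, flank: int = 5_000
) -> pd.Series:
    """Peaks overlapping each gene body extended by ``flank`` bp on either
    side."""
    out = pd.Series(0, index=genes["gene"], dtype=int)
    for chrom, pk in peaks.intervals.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if not len(g):
            continue
        starts = np.sort(pk["start"].to_numpy())
        ends = np.sort(pk["end"].to_numpy())
        qs = np.maximum(g["start"].to_numpy() - flank, 0)
        qe = g["end"].to_numpy() + flank
        out.loc[g["gene"].to_numpy()] = _count_overlaps(qs, qe, starts, ends)
    return out


def _strata(counts: np.ndarray) -> np.ndarray:
    """Site-count strata 0 / 1 / 2 / >=3."""
    return np.minimum(counts, 3)


def ctcf_de_enrichment(
    counts: pd.Series, de_flags: pd.Series, fold_changes: pd.Series
) -> dict:
    """Are DE genes enriched for CTCF binding sites?

    Chi-square on the 0/1/2/>=3 site-count strata between DE and non-DE
    genes (strata with expected cells < 1 merged upward, with a warning),
    plus a Mann-Whitney comparison of |log2 fold change| between genes
    with at least the median site count and the rest.
    """
    genes = counts.index
    de = de_flags.reindex(genes).astype(bool).to_numpy()
    strata = _strata(counts.to_numpy())
    levels = [0, 1, 2, 3]
    table = np.array(
        [[(strata[de] == s).sum() for s in levels],
         [(strata[~de] == s).sum() for s in levels]],
        dtype=float,
    )
    # merge sparse strata upward until all expected cells >= 1
    while table.shape[1] > 2:
        exp = stats.contingency.expected_freq(table)
        if (exp >= 1).all():
            break
        warnings.warn("sparse site-count stratum merged upward")
        table = np.column_stack([table[:, :-2], table[:, -2:].sum(axis=1)])
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate contingency table")
    if np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    lfc = np.abs(fold_changes.reindex(genes).to_numpy(dtype=float))
    high = counts.to_numpy() >= np.median(counts.to_numpy())
    finite = np.isfinite(lfc)
    mw = stats.mannwhitneyu(
        lfc[high & finite], lfc[~high & finite], alternative="two-sided"
    )
    return {
        "chi2": float(chi2),
        "chi2_pvalue": float(p),
        "contingency": table,
        "foldchange_pvalue": float(mw.pvalue),
    }


def _anchor_key(t: pd.DataFrame) -> pd.DataFrame:
    """Canonical anchor order (smaller anchor first) for symmetric matching."""
    first = (t["chrom1"] < t["chrom2"]) | (
        (t["chrom1"] == t["chrom2"]) & (t["start1"] <= t["start2"])
    )
    out = t.copy()
    swap = ~first
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
        out.loc[swap, [a, b]] = t.loc[swap, [b, a]].to_numpy()
    return out


def _anchors_overlap(row, other) -> np.ndarray:
    """Boolean vector: which rows of ``other`` reciprocally overlap ``row``
    on both anchors (>= 1 bp each)."""
    same1 = (other["chrom1"] == row["chrom1"]) & \
        (other["start1"] < row["end1"]) & (other["end1"] > row["start1"])
    same2 = (other["chrom2"] == row["chrom2"]) & \
        (other["start2"] < row["end2"]) & (other["end2"] > row["start2"])
    return (same1 & same2).to_numpy()


def consensus_interactions(
    a: InteractionSet, b: InteractionSet, min_pet: int = 10
) -> InteractionSet:
    """High-confidence interactions: drop PET < ``min_pet`` from each set,
    then keep interactions of ``a`` whose both anchors reciprocally
    overlap an interaction of ``b`` (>= 1 bp per anchor)."""
    ta = _anchor_key(a.table[a.table["pet"] >= min_pet])
    tb = _anchor_key(b.table[b.table["pet"] >= min_pet])
    if not len(ta) or not len(tb):
        return InteractionSet(table=ta.iloc[0:0])
    keep = np.zeros(len(ta), dtype=bool)
    for i, (_, row) in enumerate(ta.iterrows()):
        if _anchors_overlap(row, tb).any():
            keep[i] = True
    return InteractionSet(table=ta[keep].reset_index(drop=True))


def classify_anchor_genes(
    genes: pd.DataFrame, interactions: InteractionSet, max_dist: int = 5_000
) -> pd.Series:
    """'anchor' iff the gene's TSS lies within ``max_dist`` bp of the
    nearest consensus loop anchor (0 if inside one), else 'background'."""
    anchors = interactions.anchors()
    if not len(anchors):
        raise ValueError("no anchors in interaction set")
    out = pd.Series("background", index=genes["gene"], dtype=object)
    for chrom, anc in anchors.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if not len(g):
            continue
        starts = anc["start"].to_numpy()
        ends = anc["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        tss = g["tss"].to_numpy()
        # distance to nearest interval: 0 if inside, else gap to closest edge
        dmin = np.full(len(tss), np.inf)
        for s, e in zip(starts, ends):
            d = np.where(
                (tss >= s) & (tss < e), 0, np.minimum(np.abs(tss - s), np.abs(tss - (e - 1)))
            )
            dmin = np.minimum(dmin, d)
        out.loc[g["gene"].to_numpy()] = np.where(
            dmin <= max_dist, "anchor", "background"
        )
    return out


def anchor_de_enrichment(
    classes: pd.Series, de_flags: pd.Series, fold_changes: pd.Series
) -> dict:
    """Hypergeometric tail probability of observing at least the seen
    number of DE anchor genes, plus a Mann-Whitney comparison of |log2
    fold change| between DE anchor and DE background genes."""
    genes = classes.index
    de = de_flags.reindex(genes).astype(bool).to_numpy()
    anchor = (classes == "anchor").to_numpy()
    n_total = len(genes)
    n_anchor = int(anchor.sum())
    n_de = int(de.sum())
    k = int((anchor & de).sum())
    if n_de == 0 or n_anchor == 0 or n_anchor == n_total:
        return {"hypergeom_pvalue": np.nan, "foldchange_pvalue": np.nan,
                "k": k, "undefined": True}
    p_hyper = hypergeom_sf_at_least(k, n_total, n_anchor, n_de)
    lfc = np.abs(fold_changes.reindex(genes).to_numpy(dtype=float))
    a = lfc[de & anchor]
    b = lfc[de & ~anchor]
    if len(a) and len(b):
        p_mw = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        p_mw = np.nan
    return {"hypergeom_pvalue": float(p_hyper), "foldchange_pvalue": p_mw,
            "k": k, "n_anchor": n_anchor, "n_de": n_de, "n_total": n_total,
            "undefined": False}
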