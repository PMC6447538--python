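"""Plain-text readers/writers for every interchange format the pipeline
consumes or produces: COO pixels + BED bin tables, BED boundaries/TADs,
bedGraph profiles, narrowPeak peaks, BEDPE interactions, SEG copy-number
segments, genes/expression/complex/CMS TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dosage import CopyNumberProfile, SEG_COLUMNS
from .enrichment import InteractionSet, PeakSet
from .expression import CmsTable, ExpressionMatrix
from .genome import GENE_COLUMNS, make_gene_annotation
from .hic import ContactMatrix
from .tads import BoundarySet, TadSet


# ---- Hi-C: bin table + COO pixels -------------------------------------------

def write_contacts(
    matrices: dict[str, ContactMatrix], pixels_path, bins_path
) -> None:
    """Write per-chromosome matrices as a global bin table (BED3 + id) and
    an upper-triangle COO pixel file. Zero pixels are omitted."""
    bin_rows = []
    offsets = {}
    gid = 0
    for chrom, cm in matrices.items():
        offsets[chrom] = gid
        for start, end in cm.bins:
            bin_rows.append((chrom, int(start), int(end), gid))
            gid += 1
    with open(bins_path, "w") as fh:
        for row in bin_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(pixels_path, "w") as fh:
        for chrom, cm in matrices.items():
            off = offsets[chrom]
            iu, ju = np.triu_indices(cm.n_bins)
            vals = cm.counts[iu, ju]
            nz = vals != 0
            for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
                v = int(v) if float(v).is_integer() else v
                fh.write(f"{off + i}\t{off + j}\t{v}\n")


# ---- boundaries / TADs as BED ------------------------------------------------

def write_boundaries(bs: BoundarySet, path) -> None:
    """Boundaries as 1-bp BED features at the bin edge, with strength as
    score and method in the name column."""
    with open(path, "w") as fh:
        for _, r in bs.table.iterrows():
            fh.write(
                f"{r['chrom']}\t{r['position']}\t{r['position'] + 1}"
                f"\t{r['method']}\t{r['strength']:.6g}\n"
            )


def read_boundaries(path, sample: str, bin_size: int) -> BoundarySet:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "method", "strength"],
    )
    table = pd.DataFrame(
        {"chrom": df["chrom"], "position": df["start"],
         "strength": df["strength"], "method": df["method"]}
    )
    return BoundarySet(sample=sample, bin_size=bin_size, table=table)


def write_tads(ts: TadSet, path) -> None:
    ts.table[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tads(path) -> TadSet:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return TadSet(table=df)


def write_bedgraph(track: dict[str, np.ndarray], bin_size: int, path) -> None:
    """Per-bin profile values as bedGraph; NaN bins are skipped."""
    with open(path, "w") as fh:
        for chrom, values in track.items():
            for i, v in enumerate(values):
                if np.isfinite(v):
                    fh.write(
                        f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n"
                    )


# ---- peaks / interactions ----------------------------------------------------

def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for k, (_, r) in enumerate(peaks.intervals.iterrows()):
            fh.write(
                f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                f"{peaks.source or 'peak'}_{k}\t0\t.\t0\t-1\t-1\t-1\n"
            )


def read_narrowpeak(path, source: str = "") -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return PeakSet(intervals=df, source=source)


def write_bedpe(interactions: InteractionSet, path) -> None:
    interactions.table[
        ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "pet"]
    ].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path) -> InteractionSet:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "pet"],
    )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"malformed paired record at line {bad}")
    return InteractionSet(table=df)


# ---- copy number / genes -----------------------------------------------------

def write_segments(profile: CopyNumberProfile, path) -> None:
    profile.segments[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_segments(path) -> CopyNumberProfile:
    return CopyNumberProfile(segments=pd.read_csv(path, sep="\t"))


def write_genes(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    return make_gene_annotation(pd.read_csv(path, sep="\t"))


# ---- expression --------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path) -> None:
    """TSV with a two-line header: '#layer <layer>' then per-sample group
    labels, then the genes x samples matrix."""
    with open(path, "w") as fh:
        fh.write(f"#layer\t{expr.layer}\n")
        fh.write("#group\t" + "\t".join(expr.groups.astype(str)) + "\n")
        expr.values.to_csv(fh, sep="\t", index_label="gene")


def read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        layer_line = fh.readline().strip().split("\t")
        group_line = fh.readline().strip().split("\t")
        values = pd.read_csv(fh, sep="\t", index_col="gene")
    if layer_line[0] != "#layer" or group_line[0] != "#group":
        raise ValueError("expected '#layer' and '#group' header lines")
    groups = pd.Series(group_line[1:], index=values.columns, name="group")
    return ExpressionMatrix(layer=layer_line[1], values=values, groups=groups)


def write_complex_map(complex_map: pd.Series, path) -> None:
    complex_map.rename("complex_id").rename_axis("gene").to_csv(path, sep="\t")


def read_complex_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["complex_id"].to_numpy(), index=df["gene"], dtype=object)


def write_cms(table: CmsTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_cms(path) -> CmsTable:
    return CmsTable(table=pd.read_csv(path, sep="\t"))
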