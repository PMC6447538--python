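"""Genome and annotation containers shared across the pipeline.

Coordinates are 0-based half-open throughout; bin ``i`` of a chromosome
covers ``[i * bin_size, (i + 1) * bin_size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: resolutions (bp) the analysis operates at; a GenomeSpec bin size must
#: divide all of them so matrices can be re-binned without remainder.
ANALYSIS_RESOLUTIONS = (25_000, 50_000, 100_000, 500_000)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    ploidy: int | None = 2  # normal copy number; None = undefined (e.g. Y in females)


@dataclass
class GenomeSpec:
    """Chromosome names/lengths/normal ploidies plus the working bin size."""

    chromosomes: list[Chromosome]
    bin_size: int = 25_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for res in ANALYSIS_RESOLUTIONS:
            if res % self.bin_size != 0:
                raise ValueError(
                    f"bin_size {self.bin_size} does not divide analysis resolution {res}"
                )
        for chrom in self.chromosomes:
            if chrom.length <= 0:
                raise ValueError(f"chromosome {chrom.name} has non-positive length")
            if chrom.ploidy is not None and chrom.ploidy not in (1, 2):
                raise ValueError(f"chromosome {chrom.name}: ploidy must be 1, 2 or None")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in genome")

    def length(self, name: str) -> int:
        return self.chromosome(name).length

    def ploidy(self, name: str) -> int | None:
        return self.chromosome(name).ploidy

    def n_bins(self, name: str) -> int:
        return -(-self.length(name) // self.bin_size)

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand", "tss"]


def make_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a gene annotation table.

    Expects columns gene, chrom, start, end, strand, tss; one row (one
    canonical TSS) per gene.
    """
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene annotation missing columns: {missing}")
    out = df.loc[:, GENE_COLUMNS].copy()
    if out["gene"].duplicated().any():
        dups = out.loc[out["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dups[:5]}")
    if (out["start"] >= out["end"]).any():
        raise ValueError("gene annotation has start >= end")
    out = out.reset_index(drop=True)
    return out


@dataclass
class TadTruth:
    """Planted TAD tiling with per-internal-boundary insulation strengths.

    ``domains[chrom]`` tiles the chromosome without overlap;
    ``boundary_strengths[chrom]`` holds one value in [0, 1] per internal
    boundary (1 = fully insulating, 0 = no boundary at all).
    """

    domains: dict[str, list[tuple[int, int]]]
    boundary_strengths: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, doms in self.domains.items():
            doms = sorted(doms)
            self.domains[chrom] = doms
            for (s0, e0), (s1, _e1) in zip(doms, doms[1:]):
                if e0 != s1:
                    raise ValueError(
                        f"domains on {chrom} do not tile: [{s0},{e0}) then [{s1},...)"
                    )
            n_internal = max(len(doms) - 1, 0)
            strengths = np.asarray(
                self.boundary_strengths.get(chrom, np.ones(n_internal)), dtype=float
            )
            if strengths.shape != (n_internal,):
                raise ValueError(
                    f"{chrom}: {len(strengths)} strengths for {n_internal} internal boundaries"
                )
            if ((strengths < 0) | (strengths > 1)).any():
                raise ValueError(f"{chrom}: boundary strengths must lie in [0, 1]")
            self.boundary_strengths[chrom] = strengths

    def boundaries(self, chrom: str) -> np.ndarray:
        """Internal boundary positions (bp) on ``chrom``."""
        doms = self.domains[chrom]
        return np.array([e for _s, e in doms[:-1]], dtype=int)
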