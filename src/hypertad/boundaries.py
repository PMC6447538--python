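"""Cross-sample TAD-boundary comparison: matching within a positional
tolerance, recurrent subgroup-specific boundary loss, CTCF/RAD21 peak
support, and the expression-direction enrichment around lost boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import PeakSet
from .stats import chisq_down_up
from .tads import BoundarySet, InsulationProfile
from .hic import ContactMatrix

PRESENT, WEAK, LOST = "present", "weak", "lost"


@dataclass
class BoundaryMatch:
    """One reference boundary with its per-sample status."""

    chrom: str
    position: int
    status: dict[str, str]  # sample -> present | weak | lost
    tolerance: int

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        bad = {s for s, v in self.status.items() if v not in (PRESENT, WEAK, LOST)}
        if bad:
            raise ValueError(f"invalid status for samples {sorted(bad)}")


def _greedy_match(ref: np.ndarray, other: np.ndarray, tolerance: int) -> dict[int, int]:
    """One-to-one greedy matching of two sorted position arrays: pairs
    within tolerance, taken by smallest distance then leftmost."""
    cand = []
    for i, p in enumerate(ref):
        lo = np.searchsorted(other, p - tolerance, side="left")
        hi = np.searchsorted(other, p + tolerance, side="right")
        for j in range(lo, hi):
            cand.append((abs(int(other[j]) - int(p)), int(p), int(other[j]), i, j))
    cand.sort()
    used_i, used_j = set(), set()
    out = {}
    for _d, _p, _q, i, j in cand:
        if i in used_i or j in used_j:
            continue
        out[i] = j
        used_i.add(i)
        used_j.add(j)
    return out


def match_boundaries(
    sets: list[BoundarySet],
    tolerance: int = 100_000,
    reference: int = 0,
    weak_threshold: float | None = None,
) -> list[BoundaryMatch]:
    """Match every sample's boundaries to a reference set.

    Boundaries within ``tolerance`` bp are considered the same boundary
    (greedy nearest-neighbor, one-to-one). Unmatched reference boundaries
    are ``lost`` in that sample; matched boundaries whose strength falls
    below ``weak_threshold`` (if given) are ``weak``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    bin_sizes = {s.bin_size for s in sets}
    if len(bin_sizes) > 1:
        raise ValueError(f"mixed bin sizes: {sorted(bin_sizes)}")
    ref = sets[reference]
    out = []
    chroms = list(pd.unique(ref.table["chrom"]))
    per_sample_pos = {
        s.sample: {c: s.positions(c) for c in chroms} for s in sets
    }
    per_sample_strength = {}
    for s in sets:
        per_sample_strength[s.sample] = {}
        for c in chroms:
            sub = s.table[s.table["chrom"] == c]
            per_sample_strength[s.sample][c] = sub["strength"].to_numpy()
    for chrom in chroms:
        ref_pos = ref.positions(chrom)
        statuses: list[dict[str, str]] = [dict() for _ in ref_pos]
        for s in sets:
            pos = per_sample_pos[s.sample][chrom]
            strength = per_sample_strength[s.sample][chrom]
            pairs = _greedy_match(ref_pos, pos, tolerance)
            for i in range(len(ref_pos)):
                if i in pairs:
                    j = pairs[i]
                    if weak_threshold is not None and strength[j] < weak_threshold:
                        statuses[i][s.sample] = WEAK
                    else:
                        statuses[i][s.sample] = PRESENT
                else:
                    statuses[i][s.sample] = LOST
        for i, p in enumerate(ref_pos):
            out.append(
                BoundaryMatch(
                    chrom=chrom, position=int(p), status=statuses[i],
                    tolerance=tolerance,
                )
            )
    return out


def recurrent_lost_boundaries(
    matches: list[BoundaryMatch],
    group_labels: dict[str, str],
    min_recurrence: int = 2,
    strict: bool = True,
) -> dict[str, pd.DataFrame]:
    """Boundaries weakened or lost in at least ``min_recurrence`` samples
    of one group; with ``strict=True`` additionally required to be present
    in every sample of the other group."""
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    members = {g: [s for s, lab in group_labels.items() if lab == g] for g in groups}
    for g, mem in members.items():
        if len(mem) < min_recurrence:
            raise ValueError(f"group {g!r} has fewer than {min_recurrence} samples")
    out = {g: [] for g in groups}
    for m in matches:
        for g in groups:
            other = groups[1 - groups.index(g)]
            n_lost = sum(m.status[s] in (WEAK, LOST) for s in members[g])
            ok_other = (
                all(m.status[s] == PRESENT for s in members[other])
                if strict
                else True
            )
            if n_lost >= min_recurrence and ok_other:
                out[g].append(
                    {"chrom": m.chrom, "position": m.position,
                     "n_lost": n_lost, "group": g}
                )
    return {
        g: pd.DataFrame(rows, columns=["chrom", "position", "n_lost", "group"])
        for g, rows in out.items()
    }


def classify_boundary_change(
    cm: ContactMatrix,
    boundary: int,
    insulation: InsulationProfile,
    tolerance: int = 100_000,
    b_weak: float = 0.5,
    b_lost: float = 0.08,
) -> str:
    """Quantitative proxy for the visual strong/weak/lost stratification:
    ``lost`` if no upward delta zero-crossing with swing >= ``b_lost``
    lies within ``tolerance`` of the boundary, ``weak`` if the best swing
    is below ``b_weak``, else ``strong``.

    Defaults are calibrated on simulated matrices at ~50+ counts per
    near-diagonal pixel: noise-only swings stay below ~0.08 log2 units
    while fully insulating boundaries swing above ~1.5.
    """
    if not 0 <= boundary <= cm.n_bins * cm.bin_size:
        raise ValueError(f"boundary {boundary} outside chromosome {cm.chrom}")
    delta = insulation.delta[cm.chrom]
    span = insulation.delta_span // insulation.bin_size
    e = boundary // cm.bin_size
    tol_bins = max(1, tolerance // cm.bin_size)
    best_swing = None
    for k in range(max(0, e - tol_bins - 1), min(len(delta) - 1, e + tol_bins)):
        a, b = delta[k], delta[k + 1]
        if not (np.isfinite(a) and np.isfinite(b)) or not (a < 0 <= b):
            continue
        if abs((k + 1) - e) > tol_bins:
            continue
        after = delta[k + 1: k + 1 + span]
        before = delta[max(0, k - span + 1): k + 1]
        if not (np.isfinite(after).any() and np.isfinite(before).any()):
            continue
        swing = float(np.nanmax(after) - np.nanmin(before))
        if best_swing is None or swing > best_swing:
            best_swing = swing
    if best_swing is None or best_swing < b_lost:
        return LOST
    return WEAK if best_swing < b_weak else "strong"


def peak_support(
    boundaries: BoundarySet, peaks: PeakSet, window: int = 50_000
) -> tuple[pd.Series, float]:
    """Per-boundary flag: is there at least one peak within +/-window of
    the boundary position? Also returns the supported fraction."""
    flags = []
    for _, row in boundaries.table.iterrows():
        pk = peaks.intervals[peaks.intervals["chrom"] == row["chrom"]]
        lo, hi = row["position"] - window, row["position"] + window
        hit = ((pk["start"] < hi) & (pk["end"] > lo)).any()
        flags.append(bool(hit))
    flags = pd.Series(flags, index=boundaries.table.index)
    fraction = float(flags.mean()) if len(flags) else 0.0
    return flags, fraction


@dataclass
class DirectionEnrichment:
    n_down: int
    n_up: int
    genome_wide_down_fraction: float
    chi2: float
    pvalue: float
    undefined: bool = False


def boundary_proximal_enrichment(
    lost: pd.DataFrame,
    genes: pd.DataFrame,
    de_table: pd.DataFrame,
    genome_wide_down_fraction: float,
    radius: int = 1_000_000,
    alpha: float = 0.05,
) -> DirectionEnrichment:
    """Down/up direction split of significant DE features whose TSS lies
    within ``radius`` of any lost boundary, tested against the
    genome-wide down fraction by a 1-df goodness-of-fit chi-square (no
    continuity correction).

    ``lost``: DataFrame with chrom/position. ``de_table``: indexed by gene
    with adj_pvalue and direction columns.
    """
    sig = de_table[de_table["adj_pvalue"] <= alpha]
    tss = genes.set_index("gene")[["chrom", "tss"]]
    proximal = []
    for gene in sig.index:
        if gene not in tss.index:
            continue
        chrom, pos = tss.loc[gene, "chrom"], tss.loc[gene, "tss"]
        near = lost[lost["chrom"] == chrom]
        if len(near) and (np.abs(near["position"] - pos) <= radius).any():
            proximal.append(gene)
    if not proximal:
        return DirectionEnrichment(
            n_down=0, n_up=0,
            genome_wide_down_fraction=genome_wide_down_fraction,
            chi2=np.nan, pvalue=np.nan, undefined=True,
        )
    directions = sig.loc[proximal, "direction"]
    n_down = int((directions == "down").sum())
    n_up = int((directions == "up").sum())
    chi2, p = chisq_down_up(n_down, n_up, genome_wide_down_fraction)
    return DirectionEnrichment(
        n_down=n_down, n_up=n_up,
        genome_wide_down_fraction=genome_wide_down_fraction,
        chi2=chi2, pvalue=p,
    )
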