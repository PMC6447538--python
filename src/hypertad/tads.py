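"""TAD architecture: directionality index, insulation score, boundary and
domain calling, aligned boundary profiles, and A/B compartments.

Boundary calling follows two deterministic rules:

* DI mode — a boundary is placed where the standardized directionality
  index switches from at most ``-t`` to at least ``+t`` within ``gap``
  bins; the boundary sits on the bin edge between the last negative and
  first positive bin, and its strength is the size of the DI jump.
* Insulation mode — a boundary is placed at an upward zero-crossing of
  the insulation delta whose local swing (max after minus min before,
  within the delta span) reaches ``min_swing`` log2 units; the swing is
  the boundary strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic import ContactMatrix


def _as_genome(matrices) -> dict[str, ContactMatrix]:
    if isinstance(matrices, ContactMatrix):
        return {matrices.chrom: matrices}
    return dict(matrices)


@dataclass
class DiProfile:
    window: int
    bin_size: int
    raw: dict[str, np.ndarray]
    z: dict[str, np.ndarray]


@dataclass
class InsulationProfile:
    square: int
    delta_span: int
    bin_size: int
    score: dict[str, np.ndarray]  # log2(value / genome-wide median)
    delta: dict[str, np.ndarray]


@dataclass
class BoundarySet:
    """Called boundaries: one row per boundary with chrom, position (bp, on
    a bin edge), strength and calling method."""

    sample: str
    bin_size: int
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "position", "strength", "method"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"boundary table needs columns {sorted(required)}")
        if len(self.table) and (self.table["position"] % self.bin_size != 0).any():
            raise ValueError("boundary positions must lie on bin edges")
        self.table = (
            self.table.sort_values(["chrom", "position"]).reset_index(drop=True)
        )

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.table[self.table["chrom"] == chrom]
        return sub["position"].to_numpy(dtype=int)


@dataclass
class TadSet:
    table: pd.DataFrame  # chrom, start, end

    def __post_init__(self) -> None:
        t = self.table.sort_values(["chrom", "start"]).reset_index(drop=True)
        if len(t) and (t["start"] >= t["end"]).any():
            raise ValueError("TADs must have start < end")
        for chrom, sub in t.groupby("chrom"):
            e = sub["end"].to_numpy()[:-1]
            s = sub["start"].to_numpy()[1:]
            if (s < e).any():
                raise ValueError(f"overlapping TADs on {chrom}")
        self.table = t


@dataclass
class CompartmentProfile:
    bin_size: int
    values: np.ndarray  # signed eigenvector entry, NaN on masked bins
    labels: np.ndarray  # 'A' / 'B' / '' on masked bins


def _di_raw(balanced: np.ndarray, w: int) -> np.ndarray:
    n = balanced.shape[0]
    di = np.full(n, np.nan)
    for i in range(n):
        row = balanced[i]
        if np.isnan(row).all():
            continue
        a = np.nansum(row[max(0, i - w): i])
        b = np.nansum(row[i + 1: i + 1 + w])
        s = a + b
        if s == 0 or a == b:
            di[i] = 0.0
            continue
        e = s / 2.0
        di[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return di


def directionality_index(
    matrices, window: int = 500_000, scope: str = "genome"
) -> DiProfile:
    """Per-bin directionality index with z-score standardization.

    ``scope`` controls the standardization family: ``"genome"`` pools all
    chromosomes (the default), ``"chrom"`` standardizes each chromosome
    separately.
    """
    genome = _as_genome(matrices)
    bin_size = next(iter(genome.values())).bin_size
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    w = window // bin_size
    if w < 2:
        raise ValueError("window must span at least two bins")
    raw = {}
    for chrom, cm in genome.items():
        if cm.bin_size != bin_size:
            raise ValueError("mixed bin sizes in genome")
        raw[chrom] = _di_raw(cm.get_balanced(), w)

    def zscore(values: np.ndarray, mu: float, sd: float) -> np.ndarray:
        z = np.full_like(values, np.nan)
        finite = np.isfinite(values)
        if sd > 0:
            z[finite] = (values[finite] - mu) / sd
        else:
            z[finite] = 0.0
        return z

    z = {}
    if scope == "genome":
        pooled = np.concatenate([v[np.isfinite(v)] for v in raw.values()])
        mu, sd = (pooled.mean(), pooled.std()) if pooled.size else (0.0, 0.0)
        for chrom, v in raw.items():
            z[chrom] = zscore(v, mu, sd)
    elif scope == "chrom":
        for chrom, v in raw.items():
            finite = v[np.isfinite(v)]
            mu, sd = (finite.mean(), finite.std()) if finite.size else (0.0, 0.0)
            z[chrom] = zscore(v, mu, sd)
    else:
        raise ValueError("scope must be 'genome' or 'chrom'")
    return DiProfile(window=window, bin_size=bin_size, raw=raw, z=z)


def insulation_score(
    matrices, square: int = 250_000, delta_span: int = 125_000
) -> InsulationProfile:
    """Sliding-square insulation normalized by the genome-wide median.

    The square at bin ``i`` averages balanced contacts between the ``s``
    bins upstream and the ``s`` bins downstream of ``i`` (s = square /
    bin_size); values are reported as log2 ratios to the genome-wide
    median so their median is 0 by construction. The delta at ``i`` is
    the mean score over ``(i, i+span]`` minus the mean over ``[i-span, i)``.
    """
    genome = _as_genome(matrices)
    bin_size = next(iter(genome.values())).bin_size
    if square % bin_size or delta_span % bin_size:
        raise ValueError("square and delta_span must be multiples of bin_size")
    s = square // bin_size
    d = delta_span // bin_size
    if s < 1 or d < 1:
        raise ValueError("square and delta_span must span at least one bin")

    values: dict[str, np.ndarray] = {}
    for chrom, cm in genome.items():
        bal = cm.get_balanced()
        n = bal.shape[0]
        v = np.full(n, np.nan)
        for i in range(s, n - s):
            sub = bal[i - s: i, i + 1: i + 1 + s]
            if np.isfinite(sub).any():
                v[i] = np.nanmean(sub)
        values[chrom] = v
    pooled = np.concatenate([v[np.isfinite(v) & (v > 0)] for v in values.values()])
    if pooled.size == 0:
        raise ValueError("no finite positive insulation values")
    med = np.median(pooled)

    score, delta = {}, {}
    for chrom, v in values.items():
        n = len(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            sc = np.log2(v / med)
        sc[~np.isfinite(sc)] = np.nan
        dl = np.full(n, np.nan)
        for i in range(n):
            right = sc[i + 1: i + 1 + d]
            left = sc[max(0, i - d): i]
            if np.isfinite(right).any() and np.isfinite(left).any():
                dl[i] = np.nanmean(right) - np.nanmean(left)
        score[chrom] = sc
        delta[chrom] = dl
    return InsulationProfile(
        square=square, delta_span=delta_span, bin_size=bin_size,
        score=score, delta=delta,
    )


def _call_di(z: np.ndarray, t: float, gap: int) -> list[tuple[int, float]]:
    """Boundary edges and strengths from one chromosome's standardized DI."""
    out = []
    last_neg = None
    for i, v in enumerate(z):
        if not np.isfinite(v):
            continue
        if v <= -t:
            last_neg = i
        elif v >= t:
            if last_neg is not None and i - last_neg <= gap:
                edge = (last_neg + 1 + i) // 2
                out.append((edge, float(v - z[last_neg])))
            last_neg = None
    return out


def _call_insulation(
    delta: np.ndarray, span_bins: int, min_swing: float
) -> list[tuple[int, float]]:
    out = []
    n = len(delta)
    for k in range(n - 1):
        a, b = delta[k], delta[k + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a < 0 <= b:
            after = delta[k + 1: k + 1 + span_bins]
            before = delta[max(0, k - span_bins + 1): k + 1]
            if not (np.isfinite(after).any() and np.isfinite(before).any()):
                continue
            swing = np.nanmax(after) - np.nanmin(before)
            if swing >= min_swing:
                out.append((k + 1, float(swing)))
    return out


def call_boundaries(
    profile,
    sample: str = "sample",
    t: float = 0.5,
    gap: int = 2,
    min_swing: float = 0.1,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[BoundarySet, TadSet]:
    """Call boundaries and derive inter-boundary domains from a DI or
    insulation profile (dispatch on the profile type)."""
    bin_size = profile.bin_size
    rows = []
    if isinstance(profile, DiProfile):
        method = "di"
        per_chrom = {c: _call_di(z, t=t, gap=gap) for c, z in profile.z.items()}
        n_bins = {c: len(z) for c, z in profile.z.items()}
    elif isinstance(profile, InsulationProfile):
        method = "insulation"
        span_bins = profile.delta_span // bin_size
        per_chrom = {
            c: _call_insulation(d, span_bins=span_bins, min_swing=min_swing)
            for c, d in profile.delta.items()
        }
        n_bins = {c: len(d) for c, d in profile.delta.items()}
    else:
        raise TypeError("profile must be a DiProfile or InsulationProfile")

    tad_rows = []
    for chrom, calls in per_chrom.items():
        length = (
            chrom_lengths[chrom] if chrom_lengths else n_bins[chrom] * bin_size
        )
        edges = [0]
        for edge, strength in calls:
            pos = edge * bin_size
            rows.append(
                {"chrom": chrom, "position": pos, "strength": strength,
                 "method": method}
            )
            edges.append(pos)
        edges.append(length)
        for a, b in zip(edges, edges[1:]):
            if a < b:
                tad_rows.append({"chrom": chrom, "start": a, "end": b})
    btable = pd.DataFrame(rows, columns=["chrom", "position", "strength", "method"])
    ttable = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    return (
        BoundarySet(sample=sample, bin_size=bin_size, table=btable),
        TadSet(table=ttable),
    )


def boundary_profile(
    profile, boundaries: BoundarySet, flank: int = 500_000
) -> tuple[np.ndarray, np.ndarray]:
    """Median profile aligned on boundary positions.

    Returns (offsets_bp, median_curve): offsets are bin starts relative to
    the boundary edge, from -flank to +flank - bin_size. Uses the
    standardized DI for a DiProfile and the normalized insulation score
    for an InsulationProfile; missing values are ignored per offset.
    """
    if len(boundaries.table) == 0:
        raise ValueError("empty boundary set")
    bin_size = profile.bin_size
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    f = flank // bin_size
    if isinstance(profile, DiProfile):
        tracks = profile.z
    elif isinstance(profile, InsulationProfile):
        tracks = profile.score
    else:
        raise TypeError("profile must be a DiProfile or InsulationProfile")
    stacks = []
    for _, row in boundaries.table.iterrows():
        track = tracks.get(row["chrom"])
        if track is None:
            continue
        e = int(row["position"]) // bin_size
        window = np.full(2 * f, np.nan)
        lo, hi = e - f, e + f
        src_lo, src_hi = max(0, lo), min(len(track), hi)
        window[src_lo - lo: src_hi - lo] = track[src_lo: src_hi]
        stacks.append(window)
    if not stacks:
        raise ValueError("no boundaries on profiled chromosomes")
    mat = np.vstack(stacks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmedian(mat, axis=0)
    offsets = (np.arange(-f, f)) * bin_size
    return offsets, curve


def compartments(
    cm: ContactMatrix, orientation_track: np.ndarray
) -> CompartmentProfile:
    """A/B compartments from the leading eigenvector of the O/E correlation
    matrix, sign-oriented so positive values correlate with the supplied
    gene-density (or GC) track; A = positive."""
    bal = cm.get_balanced()
    n = bal.shape[0]
    active = ~cm.mask & np.isfinite(bal).any(axis=1)
    if active.sum() < 3:
        raise ValueError("degenerate matrix: too few unmasked bins")
    expected = np.full(n, np.nan)
    for dist in range(n):
        diag = np.diagonal(bal, offset=dist)
        finite = np.isfinite(diag)
        if finite.any():
            expected[dist] = diag[finite].mean()
    dmat = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = bal / expected[dmat]
    sub = oe[np.ix_(active, active)]
    sub = np.nan_to_num(sub, nan=1.0)
    if np.allclose(sub.std(axis=1), 0):
        raise ValueError("degenerate (rank-0) observed/expected matrix")
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr)
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvecs[:, -1]
    track = np.asarray(orientation_track, dtype=float)[active]
    finite = np.isfinite(track)
    if finite.any() and np.corrcoef(lead[finite], track[finite])[0, 1] < 0:
        lead = -lead
    values = np.full(n, np.nan)
    values[active] = lead
    labels = np.array([""] * n, dtype=object)
    labels[active] = np.where(lead > 0, "A", "B")
    return CompartmentProfile(bin_size=cm.bin_size, values=values, labels=labels)


def compartment_agreement(a: CompartmentProfile, b: CompartmentProfile) -> float:
    """Fraction of jointly labeled bins carrying the same A/B label."""
    if a.bin_size != b.bin_size or len(a.labels) != len(b.labels):
        raise ValueError("profiles must share binning")
    joint = (a.labels != "") & (b.labels != "")
    if not joint.any():
        raise ValueError("no jointly labeled bins (disjoint masks)")
    return float((a.labels[joint] == b.labels[joint]).mean())
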