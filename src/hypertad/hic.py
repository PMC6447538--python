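"""Binned Hi-C contact matrices: I/O, bin filtering and balancing.

A ContactMatrix holds the symmetric per-chromosome count matrix together
with a per-bin exclusion mask and, after balancing, per-bin correction
weights. Balancing comes in two flavors:

* ``ice`` — iterative proportional fitting until all unmasked marginals
  agree, normalized so the mean unmasked balanced marginal is 1. Applied
  per chromosome this already removes any whole-chromosome multiplicative
  (copy-number) bias.
* ``caicb`` — ICE followed by a per-chromosome, per-genomic-distance-band
  rescaling so that each chromosome's mean balanced contact at a given
  separation matches the cross-chromosome mean for that separation. This
  equalizes the distance-decay profile across chromosomes, the adjustment
  aneuploid genomes need before chromosomes are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MASK_REASONS = ("low_coverage", "short_range", "user")


@dataclass
class BinMask:
    """Per-bin exclusion flags plus a reason code for each masked bin."""

    mask: np.ndarray  # bool, True = excluded
    reasons: np.ndarray  # object array of reason codes or ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.reasons.shape != self.mask.shape:
            raise ValueError("mask and reasons lengths differ")


@dataclass
class ContactMatrix:
    chrom: str
    bin_size: int
    counts: np.ndarray
    mask: np.ndarray | None = None
    weights: np.ndarray | None = None
    balanced: np.ndarray | None = field(default=None, repr=False)
    converged: bool | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise ValueError("mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bins(self) -> np.ndarray:
        """(n, 2) array of 0-based half-open bin intervals."""
        starts = np.arange(self.n_bins) * self.bin_size
        return np.column_stack([starts, starts + self.bin_size])

    def get_balanced(self) -> np.ndarray:
        """Balanced matrix with masked rows/columns as NaN.

        Falls back to raw counts (masked as NaN) when no balancing has
        been run, so profile code can operate on either.
        """
        if self.balanced is not None:
            out = self.balanced.copy()
        elif self.weights is not None:
            out = self.counts * np.outer(self.weights, self.weights)
        else:
            out = self.counts.copy()
        out[self.mask, :] = np.nan
        out[:, self.mask] = np.nan
        return out

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            chrom=self.chrom,
            bin_size=self.bin_size,
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            weights=None if self.weights is None else self.weights.copy(),
            balanced=None if self.balanced is None else self.balanced.copy(),
            converged=self.converged,
        )


def load_contacts(pixels_path, bins_path) -> dict[str, ContactMatrix]:
    """Load per-chromosome contact matrices from a COO triplet file and a
    BED-like bin table.

    Bin table: TSV ``chrom start end bin_id`` (global, consecutive ids).
    Pixels: TSV ``bin1_id bin2_id count``; upper- or lower-triangle entries
    accepted, duplicates summed, the matrix is mirrored to symmetry.
    """
    bins = pd.read_csv(
        bins_path, sep="\t", header=None, names=["chrom", "start", "end", "bin_id"],
        comment="#",
    )
    bins = bins.sort_values("bin_id").reset_index(drop=True)
    if not (bins["bin_id"].to_numpy() == np.arange(len(bins))).all():
        raise ValueError("bin ids must be consecutive from 0")
    sizes = (bins["end"] - bins["start"]).to_numpy()
    bin_size = int(np.bincount(sizes).argmax()) if len(sizes) else 0
    chrom_of = bins["chrom"].to_numpy()
    # local index of each global bin within its chromosome
    local = np.zeros(len(bins), dtype=int)
    n_per_chrom: dict[str, int] = {}
    for chrom in pd.unique(chrom_of):
        idx = np.flatnonzero(chrom_of == chrom)
        local[idx] = np.arange(len(idx))
        n_per_chrom[str(chrom)] = len(idx)

    mats = {
        chrom: np.zeros((n, n)) for chrom, n in n_per_chrom.items()
    }
    with open(pixels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"pixels line {lineno}: expected 3 fields")
            try:
                i, j = int(parts[0]), int(parts[1])
                c = float(parts[2])
            except ValueError as err:
                raise ValueError(f"pixels line {lineno}: non-numeric field") from err
            if not (0 <= i < len(bins)) or not (0 <= j < len(bins)):
                raise ValueError(f"pixels line {lineno}: bin id out of range")
            if chrom_of[i] != chrom_of[j]:
                raise ValueError(
                    f"pixels line {lineno}: cross-chromosome pixel not supported"
                )
            a, b = sorted((local[i], local[j]))
            mats[str(chrom_of[i])][a, b] += c
    out = {}
    for chrom, m in mats.items():
        full = m + np.triu(m, k=1).T  # mirror the upper triangle
        full = np.triu(full) + np.triu(full, k=1).T
        out[chrom] = ContactMatrix(chrom=chrom, bin_size=bin_size, counts=full)
    return out


def filter_bins(
    cm: ContactMatrix, madmax: float = 2.0
) -> tuple[ContactMatrix, BinMask]:
    """Mask low-coverage bins by the MAD-max rule and zero their rows.

    A bin is masked iff ``(median(log m) - log m) / MAD(log m) > madmax``
    where ``m`` are the per-bin marginal totals over unmasked, nonzero
    bins (one-sided: only low coverage is removed; MAD is the
    consistency-scaled robust sigma estimate). Zero-marginal bins are
    always masked. The decision is single-pass on the input marginals;
    re-application is a no-op whenever the masked bins' contribution to
    the surviving marginals is negligible — the dropout regime the filter
    targets.
    """
    if madmax <= 0:
        raise ValueError("madmax must be positive")
    out = cm.copy()
    n = out.n_bins
    reasons = np.array([""] * n, dtype=object)
    reasons[out.mask] = "user"
    counts = out.counts.copy()
    counts[out.mask, :] = 0.0
    counts[:, out.mask] = 0.0
    mask = out.mask.copy()

    marginals = counts.sum(axis=1)
    active = ~mask & (marginals > 0)
    newly_zero = ~mask & (marginals <= 0)
    if active.any():
        with np.errstate(divide="ignore"):
            logm_all = np.log(marginals)
        logm = logm_all[active]
        med = np.median(logm)
        mad = 1.4826 * np.median(np.abs(logm - med))
        if mad > 0:
            dev = (med - logm_all) / mad
        else:
            # degenerate spread: anything strictly below the median is a
            # dropout, exactly-median bins are fine
            dev = np.where(logm_all < med, np.inf, 0.0)
        low = active & (dev > madmax)
        to_mask = low | newly_zero
        if to_mask.any():
            reasons[to_mask] = "low_coverage"
            mask |= to_mask
            counts[to_mask, :] = 0.0
            counts[:, to_mask] = 0.0
    else:
        to_mask = ~mask
        reasons[to_mask] = "low_coverage"
        mask |= to_mask

    if mask.all():
        warnings.warn(f"{cm.chrom}: all bins masked by coverage filter")
    out.counts = counts
    out.mask = mask
    out.weights = None
    out.balanced = None
    return out, BinMask(mask=mask.copy(), reasons=reasons)


def remove_short_range(cm: ContactMatrix) -> ContactMatrix:
    """Zero the main diagonal and the +/-1 off-diagonals (same-bin and
    adjacent-bin ligation artifacts)."""
    out = cm.copy()
    n = out.n_bins
    idx = np.arange(n)
    out.counts[idx, idx] = 0.0
    out.counts[idx[:-1], idx[:-1] + 1] = 0.0
    out.counts[idx[:-1] + 1, idx[:-1]] = 0.0
    out.weights = None
    out.balanced = None
    return out


def _ice(cm: ContactMatrix, max_iter: int, tol: float) -> ContactMatrix:
    out = cm.copy()
    n = out.n_bins
    active = ~out.mask
    counts = out.counts.copy()
    counts[~active, :] = 0.0
    counts[:, ~active] = 0.0
    bias = np.ones(n)
    converged = False
    for _ in range(max_iter):
        w = np.zeros(n)
        w[active] = 1.0 / bias[active]
        m = (counts * w[None, :]).sum(axis=1) * w
        mu = m[active].mean() if active.any() else 0.0
        if mu <= 0:
            break
        cv = m[active].std() / mu
        if cv < tol:
            converged = True
            break
        adj = np.ones(n)
        adj[active] = m[active] / mu
        bias *= adj
    weights = np.full(n, np.nan)
    weights[active] = 1.0 / bias[active]
    # normalize: mean unmasked balanced marginal = 1
    bal = counts * np.outer(np.nan_to_num(weights), np.nan_to_num(weights))
    mmean = bal.sum(axis=1)[active].mean() if active.any() else 0.0
    if mmean > 0:
        weights /= np.sqrt(mmean)
    out.weights = weights
    out.converged = converged
    out.balanced = None
    return out


def balance(
    cm: ContactMatrix,
    method: str = "ice",
    max_iter: int = 200,
    tol: float = 1e-5,
) -> ContactMatrix:
    """Balance one chromosome. ``method='caicb'`` on a single matrix is ICE
    (the chromosome adjustment needs the whole genome; see
    :func:`balance_genome`)."""
    if method not in ("ice", "caicb"):
        raise ValueError(f"unknown balancing method {method!r}")
    return _ice(cm, max_iter=max_iter, tol=tol)


def balance_genome(
    matrices: dict[str, ContactMatrix],
    method: str = "caicb",
    max_iter: int = 200,
    tol: float = 1e-5,
) -> dict[str, ContactMatrix]:
    """Balance every chromosome; with ``caicb`` additionally rescale each
    chromosome's distance bands to the cross-chromosome band means."""
    if method not in ("ice", "caicb"):
        raise ValueError(f"unknown balancing method {method!r}")
    out = {c: _ice(m, max_iter=max_iter, tol=tol) for c, m in matrices.items()}
    if method == "ice":
        return out
    # per-chromosome balanced matrices with NaN on masked bins
    bal = {c: m.get_balanced() for c, m in out.items()}
    max_d = max(m.n_bins for m in out.values()) - 1
    band_means: dict[str, np.ndarray] = {}
    for c, b in bal.items():
        n = b.shape[0]
        means = np.full(max_d + 1, np.nan)
        for d in range(n):
            diag = np.diagonal(b, offset=d)
            finite = np.isfinite(diag)
            if finite.any():
                means[d] = diag[finite].mean()
        band_means[c] = means
    stacked = np.vstack([band_means[c] for c in out])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        target = np.nanmean(stacked, axis=0)
    for c, m in out.items():
        b = bal[c]
        n = b.shape[0]
        scaled = b.copy()
        for d in range(n):
            bm = band_means[c][d]
            if np.isfinite(bm) and bm > 0 and np.isfinite(target[d]) and target[d] > 0:
                scale = target[d] / bm
                i = np.arange(n - d)
                scaled[i, i + d] *= scale
                if d > 0:
                    scaled[i + d, i] *= scale
        m.balanced = scaled
    return out
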