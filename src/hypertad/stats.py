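"""Shared statistical primitives: BH adjustment, vectorized Spearman,
chi-square goodness of fit on a two-way split."""

from __future__ import annotations

import numpy as np
from scipy import stats, special
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if finite.sum():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def rank_standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rank rows (average ties) and standardize to zero mean / unit norm.

    Dot products of two such vectors give the Spearman coefficient.
    Constant rows come back as all-NaN.
    """
    r = stats.rankdata(x, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=axis, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = r / norm
    return r


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p between every row of ``a`` and row of ``b``.

    ``a``: (m, n) and ``b``: (k, n) across the same n samples. Returns
    (m, k) coefficient and p matrices; pairs involving a constant vector
    are NaN. p uses the t approximation (the convention for n > ~10).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = a.shape[1]
    if b.shape[1] != n:
        raise ValueError("sample dimensions differ")
    ra = rank_standardize(a)
    rb = rank_standardize(b)
    rho = ra @ rb.T
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[~np.isfinite(rho)] = np.nan
    return rho, p


def chisq_down_up(n_down: int, n_up: int, down_fraction: float) -> tuple[float, float]:
    """Goodness-of-fit chi-square (1 df, no continuity correction) of an
    observed down/up split against a reference down fraction."""
    if not 0.0 < down_fraction < 1.0:
        raise ValueError("down_fraction must be strictly between 0 and 1")
    total = n_down + n_up
    if total == 0:
        raise ValueError("no observations")
    expected = np.array([total * down_fraction, total * (1.0 - down_fraction)])
    observed = np.array([n_down, n_up], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(special.chdtrc(1, stat))
    return stat, p


def hypergeom_sf_at_least(k: int, total: int, successes: int, draws: int) -> float:
    """P(X >= k) for a hypergeometric draw of ``draws`` from ``total`` with
    ``successes`` marked items."""
    return float(stats.hypergeom.sf(k - 1, total, successes, draws))
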