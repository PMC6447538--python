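"""Expression-layer analytics: expressed-gene filtering, iterative
empirical-control normalization, differential expression, mRNA-protein
correlation, complex co-regulation, partial correlation and the
chromosome-morphology score comparison.

Differential expression is a Welch two-sample t-test on log-scale values
with Benjamini-Hochberg control: the downstream analyses consume only
(log2 fold change, adjusted p, direction), which this supplies without a
count-model dependency. Unwanted-variation removal follows the iterative
empirical-control scheme: features that look null (BH-adjusted p above a
high threshold) define controls, unwanted factors are estimated from the
group-mean-centered control submatrix by SVD, regressed out, and the
control set is re-derived, for a fixed number of iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust, spearman_matrix, rank_standardize


@dataclass
class ExpressionMatrix:
    """Genes x samples values for one layer, with sample group labels."""

    layer: str  # 'rna' | 'protein'
    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label
    batches: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in ("rna", "protein"):
            raise ValueError("layer must be 'rna' or 'protein'")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without group label: {missing[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class DeResult:
    table: pd.DataFrame  # index gene: log2fc, pvalue, adj_pvalue, direction

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adj_pvalue"] <= alpha]


@dataclass
class CmsTable:
    """Chromosome morphology scores: one row per scored metaphase."""

    table: pd.DataFrame  # case_id, group, metaphase_index, score

    def __post_init__(self) -> None:
        required = {"case_id", "group", "metaphase_index", "score"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"CMS table needs columns {sorted(required)}")
        if not self.table["score"].isin([1, 2, 3]).all():
            raise ValueError("CMS scores must be integers in {1, 2, 3}")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    return counts / libsize * 1e6


def filter_expressed(
    counts: pd.DataFrame,
    groups: pd.Series,
    cpm_threshold: float = 1.0,
    fraction: float = 0.8,
) -> pd.Index:
    """Genes with CPM strictly above ``cpm_threshold`` in strictly more than
    ``fraction`` of samples in at least one group."""
    c = cpm(counts)
    keep = pd.Series(False, index=counts.index)
    for _group, samples in groups.groupby(groups):
        sub = c.loc[:, samples.index]
        frac_expr = (sub > cpm_threshold).mean(axis=1)
        keep |= frac_expr > fraction
    return counts.index[keep]


def _welch_rows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test; degenerate rows (zero variance in both
    groups) fall back to p=1 on equal means, rank test otherwise."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    stat = np.asarray(res.statistic, dtype=float)
    degenerate = ~np.isfinite(pvals)
    for i in np.flatnonzero(degenerate):
        if np.isclose(x[i].mean(), y[i].mean()):
            pvals[i] = 1.0
            stat[i] = 0.0
        else:
            try:
                pvals[i] = stats.mannwhitneyu(
                    x[i], y[i], alternative="two-sided"
                ).pvalue
            except ValueError:
                pvals[i] = np.nan
            stat[i] = np.sign(x[i].mean() - y[i].mean()) * np.inf
    return stat, pvals


def differential_expression(
    values: pd.DataFrame | ExpressionMatrix,
    groups: pd.Series | None = None,
) -> DeResult:
    """Per-feature Welch test on log-scale values between two groups.

    Fold change is group1 minus group2 mean (log2 scale), where group1 is
    the first label in sorted order unless ``groups`` is categorical with
    an explicit order.
    """
    if isinstance(values, ExpressionMatrix):
        groups = values.groups
        values = values.values
    if groups is None:
        raise ValueError("groups required")
    groups = groups.reindex(values.columns)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1 = values.loc[:, groups == labels[0]].to_numpy(dtype=float)
    g2 = values.loc[:, groups == labels[1]].to_numpy(dtype=float)
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    lfc = g1.mean(axis=1) - g2.mean(axis=1)
    _stat, pvals = _welch_rows(g1, g2)
    adj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=values.index,
    )
    return DeResult(table=table)


def median_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's median (log-scale ratio convention)."""
    return values - values.median(axis=0)


@dataclass
class EmpiricalControlResult:
    controls: pd.Index
    adjusted: pd.DataFrame
    n_iterations_run: int
    converged_cleanly: bool = True
    control_history: list[int] = field(default_factory=list)


def iterative_empirical_controls(
    expr: pd.DataFrame | ExpressionMatrix,
    groups: pd.Series | None = None,
    n_iter: int = 10,
    control_p: float = 0.9,
    k_factors: int = 2,
) -> EmpiricalControlResult:
    """Iterative empirical-control normalization.

    Starts from median-normalized data; controls are features whose
    differential-abundance BH-adjusted p exceeds ``control_p``. At each of
    ``n_iter`` iterations, up to ``k_factors`` unwanted factors are
    estimated as the leading right singular vectors of the
    group-mean-centered control submatrix, regressed out of the full
    matrix (alongside the group effect, which is protected), and controls
    are re-derived from the adjusted matrix. ``k_factors=0`` reduces to
    median normalization.

    A candidate factor is only removed when its singular value exceeds
    the Marchenko-Pastur expectation for an iid-noise matrix of the same
    shape (robust sigma from the centered control entries, 5% margin):
    on structureless data no factor clears the bar and the matrix passes
    through unchanged, so the procedure cannot overcorrect pure noise.
    """
    if isinstance(expr, ExpressionMatrix):
        groups = expr.groups
        expr = expr.values
    if groups is None:
        raise ValueError("groups required")
    groups = groups.reindex(expr.columns)
    for label, members in groups.groupby(groups):
        if len(members) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 samples")

    base = median_normalize(expr)
    de = differential_expression(base, groups)
    controls = base.index[de.table["adj_pvalue"] > control_p]
    history = [len(controls)]
    if k_factors == 0:
        return EmpiricalControlResult(
            controls=controls, adjusted=base, n_iterations_run=0,
            control_history=history,
        )

    labels = pd.unique(groups)
    design = np.column_stack(
        [np.ones(base.shape[1])] + [(groups == lab).to_numpy(float) for lab in labels[:-1]]
    )
    adjusted = base
    n_run = 0
    clean = True
    for _ in range(n_iter):
        if len(controls) == 0:
            clean = False
            break
        ctrl = base.loc[controls].to_numpy(dtype=float)
        # remove group means so factors cannot absorb the biology
        centered = ctrl.copy()
        for lab in labels:
            cols = (groups == lab).to_numpy()
            centered[:, cols] -= centered[:, cols].mean(axis=1, keepdims=True)
        k = min(k_factors, min(centered.shape) - 1)
        if k < 1:
            clean = False
            break
        _u, svals, vt = np.linalg.svd(centered, full_matrices=False)
        # Marchenko-Pastur noise bar: robust sigma * (sqrt(m) + sqrt(n))
        sigma = np.median(np.abs(centered - np.median(centered))) / 0.6745
        bar = 1.05 * sigma * (np.sqrt(centered.shape[0]) + np.sqrt(centered.shape[1]))
        k = int(min(k, (svals > bar).sum()))
        if k == 0:
            adjusted = base
            de = differential_expression(adjusted, groups)
            controls = adjusted.index[de.table["adj_pvalue"] > control_p]
            history.append(len(controls))
            n_run += 1
            continue
        factors = vt[:k].T  # samples x k
        x = np.column_stack([design, factors])
        y = base.to_numpy(dtype=float).T  # samples x genes
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        unwanted = factors @ coef[design.shape[1]:, :]  # samples x genes
        adjusted = pd.DataFrame(
            base.to_numpy(dtype=float) - unwanted.T,
            index=base.index, columns=base.columns,
        )
        de = differential_expression(adjusted, groups)
        controls = adjusted.index[de.table["adj_pvalue"] > control_p]
        history.append(len(controls))
        n_run += 1
    return EmpiricalControlResult(
        controls=controls, adjusted=adjusted, n_iterations_run=n_run,
        converged_cleanly=clean, control_history=history,
    )


def mrna_protein_correlation(
    rna: pd.DataFrame, protein: pd.DataFrame, min_pairs: int = 6
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Spearman correlation between the two layers across samples.

    Genes missing in one layer are dropped (counted in the summary);
    genes with fewer than ``min_pairs`` paired finite values are skipped.
    Returns (per-gene table, summary dict).
    """
    shared = rna.index.intersection(protein.index)
    samples = rna.columns.intersection(protein.columns)
    n_dropped = len(rna.index.union(protein.index)) - len(shared)
    rows = []
    for gene in shared:
        x = rna.loc[gene, samples].to_numpy(dtype=float)
        y = protein.loc[gene, samples].to_numpy(dtype=float)
        finite = np.isfinite(x) & np.isfinite(y)
        if finite.sum() < min_pairs:
            continue
        rho, p = stats.spearmanr(x[finite], y[finite])
        rows.append({"gene": gene, "rho": rho, "pvalue": p})
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["rho", "pvalue"]
    )
    if len(table):
        table["adj_pvalue"] = bh_adjust(table["pvalue"].to_numpy())
    summary = {
        "n_genes": len(table),
        "n_unmatched": n_dropped,
        "mean_rho": float(table["rho"].mean()) if len(table) else np.nan,
        "fraction_positive": float((table["rho"] > 0).mean()) if len(table) else np.nan,
        "fraction_significant": (
            float((table["adj_pvalue"] <= 0.05).mean()) if len(table) else np.nan
        ),
    }
    return table, summary


def pairwise_spearman(values: pd.DataFrame, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Spearman coefficient across samples for an explicit list of feature
    pairs (vectorized through rank-standardized rows)."""
    ranks = pd.DataFrame(
        rank_standardize(values.to_numpy(dtype=float)),
        index=values.index, columns=values.columns,
    )
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        out[k] = float(np.nansum(ranks.loc[a].to_numpy() * ranks.loc[b].to_numpy()))
    return np.clip(out, -1.0, 1.0)


def complex_coregulation(
    values: pd.DataFrame,
    complex_map: pd.Series,
    n_random: int = 2000,
    seed: int = 0,
) -> dict:
    """Within-complex vs random protein-pair co-regulation.

    ``complex_map``: gene -> complex id. Returns the two coefficient
    distributions, their means, and a two-sided Mann-Whitney p.
    """
    members = complex_map[complex_map.index.isin(values.index)]
    within_pairs: list[tuple[str, str]] = []
    for _cid, genes in members.groupby(members):
        g = list(genes.index)
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                within_pairs.append((g[i], g[j]))
    if not within_pairs:
        raise ValueError("no complex with >= 2 measured members")
    rng = np.random.default_rng(seed)
    genes = np.asarray(values.index)
    idx = rng.integers(0, len(genes), size=(n_random, 2))
    idx = idx[idx[:, 0] != idx[:, 1]]
    random_pairs = [(genes[i], genes[j]) for i, j in idx]
    within = pairwise_spearman(values, within_pairs)
    rand = pairwise_spearman(values, random_pairs)
    p = stats.mannwhitneyu(within, rand, alternative="two-sided").pvalue
    return {
        "within": within,
        "random": rand,
        "mean_within": float(np.mean(within)),
        "mean_random": float(np.mean(rand)),
        "pvalue": float(p),
    }


def partial_correlation_by_subtype(
    x: np.ndarray, y: np.ndarray, subtype: np.ndarray
) -> float:
    """Spearman correlation of x and y after regressing each on the
    subtype indicator — guards against Simpson's paradox from pooled
    subtype mean-shifts."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    labels = pd.unique(pd.Series(subtype))
    if len(labels) < 2:
        warnings.warn("single subtype: returning plain Spearman correlation")
        return float(stats.spearmanr(x, y).statistic)
    design = np.column_stack(
        [np.ones(len(x))] + [(np.asarray(subtype) == lab).astype(float) for lab in labels[:-1]]
    )
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(stats.spearmanr(rx, ry).statistic)


def strata_correlation_compare(
    coefficients: np.ndarray, strata: np.ndarray
) -> dict:
    """Two strata: two-sided Wilcoxon rank-sum; more: Kruskal-Wallis.
    Strata with fewer than 2 members are dropped with a warning."""
    coefficients = np.asarray(coefficients, float)
    strata = np.asarray(strata)
    groups = []
    names = []
    for lab in pd.unique(pd.Series(strata)):
        vals = coefficients[strata == lab]
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            warnings.warn(f"stratum {lab!r} has < 2 members; dropped")
            continue
        groups.append(vals)
        names.append(lab)
    if len(groups) < 2:
        raise ValueError("need at least two usable strata")
    if len(groups) == 2:
        stat, p = stats.ranksums(groups[0], groups[1])
        test = "wilcoxon_rank_sum"
    else:
        stat, p = stats.kruskal(*groups)
        test = "kruskal_wallis"
    return {"test": test, "statistic": float(stat), "pvalue": float(p),
            "strata": names}


def compare_cms(
    table: CmsTable, pooled: bool = False, alternative_lower: str | None = None
) -> dict:
    """Group CMS comparison: per-case mean scores, group means, and a
    one-sided Mann-Whitney test that ``alternative_lower`` (default: the
    first group) scores lower.

    ``pooled=True`` pools all metaphases per group instead of averaging
    per case first.
    """
    df = table.table
    groups = list(pd.unique(df["group"]))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    lower = alternative_lower if alternative_lower is not None else groups[0]
    other = [g for g in groups if g != lower][0]
    case_means = df.groupby(["group", "case_id"])["score"].mean()
    for g in groups:
        if len(case_means.loc[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cases")
    if pooled:
        a = df.loc[df["group"] == lower, "score"].to_numpy(float)
        b = df.loc[df["group"] == other, "score"].to_numpy(float)
        group_means = {g: float(df.loc[df["group"] == g, "score"].mean())
                       for g in groups}
    else:
        a = case_means.loc[lower].to_numpy(float)
        b = case_means.loc[other].to_numpy(float)
        group_means = {lower: float(a.mean()), other: float(b.mean())}
    p = stats.mannwhitneyu(a, b, alternative="less").pvalue
    return {
        "case_means": case_means,
        "group_means": group_means,
        "pvalue": float(p),
        "alternative": f"{lower} < {other}",
    }
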