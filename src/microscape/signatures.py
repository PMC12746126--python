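"""Microregional transcriptomic scoring and association tests.

Counts (genes x microregions) are normalized by median-of-ratios size
factors, log10(x+1)-transformed, and scored per microregion against gene
sets with a rank-weighted single-sample enrichment running sum.  Scores can
be min-max or z scaled and compared across compartments with stratified
Pearson correlation and Mann-Whitney U tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

DEFAULT_ALPHA = 0.25


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of unique gene identifiers."""

    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ConfigurationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError(f"gene set {self.name!r} has duplicate members")

    def __len__(self):
        return len(self.genes)


def read_gmt(path) -> dict[str, GeneSet]:
    """Parse a GMT file (name <tab> description <tab> genes...)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"malformed GMT line (need name, description, >=1 gene): {line!r}"
                )
            name = fields[0]
            genes = tuple(g for g in fields[2:] if g)
            sets[name] = GeneSet(name, genes)
    return sets


def write_gmt(gene_sets: Mapping[str, GeneSet] | Sequence[GeneSet], path) -> None:
    if isinstance(gene_sets, Mapping):
        gene_sets = list(gene_sets.values())
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# normalization


def size_factor_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization (genes x microregions).

    Genes with a zero count in any microregion are excluded from the
    reference; each size factor is the median ratio of a column's counts to
    the per-gene geometric means.  Returns (normalized, size_factors).
    """
    if counts.shape[1] < 2:
        raise ValueError("size-factor normalization requires >= 2 microregions")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    reference = np.all(values > 0, axis=1)
    if not reference.any():
        raise ValueError(
            "no gene has nonzero counts in every microregion; "
            "cannot build the median-of-ratios reference"
        )
    log_ref = np.log(values[reference])
    log_geomean = log_ref.mean(axis=1)
    size_factors = np.exp(np.median(log_ref - log_geomean[:, None], axis=0))
    normalized = counts / size_factors
    return normalized, pd.Series(size_factors, index=counts.columns, name="size_factor")


def log_transform(normalized: pd.DataFrame | np.ndarray):
    """log10(x + 1); negative input is an error."""
    values = np.asarray(normalized, dtype=float)
    if np.any(values < 0):
        raise ValueError("log transform requires non-negative values")
    if isinstance(normalized, pd.DataFrame):
        return pd.DataFrame(
            np.log10(values + 1.0), index=normalized.index, columns=normalized.columns
        )
    return np.log10(values + 1.0)


# ---------------------------------------------------------------------------
# single-sample gene-set enrichment


def ssgsea(expr, genes: Sequence[str] | None = None, gene_set: GeneSet | None = None,
           alpha: float = DEFAULT_ALPHA) -> float:
    """Single-sample enrichment score: rank-weighted running-sum statistic.

    Genes are ranked by expression descending (rank 1 = highest, average
    ranks for ties).  Walking the ranked list, the score accumulates the
    difference between the in-set empirical CDF weighted by rank^alpha
    (normalized over set members) and the uniform out-of-set ECDF.
    """
    if gene_set is None:
        raise ValueError("gene_set is required")
    if isinstance(expr, pd.Series):
        genes = list(expr.index)
        values = expr.to_numpy(dtype=float)
    else:
        values = np.asarray(expr, dtype=float)
        if genes is None:
            raise ValueError("genes must accompany a bare expression vector")
        genes = list(genes)
    n = len(values)
    if n < 2:
        raise ValueError("expression vector must contain >= 2 genes")
    if len(genes) != n:
        raise ValueError("genes and expression vector differ in length")
    members = set(gene_set.genes)
    in_set = np.array([g in members for g in genes])
    k = int(in_set.sum())
    if k == 0:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the vector")
    if k == n:
        raise ValueError("gene set covers every gene; out-of-set ECDF is degenerate")
    ranks = stats.rankdata(-values, method="average")  # 1 = highest, ties averaged
    order = np.lexsort((np.arange(n), ranks))  # descending expression, stable
    weights = ranks**alpha
    in_sorted = in_set[order]
    w_sorted = np.where(in_sorted, weights[order], 0.0)
    cdf_in = np.cumsum(w_sorted) / w_sorted.sum()
    cdf_out = np.cumsum(~in_sorted) / (n - k)
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_matrix(
    expr: pd.DataFrame,
    gene_sets: Mapping[str, GeneSet] | Sequence[GeneSet],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Score every gene set in every microregion column; sets x microregions."""
    if isinstance(gene_sets, Mapping):
        gene_sets = list(gene_sets.values())
    genes = list(expr.index)
    rows = {}
    for gs in gene_sets:
        unknown = set(gs.genes) - set(genes)
        if len(unknown) == len(gs.genes):
            raise ValueError(f"gene set {gs.name!r} shares no genes with the matrix")
        rows[gs.name] = [
            ssgsea(expr[col].to_numpy(), genes, gs, alpha=alpha) for col in expr.columns
        ]
    return pd.DataFrame(rows, index=expr.columns).T


def scale_scores(scores: pd.DataFrame, method: str = "minmax") -> pd.DataFrame:
    """Per-set scaling across microregions: 'minmax' to [0,1] or 'zscore'.

    Constant rows map to 0.5 (min-max) or 0 (z-score).
    """
    values = scores.to_numpy(dtype=float)
    out = np.empty_like(values)
    if method == "minmax":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        constant = (span == 0).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (values - lo) / span
        out[constant] = 0.5
    elif method == "zscore":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, ddof=1, keepdims=True)
        constant = (sd == 0).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (values - mu) / sd
        out[constant] = 0.0
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return pd.DataFrame(out, index=scores.index, columns=scores.columns)


# ---------------------------------------------------------------------------
# association tests


def pearson_test(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p from the t statistic at n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("vectors differ in length")
    if n < 3:
        return float("nan"), float("nan"), n
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def stratified_correlation(
    scores_x, scores_y, strata
) -> pd.DataFrame:
    """Per-stratum Pearson correlation (r, two-sided p, n).

    Strata with n < 3 or zero variance yield NA with an ``ok`` flag of False.
    """
    x = np.asarray(scores_x, dtype=float)
    y = np.asarray(scores_y, dtype=float)
    strata = np.asarray(strata)
    if not (len(x) == len(y) == len(strata)):
        raise ValueError("scores and strata must have equal length")
    rows = []
    for stratum in pd.unique(strata):
        mask = strata == stratum
        r, p, n = pearson_test(x[mask], y[mask])
        rows.append(
            {"stratum": stratum, "r": r, "p": p, "n": n, "ok": np.isfinite(r)}
        )
    return pd.DataFrame(rows).set_index("stratum")


def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """Counts of the null Mann-Whitney U distribution (no ties), U=0..n1*n2."""
    # standard recurrence c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1):
    # the largest combined value comes from group 1 (beating all n of group 2)
    # or from group 2; total arrangements sum to C(n1 + n2, n1)
    size = n1 * n2 + 1
    dp = np.zeros((n1 + 1, n2 + 1, size))
    dp[:, :, 0] = 0.0
    dp[0, :, 0] = 1.0
    dp[:, 0, 0] = 1.0
    for m in range(1, n1 + 1):
        for n in range(1, n2 + 1):
            shifted = np.zeros(size)
            shifted[n:] = dp[m - 1, n, : size - n]
            dp[m, n] = shifted + dp[m, n - 1]
    return dp[n1, n2]


def rank_compare(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (for group_a) with a two-sided p value.

    Exact enumeration of the null U distribution when the combined sample has
    no ties and n <= 20; otherwise a normal approximation with tie
    correction (no continuity correction, so identical groups give p = 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and n1 + n2 <= 20:
        counts = _exact_u_cdf(n1, n2)
        total = counts.sum()
        center = n1 * n2 / 2.0
        dev = abs(u1 - center)
        extreme = np.abs(np.arange(n1 * n2 + 1) - center) >= dev - 1e-12
        p = counts[extreme].sum() / total
    else:
        mean_u = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u == 0:
            return float(u1), 1.0
        z = (u1 - mean_u) / np.sqrt(var_u)
        p = 2.0 * stats.norm.sf(abs(z))
    return float(u1), float(min(p, 1.0))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p values (optional; not applied by default anywhere)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_idx in range(n - 1, -1, -1):
        idx = order[rank_idx]
        running_min = min(running_min, p[idx] * n / (rank_idx + 1))
        adjusted[idx] = running_min
    return adjusted
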