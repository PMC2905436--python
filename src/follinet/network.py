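"""Weighted co-expression network: adjacency, scale-free fit, TOM.

The network starts from the Pearson correlation matrix of the selected
genes across samples.  Soft thresholding raises the absolute correlation
to a power beta, a_ij = |cor_ij|^beta (unsigned convention), chosen as
the smallest integer for which the network's degree distribution is
approximately scale-free: the truncated fitting index R^2 of the
regression of log10 p(k) on log10 k (and k) exceeds 0.75.  The adjacency
is then transformed into the topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu a_uj  (u != i, j)

which credits both direct connection strength and shared neighbours, and
1 - TOM is the dissimilarity the module dendrogram is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaleFreeFit",
    "correlation_matrix",
    "adjacency",
    "connectivity",
    "power_law_regression",
    "scale_free_fit",
    "pick_beta",
    "tom",
]


@dataclass
class ScaleFreeFit:
    """Degree-distribution power-law diagnostics for one adjacency."""

    bin_centers: np.ndarray
    frequencies: np.ndarray
    slope: float
    r2_plain: float
    r2_truncated: float
    slope_truncated: float = 0.0
    beta: float | None = None


def correlation_matrix(
    expr: pd.DataFrame, gene_subset: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlations between all gene pairs (genes are rows)."""
    sub = expr.loc[list(gene_subset)] if gene_subset is not None else expr
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = sub.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"gene {bad!r} has zero variance across samples")
    cor = np.corrcoef(x)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=sub.index, columns=sub.index)


def adjacency(cor: pd.DataFrame | np.ndarray, beta: float) -> pd.DataFrame:
    """Unsigned power adjacency a_ij = |cor_ij|^beta, unit diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if isinstance(cor, pd.DataFrame):
        idx, vals = cor.index, cor.to_numpy(dtype=float)
    else:
        vals = np.asarray(cor, dtype=float)
        idx = pd.RangeIndex(vals.shape[0])
    adj = np.abs(vals) ** beta
    np.fill_diagonal(adj, 1.0)
    out = pd.DataFrame(adj, index=idx, columns=idx)
    out.attrs["beta"] = beta
    return out


def connectivity(adj: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = adj.to_numpy() if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    return a.sum(axis=1) - np.diag(a)


def power_law_regression(k: np.ndarray, p: np.ndarray) -> ScaleFreeFit:
    """Fit log10 p(k) on log10 k (plain) and on [log10 k, k] (truncated).

    ``k`` are bin-representative connectivities (positive) with
    frequencies ``p`` (positive, typically summing to 1).  Returns the
    plain-model slope and both fitting indices R^2, clamped to [0, 1].
    A perfectly scale-free distribution p(k) proportional to k^-gamma
    yields r2_plain = 1 and slope = -gamma.
    """
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    if k.size < 3:
        raise ValueError("degenerate fit: need at least 3 occupied bins")
    if np.any(k <= 0) or np.any(p <= 0):
        raise ValueError("k and p(k) must be strictly positive for the log-log fit")
    logk, logp = np.log10(k), np.log10(p)

    X1 = np.column_stack([np.ones_like(logk), logk])
    coef1, *_ = np.linalg.lstsq(X1, logp, rcond=None)
    fit1 = X1 @ coef1
    sst = np.sum((logp - logp.mean()) ** 2)
    r2_plain = 1.0 if sst == 0 else 1.0 - np.sum((logp - fit1) ** 2) / sst

    X2 = np.column_stack([np.ones_like(logk), logk, k])
    coef2, *_ = np.linalg.lstsq(X2, logp, rcond=None)
    fit2 = X2 @ coef2
    r2_trunc = 1.0 if sst == 0 else 1.0 - np.sum((logp - fit2) ** 2) / sst

    return ScaleFreeFit(
        bin_centers=k,
        frequencies=p,
        slope=float(coef1[1]),
        r2_plain=float(np.clip(r2_plain, 0.0, 1.0)),
        r2_truncated=float(np.clip(r2_trunc, 0.0, 1.0)),
        slope_truncated=float(coef2[1]),
    )


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> ScaleFreeFit:
    """Bin connectivities and regress the log-log degree distribution.

    ``k`` is split into ``n_bins`` equal-width bins; p(k) is the
    occupancy fraction per bin, empty bins are dropped, and the bin-mean
    connectivity is the regressor.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-12  # include the max in the last bin
    which = np.digitize(k, edges) - 1
    centers, freqs = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            centers.append(k[mask].mean())
            freqs.append(mask.mean())
    if len(centers) < 3:
        raise ValueError(
            f"degenerate fit: only {len(centers)} occupied bin(s); "
            "connectivity distribution too concentrated"
        )
    return power_law_regression(np.array(centers), np.array(freqs))


def pick_beta(
    expr_or_cor: pd.DataFrame,
    gene_subset: list[str] | None = None,
    beta_grid: list[int] | None = None,
    r2_threshold: float = 0.75,
    n_bins: int = 10,
    is_correlation: bool = False,
) -> tuple[int, dict[int, ScaleFreeFit], bool]:
    """Smallest soft-threshold power with truncated R^2 above threshold.

    Scans the integer grid (default 1..20), computing the truncated
    scale-free fitting index at each power.  Returns ``(beta, fits,
    warned)``: the smallest qualifying beta, the per-beta fit table, and
    a warning flag set when no beta qualifies (then the argmax of the
    truncated R^2 is returned instead).
    """
    if beta_grid is None:
        beta_grid = list(range(1, 21))
    if not beta_grid:
        raise ValueError("beta grid must be non-empty")
    if not 0 < r2_threshold < 1:
        raise ValueError("r2_threshold must lie in (0, 1)")
    cor = expr_or_cor if is_correlation else correlation_matrix(expr_or_cor, gene_subset)
    fits: dict[int, ScaleFreeFit] = {}
    for b in sorted(beta_grid):
        adj = adjacency(cor, b)
        k = connectivity(adj)
        try:
            fit = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            continue
        fit.beta = b
        fits[b] = fit
    if not fits:
        raise ValueError("no beta on the grid produced a fittable degree distribution")
    # a scale-free degree distribution is decreasing: a fit whose
    # power-law term has positive exponent is disqualified regardless of
    # its R^2 (signed fitting index convention)
    def decreasing(f):
        return f.slope < 0 and f.slope_truncated < 0

    for b in sorted(fits):
        if decreasing(fits[b]) and fits[b].r2_truncated > r2_threshold:
            return b, fits, False
    candidates = [b for b in fits if decreasing(fits[b])] or list(fits)
    best = max(candidates, key=lambda b: (fits[b].r2_truncated, -b))
    return best, fits, True


def select_beta_from_fit_table(
    r2_by_beta: dict[int, float], r2_threshold: float = 0.75
) -> tuple[int, bool]:
    """Smallest-qualifying rule on a precomputed {beta: truncated R^2} table."""
    for b in sorted(r2_by_beta):
        if r2_by_beta[b] > r2_threshold:
            return b, False
    return max(r2_by_beta, key=lambda b: (r2_by_beta[b], -b)), True


def tom(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency (unit diagonal)."""
    if isinstance(adj, pd.DataFrame):
        idx, a = adj.index, adj.to_numpy(dtype=float).copy()
    else:
        a = np.asarray(adj, dtype=float).copy()
        idx = pd.RangeIndex(a.shape[0])
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # l_ij: diagonal of a is zero, so u=i and u=j drop out
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    t = (t + t.T) / 2.0  # enforce exact symmetry against float drift
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=idx, columns=idx)
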