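"""Differential-expression signatures and robust batch residualization.

A gene enters a treatment's signature when it jointly satisfies three
criteria against the pooled controls: fold change of group means >= 1.2
or <= 0.83, two-sided t-test p <= 0.05, and absolute difference of group
means >= 10 intensity units.  The union of the per-treatment signatures
is the gene set the co-expression network is built on.

Batch covariates (culture date, processing date, array date and the
like) are removed gene-by-gene by robust (Huber) linear regression on
batch indicators; the residuals are carried forward into the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignatureCriteria",
    "SignatureList",
    "huber_irls",
    "residualize_batches",
    "welch_t",
    "compute_signature",
    "union_signatures",
    "signature_overlap_counts",
]

HUBER_T = 1.345  # 95% Gaussian efficiency tuning constant


@dataclass(frozen=True)
class SignatureCriteria:
    """The three joint DE criteria (fold change, p-value, mean difference)."""

    fc_up: float = 1.2
    fc_down: float = 0.83
    p_max: float = 0.05
    min_abs_diff: float = 10.0
    log2_input: bool = False  # if True, FC = 2^(mean difference of log2 values)

    def __post_init__(self):
        if not self.fc_up > 1:
            raise ValueError("fc_up must exceed 1")
        if not 0 < self.fc_down < 1:
            raise ValueError("fc_down must lie in (0, 1)")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must lie in (0, 1)")
        if self.min_abs_diff < 0:
            raise ValueError("min_abs_diff must be >= 0")


@dataclass
class SignatureList:
    """Per-treatment DE call: full statistics table plus the passing set."""

    treatment: str
    records: pd.DataFrame  # gene_id, fold_change, p_value, mean_diff, direction, passes
    genes: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# robust residualization


def huber_irls(
    X: np.ndarray,
    Y: np.ndarray,
    t: float = HUBER_T,
    max_iter: int = 300,
    tol: float = 1e-13,
) -> tuple[np.ndarray, np.ndarray]:
    """Huber M-estimation by IRLS, vectorized over response columns.

    ``X`` is (n_samples, p); ``Y`` is (n_samples, n_genes).  Starting from
    the OLS fit, iterate weighted least squares with Huber weights
    w = min(1, t*s/|r|) where s is the MAD scale of the residuals
    (median-centred, divided by 0.6745).  Returns (coef (p, n_genes),
    residuals (n_samples, n_genes)).
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    for _ in range(max_iter):
        resid = Y - X @ beta
        scale = np.median(np.abs(resid - np.median(resid, axis=0)), axis=0) / 0.6745
        scale = np.where(scale < 1e-12, 1e-12, scale)
        z = np.abs(resid) / scale
        w = np.where(z <= t, 1.0, t / np.maximum(z, 1e-300))
        # per-column weighted least squares
        new = np.empty_like(beta)
        for j in range(Y.shape[1]):
            sw = np.sqrt(w[:, j])
            new[:, j], *_ = np.linalg.lstsq(X * sw[:, None], Y[:, j] * sw, rcond=None)
        if np.max(np.abs(new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new
            break
        beta = new
    resid = Y - X @ beta
    return beta, resid


def _batch_design(design: pd.DataFrame, batch_cols: list[str]) -> np.ndarray:
    """Intercept + treatment-coded dummies for each categorical covariate."""
    parts = [np.ones((len(design), 1))]
    for col in batch_cols:
        if col not in design.columns:
            raise KeyError(f"design table has no column {col!r}")
        levels = pd.unique(design[col])
        if len(levels) == 1:
            continue  # constant column: absorbed by the intercept
        dummies = pd.get_dummies(design[col], drop_first=True).to_numpy(dtype=float)
        parts.append(dummies)
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"collinear batch design over columns {batch_cols}: "
            "a covariate level is confounded with another"
        )
    return X


def residualize_batches(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    batch_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Replace each gene's values by Huber-regression residuals on batch.

    The model per gene is intercept + indicator terms for every level of
    every covariate in ``batch_cols`` (default: the ``batch`` column).
    Adding a constant to all samples of one batch leaves the residuals
    unchanged, because the shift is absorbed by that batch's coefficient.
    """
    if batch_cols is None:
        batch_cols = ["batch"]
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    X = _batch_design(design, batch_cols)
    _, resid = huber_irls(X, expr.to_numpy().T)
    return pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# t-test and signature calling


def welch_t(group_a, group_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided t-test (Welch by default; pooled with equal_var=True).

    Degenerate convention: if both groups have zero variance, p = 1 when
    the means agree and p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compute_signature(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    treatment: str,
    criteria: SignatureCriteria | None = None,
    control_label: str = "control",
    equal_var: bool = False,
) -> SignatureList:
    """Call one treatment's DE signature against the controls.

    A gene passes iff (FC >= fc_up or FC <= fc_down) and p <= p_max and
    abs(mean_t - mean_c) >= min_abs_diff, with FC = mean_treated /
    mean_control on the linear intensity scale (or 2^(difference of
    log2 means) when the criteria declare log2 input).
    """
    criteria = criteria or SignatureCriteria()
    trt_mask = (design["treatment"] == treatment).to_numpy()
    ctl_mask = (design["treatment"] == control_label).to_numpy()
    if trt_mask.sum() == 0:
        raise KeyError(f"unknown treatment {treatment!r}")
    if trt_mask.sum() < 2 or ctl_mask.sum() < 2:
        raise ValueError("treatment and control groups each need >= 2 samples")

    xt = expr.to_numpy()[:, trt_mask]
    xc = expr.to_numpy()[:, ctl_mask]
    mt, mc = xt.mean(axis=1), xc.mean(axis=1)

    if criteria.log2_input:
        fc = 2.0 ** (mt - mc)
        lin_t, lin_c = 2.0 ** mt, 2.0 ** mc
        diff = lin_t - lin_c
    else:
        if np.any(mc <= 0) or np.any(mt <= 0):
            bad = expr.index[(mc <= 0) | (mt <= 0)][0]
            raise ValueError(f"nonpositive group mean for gene {bad!r}: fold change undefined")
        fc = mt / mc
        diff = mt - mc

    t_stat, p = stats.ttest_ind(xt, xc, axis=1, equal_var=equal_var)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: p=1 on equal means, p=0 otherwise
    degenerate = (xt.var(axis=1, ddof=1) == 0) & (xc.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        p[degenerate] = np.where(mt[degenerate] == mc[degenerate], 1.0, 0.0)

    fc_pass = (fc >= criteria.fc_up) | (fc <= criteria.fc_down)
    passes = fc_pass & (p <= criteria.p_max) & (np.abs(diff) >= criteria.min_abs_diff)
    records = pd.DataFrame(
        {
            "gene_id": expr.index,
            "fold_change": fc,
            "p_value": p,
            "mean_diff": diff,
            "direction": np.where(fc >= criteria.fc_up, "up", "down"),
            "passes": passes,
        }
    )
    genes = set(expr.index[passes])
    return SignatureList(treatment=treatment, records=records, genes=genes)


def union_signatures(signatures: list[SignatureList]) -> set[str]:
    """Union of the passing gene sets across treatments."""
    if not signatures:
        raise ValueError("need at least one signature")
    out: set[str] = set()
    for s in signatures:
        out |= s.genes
    return out


def signature_overlap_counts(signatures: list[SignatureList]) -> pd.DataFrame:
    """Symmetric pairwise overlap table; diagonal holds signature sizes."""
    if len(signatures) < 2:
        raise ValueError("need at least two signatures")
    names = [s.treatment for s in signatures]
    n = len(signatures)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            counts[i, j] = len(signatures[i].genes & signatures[j].genes)
    return pd.DataFrame(counts, index=names, columns=names)
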