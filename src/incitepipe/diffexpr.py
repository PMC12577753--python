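"""Cluster-wise size-factor normalization and a two-part hurdle DE test.

Normalization: within each cluster the size factor is the cell's library
size relative to the cluster mean; clusters are then rescaled by the
median ratio of their mean pseudo-bulk profile to the overall pseudo-bulk
(genes with zero overall sum excluded), and the factors are globally
rescaled to mean 1. Expression is y = ln(1 + a / s_c).

The hurdle test per gene combines a discrete component (logistic
regression of detection on the group indicator plus covariates,
likelihood-ratio against the covariate-only null) and a continuous
component (Gaussian linear model of y over detected cells only, same
contrast). The combined statistic is the sum of the two LR statistics,
referred to a chi-square with one degree of freedom per estimable
component. logFC is the difference of group means of y on the natural-log
scale; detection fractions gate testing (min_pct); Benjamini-Hochberg
adjusts over tested genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DegenerateDataError
from .formats_io import CellByFeatureCounts

# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def compute_size_factors(rna: CellByFeatureCounts, cluster_labels: Sequence) -> np.ndarray:
    """Cluster-wise size factors, globally rescaled to mean 1.

    Every cell must be labeled, every cluster must hold >= 2 cells, and
    all-zero cells are rejected (they belong to QC, not normalization).
    """
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != rna.n_cells:
        raise ConfigError(f"{labels.shape[0]} labels for {rna.n_cells} cells")
    lib = np.asarray(rna.counts.sum(axis=1)).ravel().astype(float)
    if np.any(lib == 0):
        bad = rna.cell_barcodes[int(np.argmax(lib == 0))]
        raise DegenerateDataError(f"cell {bad} has zero total counts; remove it in QC first")
    overall = np.asarray(rna.counts.sum(axis=0)).ravel().astype(float)
    keep = overall > 0
    overall_mean = overall / rna.n_cells
    s = np.empty(rna.n_cells, dtype=float)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            raise DegenerateDataError(f"cluster {lab!r} has {idx.size} cell(s); need >= 2")
        s[idx] = lib[idx] / lib[idx].mean()
        cluster_mean = np.asarray(rna.counts[idx].sum(axis=0)).ravel().astype(float) / idx.size
        ratio = cluster_mean[keep] / overall_mean[keep]
        s[idx] *= float(np.median(ratio))
    s /= s.mean()
    return s


@dataclass
class NormalizedExpression:
    """ln(1 + a/s) expression with the size factors and labels that produced it."""

    y: sp.csr_matrix  # cells x genes, float
    size_factors: np.ndarray
    cell_barcodes: list[str]
    feature_ids: list[str]
    cluster_labels: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)


def normalize(
    rna: CellByFeatureCounts,
    size_factors: np.ndarray,
    cluster_labels: Optional[Sequence] = None,
) -> NormalizedExpression:
    """y = ln(1 + a / s_c); zeros stay zero, so sparsity is preserved."""
    s = np.asarray(size_factors, dtype=float)
    if s.shape[0] != rna.n_cells:
        raise ConfigError("size factors not aligned to cells")
    if np.any(s <= 0):
        raise ConfigError("size factors must be strictly positive")
    scaled = sp.diags(1.0 / s) @ rna.counts.astype(float)
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    return NormalizedExpression(
        y=scaled,
        size_factors=s,
        cell_barcodes=list(rna.cell_barcodes),
        feature_ids=list(rna.feature_ids),
        cluster_labels=None if cluster_labels is None else np.asarray(cluster_labels),
    )


# ---------------------------------------------------------------------------
# Hurdle test
# ---------------------------------------------------------------------------


@dataclass
class DeSettings:
    min_pct: float = 0.01
    logfc_threshold: float = 0.0
    alpha: float = 0.05
    min_cells: int = 20
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pct <= 1.0:
            raise ConfigError("min_pct must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")


def _logistic_loglik(X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 50) -> float:
    """Maximized Bernoulli log-likelihood via ridge-stabilized Newton-Raphson.

    Returns NaN when the iteration fails to produce finite estimates.
    """
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return math.nan
        beta_new = beta + step
        if not np.all(np.isfinite(beta_new)):
            return math.nan
        if np.max(np.abs(step)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    return float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (thin wrapper, NaN-propagating)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def hurdle_de(
    norm: NormalizedExpression,
    group_a: np.ndarray,
    group_b: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    settings: Optional[DeSettings] = None,
) -> pd.DataFrame:
    """Two-part hurdle differential expression between two disjoint cell groups.

    Returns one row per tested gene with columns
    [gene, logFC_ln, pct_A, pct_B, stat, df, p, p_adj, direction].
    Genes whose detection fraction is below ``min_pct`` in both groups are
    excluded. Inestimable components (constant detection, or a continuous
    subset where the contrast cannot be fit) drop out and the remaining
    component is referred to 1 df; genes with no estimable component get
    NaN p-values and are excluded from BH adjustment.
    """
    settings = settings or DeSettings()
    a = np.asarray(group_a, dtype=bool)
    b = np.asarray(group_b, dtype=bool)
    if a.shape[0] != norm.n_cells or b.shape[0] != norm.n_cells:
        raise ConfigError("group masks not aligned to cells")
    if np.any(a & b):
        raise ConfigError("groups overlap")
    na, nb = int(a.sum()), int(b.sum())
    if na < settings.min_cells or nb < settings.min_cells:
        raise DegenerateDataError(
            f"groups need >= {settings.min_cells} cells each (got {na}, {nb})"
        )
    both = a | b
    grp = a[both].astype(float)  # 1 = group A
    n = int(both.sum())
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != norm.n_cells:
            C = C.T
        if C.shape[0] != norm.n_cells:
            raise ConfigError("covariates not aligned to cells")
        C = C[both]
        if not np.all(np.isfinite(C)):
            raise ConfigError("covariate values must be finite")
    ones = np.ones((n, 1))
    X0 = np.hstack([ones, C])
    X1 = np.hstack([ones, grp[:, None], C])

    Y = norm.y.tocsc()[np.flatnonzero(both), :].tocsc()
    amask = grp == 1.0
    bmask = ~amask

    rows = []
    for j, gene in enumerate(norm.feature_ids):
        col = np.asarray(Y[:, j].todense()).ravel()
        det = col > 0
        pct_a = float(det[amask].mean())
        pct_b = float(det[bmask].mean())
        if max(pct_a, pct_b) < settings.min_pct:
            continue
        logfc = float(col[amask].mean() - col[bmask].mean())

        stat, df = 0.0, 0
        # discrete component: detection ~ group + covariates
        if 0 < det.sum() < n:
            ll1 = _logistic_loglik(X1, det.astype(float), settings.ridge)
            ll0 = _logistic_loglik(X0, det.astype(float), settings.ridge)
            if math.isfinite(ll1) and math.isfinite(ll0):
                stat += max(0.0, 2.0 * (ll1 - ll0))
                df += 1
        # continuous component: y ~ group + covariates over detected cells
        di = np.flatnonzero(det)
        if di.size >= X1.shape[1] + 1 and amask[di].any() and bmask[di].any():
            z = col[di]
            rss1 = _ols_rss(X1[di], z)
            rss0 = _ols_rss(X0[di], z)
            if rss1 > 0 and rss0 >= rss1:
                stat += di.size * math.log(rss0 / rss1)
                df += 1
        p = float(stats.chi2.sf(stat, df)) if df > 0 else math.nan
        rows.append(
            {
                "gene": gene,
                "logFC_ln": logfc,
                "pct_A": pct_a,
                "pct_B": pct_b,
                "stat": stat,
                "df": df,
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "logFC_ln", "pct_A", "pct_B", "stat", "df", "p"]
    )
    table["p_adj"] = benjamini_hochberg(table["p"].to_numpy()) if len(table) else []
    table["direction"] = np.where(table["logFC_ln"] > 0, "up", "down") if len(table) else []
    return table


def significant_genes(table: pd.DataFrame, settings: Optional[DeSettings] = None) -> pd.DataFrame:
    """DEG membership: adjusted p < alpha and |logFC| > logfc_threshold."""
    settings = settings or DeSettings()
    return table[
        (table["p_adj"] < settings.alpha)
        & (table["logFC_ln"].abs() > settings.logfc_threshold)
    ]
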