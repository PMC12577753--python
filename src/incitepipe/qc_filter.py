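"""Per-cell quality control and a marker-score contaminant flag.

Cells pass QC when genes detected >= 500, total counts >= 500 and the
mitochondrial transcript proportion <= 0.1 (all boundaries inclusive;
configurable). Contaminating B cells are flagged by a deterministic
marker score — mean ln(1+count) over a small marker list (Cd79a, Cd79b,
Ms4a1 by default) above a cutoff — instead of embedding + clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .formats_io import CellByFeatureCounts

DEFAULT_CONTAMINANT_MARKERS = ("Cd79a", "Cd79b", "Ms4a1")


@dataclass
class QcThresholds:
    min_genes: int = 500
    min_counts: int = 500
    max_mito_fraction: float = 0.1
    contaminant_marker_genes: tuple[str, ...] = DEFAULT_CONTAMINANT_MARKERS
    contaminant_score_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.min_counts <= 0:
            raise ConfigError("min_genes and min_counts must be positive")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must lie in [0, 1]")


def compute_qc_metrics(rna: CellByFeatureCounts, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Total counts, genes detected, and mitochondrial fraction per cell.

    mito_fraction is 0 for cells with zero total counts.
    """
    if rna.modality != "gene":
        raise ConfigError(f"expected gene modality, got {rna.modality!r}")
    counts = rna.counts
    total = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    genes = np.diff(counts.tocsr().indptr)
    mito_cols = [j for j, f in enumerate(rna.feature_ids) if f.startswith(mito_prefix)]
    if mito_cols:
        mito = np.asarray(counts[:, mito_cols].sum(axis=1)).ravel().astype(float)
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "total_counts": total.astype(int),
            "genes_detected": genes.astype(int),
            "mito_fraction": frac,
        },
        index=pd.Index(rna.cell_barcodes, name="barcode"),
    )


def apply_qc(report: pd.DataFrame, thresholds: QcThresholds) -> pd.Series:
    """Boolean pass mask; all three rules must hold (boundaries inclusive)."""
    mask = (
        (report["genes_detected"] >= thresholds.min_genes)
        & (report["total_counts"] >= thresholds.min_counts)
        & (report["mito_fraction"] <= thresholds.max_mito_fraction)
    )
    return mask.rename("pass_qc")


def contaminant_score(rna: CellByFeatureCounts, marker_genes) -> pd.Series:
    """Mean ln(1+count) over the marker genes, per cell."""
    marker_genes = list(marker_genes)
    if not marker_genes:
        raise ConfigError("contaminant marker gene list is empty")
    present = [g for g in marker_genes if g in rna.feature_ids]
    missing = sorted(set(marker_genes) - set(present))
    if missing:
        warnings.warn(f"contaminant markers missing from features (ignored): {missing}")
    if not present:
        raise ConfigError("none of the contaminant marker genes are present in the feature list")
    cols = [rna.feature_ids.index(g) for g in present]
    sub = np.asarray(rna.counts[:, cols].todense(), dtype=float)
    score = np.log1p(sub).mean(axis=1)
    return pd.Series(score, index=pd.Index(rna.cell_barcodes, name="barcode"), name="contaminant_score")


def flag_contaminants(rna: CellByFeatureCounts, marker_genes, cutoff: float) -> pd.Series:
    """Contaminant mask: marker score strictly above the cutoff."""
    score = contaminant_score(rna, marker_genes)
    return (score > cutoff).rename("contaminant")
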