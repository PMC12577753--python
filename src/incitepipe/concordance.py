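"""Cross-modality concordance: sequencing summaries vs. flow cytometry.

For each phospho target, paired per-sample summaries from the two
platforms are compared by simple ordinary-least-squares regression on
two axes: percent positivity (flow percent vs. sequencing percent) and
signal magnitude (flow MFI vs. sequencing mean corrected tag level).
The sequencing summary is the predictor; R^2 — the reported quantity —
is orientation-invariant for simple OLS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .formats_io import FlowSummaryTable


@dataclass
class ConcordanceFit:
    target_id: str
    axis: str  # "percent_positive" | "magnitude"
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def fit_linear(x, y) -> tuple[float, float, float, float]:
    """Least-squares line y = a + b*x; returns (slope, intercept, R^2, p).

    p is the F-test of the slope (equivalently the two-sided t-test) and is
    NaN for n < 3, where it is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError(f"x and y must be 1-D of equal length, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise DegenerateDataError("need at least 2 points")
    if np.ptp(x) == 0:
        raise DegenerateDataError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        # flat response: slope 0, R^2 0 by convention
        slope, intercept, r2 = 0.0, float(y[0]), 0.0
        p = 1.0 if n >= 3 else math.nan
        return slope, intercept, r2, p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue) if n >= 3 else math.nan
    return float(res.slope), float(res.intercept), r2, p


def compare_modalities(
    seq_summary: pd.DataFrame,
    flow: FlowSummaryTable,
    key: str = "group",
    min_pairs: int = 3,
) -> list[ConcordanceFit]:
    """Per-target OLS fits of flow against sequencing summaries.

    ``seq_summary`` needs columns [key, target, percent_positive, mean_level];
    flow rows are matched on (sample_id == seq[key], target_id == seq target).
    Unmatched keys are warned about and dropped; targets with fewer than
    ``min_pairs`` shared samples are skipped with a warning.
    """
    seq = seq_summary.copy()
    if key != "sample_id" and "sample_id" in seq.columns:
        seq = seq.drop(columns=["sample_id"])
    seq = seq.rename(columns={key: "sample_id", "target": "target_id"})
    merged = seq.merge(
        flow.table, on=["sample_id", "target_id"], suffixes=("_seq", "_flow"), how="inner"
    )
    seq_keys = set(zip(seq["sample_id"], seq["target_id"]))
    flow_keys = set(zip(flow.table["sample_id"], flow.table["target_id"]))
    unmatched = seq_keys.symmetric_difference(flow_keys)
    if unmatched:
        warnings.warn(f"{len(unmatched)} unmatched (sample, target) keys dropped: {sorted(unmatched)[:6]}")
    fits: list[ConcordanceFit] = []
    for target, sub in merged.groupby("target_id", sort=True):
        if len(sub) < min_pairs:
            warnings.warn(f"target {target}: only {len(sub)} shared samples (< {min_pairs}); skipped")
            continue
        for axis, xcol, ycol in (
            ("percent_positive", "percent_positive_seq", "percent_positive_flow"),
            ("magnitude", "mean_level", "mfi"),
        ):
            slope, intercept, r2, p = fit_linear(sub[xcol].to_numpy(), sub[ycol].to_numpy())
            fits.append(
                ConcordanceFit(
                    target_id=str(target),
                    axis=axis,
                    n=len(sub),
                    slope=slope,
                    intercept=intercept,
                    r_squared=r2,
                    p_value=p,
                )
            )
    return fits


def fits_to_frame(fits: list[ConcordanceFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(f) for f in fits],
        columns=["target_id", "axis", "n", "slope", "intercept", "r_squared", "p_value"],
    )
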