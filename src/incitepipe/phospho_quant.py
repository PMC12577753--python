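"""Isotype-corrected intracellular antibody quantification and positivity.

Per (culture, condition) group the median raw isotype-control count is
taken over QC-passing singlets of the isotype-bearing panel. For every
phospho target the corrected level is

    v = ln(1 + max(0, a - m_s))

where ``a`` is the raw tag count and ``m_s`` the cell's group median; a
cell is positive when v > 0, i.e. exactly when a > m_s. Cells are then
annotated combinatorially per panel (unphosphorylated / single:<target> /
double) and summarized per sample as percent positivity and mean
corrected level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError
from .formats_io import CellByFeatureCounts
from .hash_demux import SINGLET, SampleDesign

STATE_UNPHOS = "unphosphorylated"
STATE_DOUBLE = "double"


def analysis_mask(annotations: pd.DataFrame) -> pd.Series:
    """QC-passing, non-contaminant singlets — the cells every summary is computed over."""
    mask = (annotations["status"] == SINGLET) & annotations["pass_qc"].astype(bool)
    if "contaminant" in annotations.columns:
        mask &= ~annotations["contaminant"].astype(bool)
    return mask


@dataclass
class AdtQuant:
    """Long-format per-(cell, target) corrected levels plus the group medians used."""

    table: pd.DataFrame  # columns: barcode, target, raw, corrected, positive, panel, group
    medians: dict = field(default_factory=dict)  # (culture, condition) -> median isotype count


def compute_isotype_medians(
    adt: CellByFeatureCounts,
    annotations: pd.DataFrame,
    design: SampleDesign,
) -> dict:
    """Median raw isotype count per (culture, condition) group.

    Medians are taken over QC-passing singlets of the isotype-bearing
    panel(s); even-sized groups use the mean-of-middle-values convention
    (numpy median). Every group present among analysis cells must contain
    at least one isotype-bearing cell.
    """
    iso_panels = design.isotype_panels
    if not iso_panels:
        raise ConfigError("no panel declares an isotype antibody")
    iso_features = {design.panels[p].isotype for p in iso_panels}
    for f in iso_features:
        if f not in adt.feature_ids:
            raise ConfigError(f"isotype feature {f!r} missing from ADT matrix")
    ann = annotations.loc[analysis_mask(annotations)]
    groups = sorted(set(zip(ann["culture"], ann["condition"])))
    if not groups:
        raise DegenerateDataError("no QC-passing singlets to compute isotype medians from")
    iso_counts = {f: pd.Series(adt.feature_column(f), index=adt.cell_barcodes) for f in iso_features}
    medians: dict = {}
    for culture, condition in groups:
        sel = ann[
            (ann["culture"] == culture)
            & (ann["condition"] == condition)
            & (ann["panel"].isin(iso_panels))
        ]
        if sel.empty:
            raise DegenerateDataError(
                f"group ({culture}, {condition}): no isotype-bearing cells for the median"
            )
        vals = np.concatenate(
            [iso_counts[design.panels[p].isotype].loc[sel.index[sel["panel"] == p]].to_numpy()
             for p in iso_panels if (sel["panel"] == p).any()]
        )
        medians[(culture, condition)] = float(np.median(vals))
    return medians


def correct_and_call(
    adt: CellByFeatureCounts,
    medians: dict,
    design: SampleDesign,
    annotations: pd.DataFrame,
) -> AdtQuant:
    """Median-subtract, clip at 0, ln+1 transform, and call positivity per cell x target.

    The isotype channel itself is excluded from the output. Each analysis
    cell is scored only for the phospho targets of its own panel.
    """
    ann = annotations.loc[analysis_mask(annotations)]
    target_counts = {}
    for panel, spec in design.panels.items():
        for t in spec.phospho_targets:
            if t not in adt.feature_ids:
                raise ConfigError(f"panel {panel} target {t!r} absent from ADT features")
            if t not in target_counts:
                target_counts[t] = pd.Series(adt.feature_column(t), index=adt.cell_barcodes)
    frames = []
    for panel, spec in design.panels.items():
        cells = ann[ann["panel"] == panel]
        if cells.empty:
            continue
        key = list(zip(cells["culture"], cells["condition"]))
        missing = sorted({k for k in key if k not in medians})
        if missing:
            raise ConfigError(f"no isotype median for groups {missing}")
        m = np.array([medians[k] for k in key], dtype=float)
        for t in spec.phospho_targets:
            raw = target_counts[t].loc[cells.index].to_numpy(dtype=float)
            corrected = np.log1p(np.clip(raw - m, 0.0, None))
            frames.append(
                pd.DataFrame(
                    {
                        "barcode": cells.index,
                        "target": t,
                        "raw": raw.astype(int),
                        "corrected": corrected,
                        "positive": corrected > 0,
                        "panel": panel,
                        "sample_id": cells["sample_id"].to_numpy(),
                        "group": cells["group"].to_numpy(),
                    }
                )
            )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["barcode", "target", "raw", "corrected", "positive", "panel", "sample_id", "group"]
        )
    )
    table = table.sort_values(["target", "barcode"], kind="stable").reset_index(drop=True)
    return AdtQuant(table=table, medians=dict(medians))


def annotate_phospho_states(quant: AdtQuant, design: SampleDesign) -> pd.DataFrame:
    """Combinatorial per-cell state from the panel's two positivity flags.

    Both targets positive -> "double"; exactly one -> "single:<target>";
    neither -> "unphosphorylated". Defined only for 2-target panels.
    """
    for panel, spec in design.panels.items():
        if len(spec.phospho_targets) != 2:
            raise ConfigError(
                f"panel {panel} has {len(spec.phospho_targets)} phospho targets; "
                "the combinatorial scheme is defined for pairs"
            )
    if quant.table.empty:
        return pd.DataFrame(columns=["panel", "state"], index=pd.Index([], name="barcode"))
    pos = quant.table.pivot_table(
        index="barcode", columns="target", values="positive", aggfunc="first"
    )
    panel_of = quant.table.drop_duplicates("barcode").set_index("barcode")["panel"]
    states = {}
    for barcode, panel in panel_of.items():
        t1, t2 = design.panels[panel].phospho_targets
        p1 = bool(pos.at[barcode, t1]) if t1 in pos.columns and pd.notna(pos.at[barcode, t1]) else False
        p2 = bool(pos.at[barcode, t2]) if t2 in pos.columns and pd.notna(pos.at[barcode, t2]) else False
        if p1 and p2:
            state = STATE_DOUBLE
        elif p1:
            state = f"single:{t1}"
        elif p2:
            state = f"single:{t2}"
        else:
            state = STATE_UNPHOS
        states[barcode] = (panel, state)
    out = pd.DataFrame.from_dict(states, orient="index", columns=["panel", "state"])
    out.index.name = "barcode"
    return out.sort_index()


def summarize_per_sample(quant: AdtQuant, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percent positivity and mean corrected level per (sample, target).

    Denominators are the QC-passing singlets of the sample (the rows of
    ``quant.table``). Empty samples are excluded with a warning upstream.
    """
    if quant.table.empty:
        warnings.warn("no cells to summarize")
        return pd.DataFrame(
            columns=["sample_id", "group", "target", "percent_positive", "mean_level", "n_cells"]
        )
    grouped = quant.table.groupby(["sample_id", "group", "target"], sort=True)
    out = grouped.agg(
        percent_positive=("positive", lambda s: 100.0 * s.mean()),
        mean_level=("corrected", "mean"),
        n_cells=("positive", "size"),
    ).reset_index()
    return out
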