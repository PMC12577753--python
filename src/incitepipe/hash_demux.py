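"""Hashtag (HTO) demultiplexing with explicit doublet and unassigned rules.

Each sample in the hashing design carries two hashtags: one of two
condition hashes (stimulated / unstimulated) and one of six identity
hashes encoding (culture, antibody panel). A cell is

* a **doublet** if it is positive for >= 2 identity hashes, or for both
  condition hashes;
* **unassigned** if it lacks a positive identity hash or a positive
  condition hash;
* otherwise a **singlet** assigned to the sample composed from its unique
  positive condition hash and unique positive identity hash.

Positivity is count >= cutoff (inclusive). Cutoffs are estimated per
hashtag on ln(1+count) — a reproducible stand-in for visual histogram
gating — and any cutoff may be overridden manually.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDataError
from .formats_io import CellByFeatureCounts

UNSTIM = "unstimulated"
STIM = "stimulated"

PSTAT3 = "p-STAT3"
PP65 = "p-p65"
PERK = "p-ERK1/2"
PFOS = "p-FOS"
ISOTYPE = "isotype"
ALL_TARGETS = (PSTAT3, PP65, PERK, PFOS)


@dataclass(frozen=True)
class PanelSpec:
    """Antibody content of one staining panel: its phospho targets and optional isotype."""

    phospho_targets: tuple[str, ...]
    isotype: Optional[str] = None


@dataclass
class SampleDesign:
    """The hashing scheme: hashtags -> condition or (culture, panel), plus panel contents."""

    condition_hashes: dict[str, str]
    identity_hashes: dict[str, tuple[str, str]]  # hashtag -> (culture, panel)
    panels: dict[str, PanelSpec]

    def __post_init__(self) -> None:
        overlap = set(self.condition_hashes) & set(self.identity_hashes)
        if overlap:
            raise ConfigError(f"hashtags {sorted(overlap)} appear as both condition and identity hashes")
        for tag, (_, panel) in self.identity_hashes.items():
            if panel not in self.panels:
                raise ConfigError(f"identity hash {tag} maps to undeclared panel {panel!r}")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition_hashes.values():
            seen.setdefault(c)
        return list(seen)

    @property
    def all_hashtags(self) -> list[str]:
        return list(self.condition_hashes) + list(self.identity_hashes)

    @property
    def isotype_panels(self) -> list[str]:
        return [p for p, spec in self.panels.items() if spec.isotype is not None]

    @staticmethod
    def sample_id(culture: str, condition: str, panel: str) -> str:
        return f"{culture}_{condition}_{panel}"

    @staticmethod
    def group_id(culture: str, condition: str) -> str:
        """Culture x condition group, the unit of isotype-median correction and flow pairing."""
        return f"{culture}_{condition}"

    def panel_of_target(self, target: str) -> str:
        for panel, spec in self.panels.items():
            if target in spec.phospho_targets:
                return panel
        raise ConfigError(f"target {target!r} not declared in any panel")

    @property
    def all_targets(self) -> list[str]:
        out: list[str] = []
        for spec in self.panels.values():
            out.extend(spec.phospho_targets)
        return out


def default_design() -> SampleDesign:
    """The 12-sample Th17 hashing scheme: 2 conditions x 3 cultures x 2 panels."""
    return SampleDesign(
        condition_hashes={"Hashtag1": UNSTIM, "Hashtag2": STIM},
        identity_hashes={
            "Hashtag3": ("A", "panel1"),
            "Hashtag4": ("B", "panel1"),
            "Hashtag5": ("C", "panel1"),
            "Hashtag6": ("A", "panel2"),
            "Hashtag7": ("B", "panel2"),
            "Hashtag8": ("C", "panel2"),
        },
        panels={
            "panel1": PanelSpec(phospho_targets=(PSTAT3, PP65), isotype=ISOTYPE),
            "panel2": PanelSpec(phospho_targets=(PERK, PFOS), isotype=None),
        },
    )


def enumerate_valid_samples(design: SampleDesign) -> list[str]:
    """Cartesian product of condition labels and identity-hash labels, in design order."""
    out: list[str] = []
    for condition, (culture, panel) in itertools.product(
        design.conditions, design.identity_hashes.values()
    ):
        sid = SampleDesign.sample_id(culture, condition, panel)
        if sid not in out:
            out.append(sid)
    return out


# ---------------------------------------------------------------------------
# Cutoff estimation
# ---------------------------------------------------------------------------


def _two_means_split(logx: np.ndarray) -> float:
    """1-D two-means on ln(1+count); returns the midpoint of the class centers."""
    lo, hi = float(logx.min()), float(logx.max())
    centers = np.array([lo, hi])
    for _ in range(200):
        assign = np.abs(logx[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array(
            [logx[assign == k].mean() if np.any(assign == k) else centers[k] for k in (0, 1)]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return float(centers.mean())


def _otsu_split(logx: np.ndarray, bins: int = 256) -> float:
    hist, edges = np.histogram(logx, bins=bins)
    mids = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(float)
    total = w.sum()
    best, best_t = -1.0, mids[0]
    csum = np.cumsum(w)
    cmean = np.cumsum(w * mids)
    mu_total = cmean[-1] / total
    for i in range(len(mids) - 1):
        w0 = csum[i]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cmean[i] / w0
        mu1 = (cmean[-1] - cmean[i]) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
        if var_between > best:
            best, best_t = var_between, (mids[i] + mids[i + 1]) / 2
    _ = mu_total
    return float(best_t)


def estimate_hash_cutoffs(
    hto: CellByFeatureCounts,
    method: str = "twomeans",
    manual: Optional[Mapping[str, float]] = None,
    quantile: float = 0.95,
) -> dict[str, float]:
    """One positive-count threshold per hashtag (cells with count >= cutoff are positive).

    Manual entries override estimates verbatim. A constant hashtag column
    without a manual override is a degenerate distribution and an error.
    """
    if hto.modality != "hashtag":
        raise ConfigError(f"expected hashtag modality, got {hto.modality!r}")
    manual = dict(manual or {})
    cutoffs: dict[str, float] = {}
    for j, tag in enumerate(hto.feature_ids):
        if tag in manual:
            cutoffs[tag] = float(manual[tag])
            continue
        col = np.asarray(hto.counts[:, j].todense()).ravel()
        if col.size == 0 or col.max() == col.min():
            raise DegenerateDataError(
                f"hashtag {tag}: constant count distribution; supply a manual cutoff"
            )
        logx = np.log1p(col.astype(float))
        if method == "twomeans":
            t = _two_means_split(logx)
        elif method == "otsu":
            t = _otsu_split(logx)
        elif method == "quantile":
            t = float(np.quantile(logx, quantile))
        else:
            raise ConfigError(f"unknown cutoff method {method!r}")
        cutoffs[tag] = float(np.expm1(t))
    for tag, val in manual.items():
        cutoffs.setdefault(tag, float(val))
    return cutoffs


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

SINGLET = "singlet"
DOUBLET = "doublet"
UNASSIGNED = "unassigned"


@dataclass
class DemuxResult:
    """Per-cell demultiplexing calls plus the cutoffs used."""

    calls: pd.DataFrame  # index: barcode; columns: status, sample_id, condition, culture, panel, group
    cutoffs: dict[str, float] = field(default_factory=dict)

    @property
    def tallies(self) -> dict[str, int]:
        t = {s: 0 for s in (SINGLET, DOUBLET, UNASSIGNED)}
        t.update(self.calls["status"].value_counts().to_dict())
        return t


def classify_cells(
    hto: CellByFeatureCounts,
    cutoffs: Mapping[str, float],
    design: SampleDesign,
) -> DemuxResult:
    """Apply the doublet / unassigned / singlet rules to every cell."""
    unknown = [t for t in hto.feature_ids if t not in design.condition_hashes and t not in design.identity_hashes]
    if unknown:
        raise ConfigError(f"hashtags present in counts but absent from design: {unknown}")
    missing_cut = [t for t in design.all_hashtags if t not in cutoffs]
    if missing_cut:
        raise ConfigError(f"no cutoff supplied for design hashtags: {missing_cut}")
    missing_col = [t for t in design.all_hashtags if t not in hto.feature_ids]
    if missing_col:
        raise ConfigError(f"design hashtags missing from count matrix: {missing_col}")

    n = hto.n_cells
    cond_tags = list(design.condition_hashes)
    id_tags = list(design.identity_hashes)
    dense = hto.to_dense().astype(float)
    col = {t: hto.feature_ids.index(t) for t in design.all_hashtags}
    pos = {t: dense[:, col[t]] >= float(cutoffs[t]) for t in design.all_hashtags}

    n_cond = np.sum([pos[t] for t in cond_tags], axis=0) if cond_tags else np.zeros(n, dtype=int)
    n_id = np.sum([pos[t] for t in id_tags], axis=0) if id_tags else np.zeros(n, dtype=int)

    doublet = (n_id >= 2) | (n_cond >= 2)
    unassigned = ~doublet & ((n_id == 0) | (n_cond == 0))
    singlet = ~doublet & ~unassigned

    status = np.where(doublet, DOUBLET, np.where(unassigned, UNASSIGNED, SINGLET))
    condition = np.full(n, "", dtype=object)
    culture = np.full(n, "", dtype=object)
    panel = np.full(n, "", dtype=object)
    for t in cond_tags:
        sel = singlet & pos[t]
        condition[sel] = design.condition_hashes[t]
    for t in id_tags:
        sel = singlet & pos[t]
        cu, pa = design.identity_hashes[t]
        culture[sel] = cu
        panel[sel] = pa
    sample_id = np.where(
        singlet,
        [SampleDesign.sample_id(cu, co, pa) if s else "" for cu, co, pa, s in zip(culture, condition, panel, singlet)],
        "",
    )
    group = np.where(singlet, [SampleDesign.group_id(cu, co) if s else "" for cu, co, s in zip(culture, condition, singlet)], "")

    calls = pd.DataFrame(
        {
            "status": status,
            "sample_id": sample_id,
            "condition": condition,
            "culture": culture,
            "panel": panel,
            "group": group,
            "n_condition_pos": n_cond.astype(int),
            "n_identity_pos": n_id.astype(int),
        },
        index=pd.Index(hto.cell_barcodes, name="barcode"),
    )
    return DemuxResult(calls=calls, cutoffs=dict(cutoffs))
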