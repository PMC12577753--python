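"""Multimodal synthetic data generator with full ground truth.

Emulates a hashed Th17 stimulation experiment: 12 samples
(2 conditions x 3 cultures x 2 antibody panels) pooled into one lane,
three count modalities sharing a cell-barcode axis — RNA, antibody tags
(phospho + isotype), hashtags — plus per-cell truth (sample, doublet,
contaminant, phospho states) so every downstream stage is testable.

Count model: negative binomial throughout (gamma-Poisson draws), with
per-gene abundances from a lognormal profile whose spread is calibrated
at construction time so the expected detected-genes-per-cell matches the
configured target. Phospho-state-coupled gene programs shift member-gene
means on the natural-log scale. Doublets are element-wise sums of two
independently drawn singlet profiles from distinct samples (hash-
detectable by construction); a configurable fraction of cells is a
contaminant population expressing B-cell markers and no phospho signal.
Mitochondrial genes (prefix "mt-") receive a Beta-distributed share of
each cell's counts.

All randomness flows from one root seed through named substreams;
identical configuration implies bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .errors import ConfigError, DegenerateDataError
from .formats_io import CellByFeatureCounts, FlowSummaryTable, write_counts_dir
from .hash_demux import (
    PERK,
    PFOS,
    PP65,
    PSTAT3,
    STIM,
    UNSTIM,
    SampleDesign,
    default_design,
    enumerate_valid_samples,
)

# Named substreams off the root seed (spawn keys).
STREAM_STRUCTURE = 0  # doublet flags (first draw), partners, contaminants, phospho states
STREAM_RNA = 1
STREAM_ADT = 2
STREAM_HTO = 3
STREAM_MITO = 4
STREAM_FLOW = 5


def substream(seed: int, tag: int) -> np.random.Generator:
    """Deterministic named child stream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


# Activity predicates a program may bind to (evaluated on per-cell truth).
PROGRAM_STATES = ("resting", "activation", "proliferation", "lipid", "contaminant")


@dataclass(frozen=True)
class GeneProgram:
    """A named gene list with one natural-log fold effect, tied to a truth state."""

    name: str
    genes: tuple[str, ...]
    log_fold: float
    active_when: str

    def __post_init__(self) -> None:
        if self.active_when not in PROGRAM_STATES:
            raise ConfigError(
                f"program {self.name!r}: unknown state {self.active_when!r}; "
                f"expected one of {PROGRAM_STATES}"
            )


def default_gene_programs() -> dict[str, GeneProgram]:
    return {
        "resting": GeneProgram(
            "resting", ("Tcf7", "Ccr7", "Sell", "Lef1"), 1.2, "resting"
        ),
        "activation": GeneProgram(
            "activation",
            ("Il2", "Il17a", "Il17f", "Tnf", "Cd69", "Cd40lg", "Jak2", "Rela", "Nfkb1", "Il21", "Mir155hg"),
            1.5,
            "activation",
        ),
        "proliferation": GeneProgram(
            "proliferation", ("Mki67", "Top2a", "Cdk1", "Cdk4", "Cenpf"), 1.2, "proliferation"
        ),
        "lipid": GeneProgram(
            "lipid", ("Scd2", "Fasn", "Dgat1", "Fabp5", "Acot7"), 1.0, "lipid"
        ),
        "contaminant": GeneProgram(
            "contaminant", ("Cd79a", "Cd79b", "Ms4a1"), 5.0, "contaminant"
        ),
    }


MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


def default_positive_fractions(design: Optional[SampleDesign] = None) -> dict:
    """(sample_id, target) -> truth-positive fraction; condition-dependent, culture-shared.

    p-FOS uses the measured 5.42% -> 86.4% stimulation shift; the other
    targets follow the qualitative pattern of the experiment (large shift
    for p-ERK1/2, modest for p-p65, high and stable for p-STAT3).
    """
    design = design or default_design()
    per_condition = {
        PFOS: {UNSTIM: 0.0542, STIM: 0.864},
        PERK: {UNSTIM: 0.08, STIM: 0.78},
        PP65: {UNSTIM: 0.22, STIM: 0.41},
        PSTAT3: {UNSTIM: 0.62, STIM: 0.68},
    }
    out: dict = {}
    for condition, (culture, panel) in (
        (c, ih) for c in design.conditions for ih in design.identity_hashes.values()
    ):
        sid = SampleDesign.sample_id(culture, condition, panel)
        for target in design.panels[panel].phospho_targets:
            if target in per_condition:
                out[(sid, target)] = per_condition[target][condition]
            else:
                out[(sid, target)] = 0.3 if condition == STIM else 0.1
    return out


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic experiment (defaults mirror the real one)."""

    n_cells_per_sample: int = 200
    design: SampleDesign = field(default_factory=default_design)
    gene_programs: dict = field(default_factory=default_gene_programs)
    n_genes: int = 10_000
    mean_genes_per_cell: float = 3026.0
    mean_counts_per_cell: float = 6644.0
    counts_cv_log_sd: float = 0.45  # lognormal sd of per-cell library size
    dispersion: float = 2.0  # NB shape for genes
    isotype_background_mean: float = 4.0
    phospho_background_mean: float = 0.5  # nonspecific floor of the phospho channels
    phospho_signal_mean: float = 60.0
    adt_dispersion: float = 8.0
    adt_ambient_rate: float = 0.25  # off-panel channels
    positive_fraction: dict = field(default_factory=default_positive_fractions)
    doublet_rate: float = 0.08
    ambient_hash_rate: float = 2.0
    hash_signal_mean: float = 200.0
    hash_dispersion: float = 10.0
    contaminant_fraction: float = 0.07
    mito_fraction_mean: float = 0.05
    mito_concentration: float = 30.0
    mito_prefix: str = "mt-"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("doublet_rate", "contaminant_fraction", "mito_fraction_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "mean_genes_per_cell", "mean_counts_per_cell", "dispersion",
            "isotype_background_mean", "phospho_background_mean", "phospho_signal_mean",
            "adt_dispersion", "ambient_hash_rate", "hash_signal_mean", "hash_dispersion",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.n_cells_per_sample < 0 or self.n_genes <= 0:
            raise ConfigError("n_cells_per_sample must be >= 0 and n_genes positive")
        for key, frac in self.positive_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"positive_fraction{key} must lie in [0, 1]")
        # overlapping programs must declare the same effect to be compatible
        effect: dict[str, float] = {}
        for prog in self.gene_programs.values():
            for g in prog.genes:
                if g in effect and effect[g] != prog.log_fold:
                    raise ConfigError(
                        f"gene {g!r} appears in overlapping programs with incompatible "
                        f"log-fold effects ({effect[g]} vs {prog.log_fold})"
                    )
                effect[g] = prog.log_fold


@dataclass
class SyntheticTruth:
    """Ground truth: one row per generated barcode plus the config that produced it."""

    cells: pd.DataFrame
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if self.cells.index.has_duplicates:
            raise ConfigError("duplicate barcodes in truth")

    def __len__(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# Gene universe and abundance calibration
# ---------------------------------------------------------------------------


def _gene_universe(config: GeneratorConfig) -> list[str]:
    named: list[str] = []
    for prog in config.gene_programs.values():
        for g in prog.genes:
            if g not in named:
                named.append(g)
    mito = [g for g in MITO_GENES if g.startswith(config.mito_prefix)] or list(MITO_GENES)
    n_filler = config.n_genes - len(named) - len(mito)
    if n_filler < 0:
        raise ConfigError(
            f"n_genes={config.n_genes} smaller than program + mitochondrial gene count"
        )
    filler = [f"Gene{i:05d}" for i in range(n_filler)]
    return named + filler + mito


def _calibrate_profile(
    config: GeneratorConfig, rng: np.random.Generator, n_nonmito: int, n_mito: int
) -> np.ndarray:
    """Relative abundance profile for non-mito genes.

    A standard-normal draw z is scaled by sigma, exponentiated, and
    normalized; sigma is root-found so the expected detected genes per
    cell (averaged over the library-size distribution) hits the target.
    """
    z = rng.standard_normal(n_nonmito)
    r = config.dispersion
    mu_log = math.log(config.mean_counts_per_cell) - config.counts_cv_log_sd**2 / 2
    # quantile grid of the lognormal library-size distribution
    q = np.linspace(0.02, 0.98, 25)
    t_grid = np.exp(mu_log + config.counts_cv_log_sd * np.sqrt(2) * _erfinv(2 * q - 1))
    t_nonmito = t_grid * (1.0 - config.mito_fraction_mean)

    def expected_detected(sigma: float) -> float:
        w = np.exp(sigma * z)
        p = w / w.sum()
        lam = np.outer(t_nonmito, p)  # grid x genes
        pdet = 1.0 - (r / (r + lam)) ** r
        return float(pdet.sum(axis=1).mean()) + n_mito

    target = config.mean_genes_per_cell

    def f(sigma: float) -> float:
        return expected_detected(sigma) - target

    lo, hi = 0.01, 6.0
    flo, fhi = f(lo), f(hi)
    if flo <= 0:  # even a flat profile detects too few genes: use the flattest
        sigma = lo
    elif fhi >= 0:  # even extreme skew detects too many: use the most skewed
        sigma = hi
    else:
        sigma = brentq(f, lo, hi, xtol=1e-4)
    w = np.exp(sigma * z)
    return w / w.sum()


def _erfinv(x: np.ndarray) -> np.ndarray:
    from scipy.special import erfinv

    return erfinv(x)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw, elementwise mean."""
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) / shape)
    return rng.poisson(lam)


def _program_activity(prog: GeneProgram, pos: dict[str, np.ndarray], contaminant: np.ndarray) -> np.ndarray:
    """Boolean activity per cell for one program's state predicate."""
    n = contaminant.shape[0]
    any_pos = np.zeros(n, dtype=bool)
    for v in pos.values():
        any_pos |= v
    if prog.active_when == "resting":
        return ~any_pos & ~contaminant
    if prog.active_when == "activation":
        return (pos.get(PERK, np.zeros(n, bool)) | pos.get(PFOS, np.zeros(n, bool))) & ~contaminant
    if prog.active_when == "proliferation":
        return pos.get(PSTAT3, np.zeros(n, bool)) & pos.get(PP65, np.zeros(n, bool)) & ~contaminant
    if prog.active_when == "lipid":
        return pos.get(PSTAT3, np.zeros(n, bool)) & ~contaminant
    return contaminant.copy()  # "contaminant"


def _empty_dataset(config: GeneratorConfig):
    genes = _gene_universe(config)
    adt_features = list(dict.fromkeys(config.design.all_targets)) + [
        config.design.panels[p].isotype for p in config.design.isotype_panels
    ]
    hto_features = config.design.all_hashtags
    empty = lambda feats, modality: CellByFeatureCounts(
        [], feats, sp.csr_matrix((0, len(feats)), dtype=np.int64), modality
    )
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            columns=["sample_id", "condition", "culture", "panel", "group",
                     "is_doublet", "partner_sample", "is_contaminant", "cluster"]
            + [f"pos_{t}" for t in config.design.all_targets],
            index=pd.Index([], name="barcode"),
        ),
        config=config,
    )
    return empty(genes, "gene"), empty(adt_features, "adt"), empty(hto_features, "hashtag"), truth


def generate_dataset(
    config: GeneratorConfig, _return_components: bool = False
):
    """Generate (rna, adt, hto, truth) sharing one barcode axis.

    With ``_return_components=True`` additionally returns, per modality,
    the primary and partner count matrices whose element-wise sum is the
    output (partner rows are nonzero only for doublets) — a hook for
    conservation checks.
    """
    design = config.design
    samples = enumerate_valid_samples(design)
    if not samples:
        raise ConfigError("design declares zero samples")
    n_total = config.n_cells_per_sample * len(samples)
    if n_total == 0:
        out = _empty_dataset(config)
        return (*out, None) if _return_components else out

    sample_meta = {}
    for condition in design.conditions:
        for culture, panel in design.identity_hashes.values():
            sid = SampleDesign.sample_id(culture, condition, panel)
            sample_meta[sid] = (condition, culture, panel)

    sample_idx = np.repeat(np.arange(len(samples)), config.n_cells_per_sample)
    barcodes = [f"BC{i:06d}" for i in range(n_total)]

    # --- structure stream: doublets first (documented draw order) ---------
    rs = substream(config.seed, STREAM_STRUCTURE)
    is_doublet = rs.random(n_total) < config.doublet_rate
    n_doub = int(is_doublet.sum())
    partner_offset = rs.integers(1, max(len(samples), 2), size=n_doub) if n_doub else np.array([], dtype=int)
    if len(samples) == 1:
        is_doublet[:] = False  # cross-sample doublets impossible
        n_doub, partner_offset = 0, np.array([], dtype=int)
    partner_sample_idx = (sample_idx[is_doublet] + partner_offset) % len(samples)
    is_contaminant = (rs.random(n_total) < config.contaminant_fraction) & ~is_doublet

    all_targets = list(dict.fromkeys(design.all_targets))

    def draw_states(s_idx: np.ndarray, contaminant: np.ndarray) -> dict[str, np.ndarray]:
        """Per-target truth positivity for a vector of cells (by sample index)."""
        n = s_idx.shape[0]
        pos = {}
        for t in all_targets:  # fixed target order for reproducibility
            u = rs.random(n)
            frac = np.array(
                [config.positive_fraction.get((samples[i], t), 0.0) for i in s_idx],
                dtype=float,
            )
            on_panel = np.array(
                [t in design.panels[sample_meta[samples[i]][2]].phospho_targets for i in s_idx],
                dtype=bool,
            )
            pos[t] = (u < frac) & on_panel & ~contaminant
        return pos

    pos_primary = draw_states(sample_idx, is_contaminant)
    pos_partner = draw_states(partner_sample_idx, np.zeros(n_doub, dtype=bool))

    # --- extended cell list: primaries then doublet partners --------------
    ext_sample_idx = np.concatenate([sample_idx, partner_sample_idx])
    ext_contaminant = np.concatenate([is_contaminant, np.zeros(n_doub, dtype=bool)])
    ext_pos = {
        t: np.concatenate([pos_primary[t], pos_partner[t]]) for t in all_targets
    }
    n_ext = n_total + n_doub
    ext_panel = np.array([sample_meta[samples[i]][2] for i in ext_sample_idx])

    genes = _gene_universe(config)
    mito_idx = np.array([j for j, g in enumerate(genes) if g.startswith(config.mito_prefix)])
    nonmito_idx = np.array([j for j in range(len(genes)) if j not in set(mito_idx)])
    gene_col = {g: j for j, g in enumerate(genes)}

    # --- RNA ---------------------------------------------------------------
    rr = substream(config.seed, STREAM_RNA)
    base_profile = _calibrate_profile(config, rr, nonmito_idx.size, mito_idx.size)
    # program genes get controlled baselines: the mean abundance, except
    # lineage-marker (contaminant) genes which are near-silent off-state
    nonmito_lookup = {g: k for k, g in enumerate(np.array(genes)[nonmito_idx])}
    w_mean = 1.0 / nonmito_idx.size
    for prog in config.gene_programs.values():
        rel = 0.05 if prog.active_when == "contaminant" else 1.0
        for g in prog.genes:
            if g in nonmito_lookup:
                base_profile[nonmito_lookup[g]] = w_mean * rel
    base_profile /= base_profile.sum()
    mu_log = math.log(config.mean_counts_per_cell) - config.counts_cv_log_sd**2 / 2
    libsize = rr.lognormal(mean=mu_log, sigma=config.counts_cv_log_sd, size=n_ext)

    rm = substream(config.seed, STREAM_MITO)
    m0, conc = config.mito_fraction_mean, config.mito_concentration
    if m0 in (0.0, 1.0):
        mito_frac = np.full(n_ext, m0)
    else:
        mito_frac = rm.beta(m0 * conc, (1 - m0) * conc, size=n_ext)

    # per-cell effect multiplier on member genes (natural-log fold)
    activity = {
        name: _program_activity(prog, ext_pos, ext_contaminant)
        for name, prog in config.gene_programs.items()
    }

    chunks = []
    chunk_size = 256
    r = config.dispersion
    nonmito_profile = base_profile  # over nonmito_idx, sums to 1
    nonmito_pos = {g: k for k, g in enumerate(np.array(genes)[nonmito_idx])}
    program_cols = {
        name: [nonmito_pos[g] for g in prog.genes if g in nonmito_pos]
        for name, prog in config.gene_programs.items()
    }
    for start in range(0, n_ext, chunk_size):
        stop = min(start + chunk_size, n_ext)
        nc = stop - start
        prof = np.tile(nonmito_profile, (nc, 1))
        for name, prog in config.gene_programs.items():
            act = activity[name][start:stop]
            cols = program_cols[name]
            if not act.any() or not cols:
                continue
            prof[np.ix_(np.flatnonzero(act), cols)] *= math.exp(prog.log_fold)
        prof /= prof.sum(axis=1, keepdims=True)
        t_nm = libsize[start:stop] * (1.0 - mito_frac[start:stop])
        lam = np.zeros((nc, len(genes)))
        lam[:, nonmito_idx] = prof * t_nm[:, None]
        lam[:, mito_idx] = (libsize[start:stop] * mito_frac[start:stop] / mito_idx.size)[:, None]
        counts = _nb_draw(rr, lam, r)
        chunks.append(sp.csr_matrix(counts))
    rna_ext = sp.vstack(chunks, format="csr").astype(np.int64)

    # --- ADT ---------------------------------------------------------------
    ra = substream(config.seed, STREAM_ADT)
    iso_features = [design.panels[p].isotype for p in design.isotype_panels]
    adt_features = all_targets + iso_features
    adt_mean = np.full((n_ext, len(adt_features)), config.adt_ambient_rate)
    for j, t in enumerate(all_targets):
        on_panel = np.array([t in design.panels[p].phospho_targets for p in ext_panel])
        adt_mean[on_panel, j] = config.phospho_background_mean
        adt_mean[ext_pos[t], j] += config.phospho_signal_mean
    for k, p in enumerate(design.isotype_panels):
        j = len(all_targets) + iso_features.index(design.panels[p].isotype)
        adt_mean[ext_panel == p, j] = config.isotype_background_mean
    adt_ext = sp.csr_matrix(_nb_draw(ra, adt_mean, config.adt_dispersion)).astype(np.int64)

    # --- HTO ---------------------------------------------------------------
    rh = substream(config.seed, STREAM_HTO)
    hto_features = design.all_hashtags
    hto_mean = np.full((n_ext, len(hto_features)), config.ambient_hash_rate)
    cond_hash = {v: k for k, v in design.condition_hashes.items()}
    id_hash = {v: k for k, v in design.identity_hashes.items()}
    for i in range(n_ext):
        condition, culture, panel = sample_meta[samples[ext_sample_idx[i]]]
        hto_mean[i, hto_features.index(cond_hash[condition])] = config.hash_signal_mean
        hto_mean[i, hto_features.index(id_hash[(culture, panel)])] = config.hash_signal_mean
    hto_ext = sp.csr_matrix(_nb_draw(rh, hto_mean, config.hash_dispersion)).astype(np.int64)

    # --- fold doublet partners into their primary barcodes -----------------
    doublet_rows = np.flatnonzero(is_doublet)

    def fold(mat_ext: sp.csr_matrix):
        primary = mat_ext[:n_total]
        partner = sp.lil_matrix(primary.shape, dtype=np.int64)
        if n_doub:
            partner[doublet_rows] = mat_ext[n_total:]
        partner = sp.csr_matrix(partner)
        return (primary + partner).tocsr(), primary, partner

    rna_counts, rna_p, rna_q = fold(rna_ext)
    adt_counts, adt_p, adt_q = fold(adt_ext)
    hto_counts, hto_p, hto_q = fold(hto_ext)

    rna = CellByFeatureCounts(barcodes, genes, rna_counts, "gene")
    adt = CellByFeatureCounts(barcodes, adt_features, adt_counts, "adt")
    hto = CellByFeatureCounts(barcodes, hto_features, hto_counts, "hashtag")

    meta = [sample_meta[samples[i]] for i in sample_idx]
    cells = pd.DataFrame(
        {
            "sample_id": [samples[i] for i in sample_idx],
            "condition": [m[0] for m in meta],
            "culture": [m[1] for m in meta],
            "panel": [m[2] for m in meta],
            "group": [SampleDesign.group_id(m[1], m[0]) for m in meta],
            "is_doublet": is_doublet,
            "partner_sample": "",
            "is_contaminant": is_contaminant,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    cells.loc[cells.index[doublet_rows], "partner_sample"] = [
        samples[i] for i in partner_sample_idx
    ]
    for t in all_targets:
        cells[f"pos_{t}"] = pos_primary[t]
    cells["cluster"] = np.where(is_contaminant, "contaminant", cells["condition"])
    truth = SyntheticTruth(cells=cells, config=config)

    if _return_components:
        components = {
            "gene": (rna_p, rna_q),
            "adt": (adt_p, adt_q),
            "hashtag": (hto_p, hto_q),
        }
        return rna, adt, hto, truth, components
    return rna, adt, hto, truth


# ---------------------------------------------------------------------------
# Truth-side summaries and the paired flow table
# ---------------------------------------------------------------------------


def _eligible(truth: SyntheticTruth) -> pd.DataFrame:
    c = truth.cells
    return c[~c["is_doublet"] & ~c["is_contaminant"]]


def truth_summary(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-(group, target) truth percent positivity and expected mean corrected level."""
    cells = _eligible(truth)
    design = truth.config.design
    level_pos = math.log1p(truth.config.phospho_signal_mean)
    rows = []
    for group, sub in cells.groupby("group", sort=True):
        for panel, spec in design.panels.items():
            psub = sub[sub["panel"] == panel]
            if psub.empty:
                continue
            for t in spec.phospho_targets:
                frac = float(psub[f"pos_{t}"].mean())
                rows.append(
                    {
                        "group": group,
                        "target": t,
                        "percent_positive": 100.0 * frac,
                        "mean_level": frac * level_pos,
                        "n_cells": len(psub),
                    }
                )
    return pd.DataFrame(rows, columns=["group", "target", "percent_positive", "mean_level", "n_cells"])


MFI_INTERCEPT = 150.0
MFI_SCALE = 400.0


def generate_flow_table(
    truth: SyntheticTruth, noise_sd: float, seed: int
) -> FlowSummaryTable:
    """Paired flow-cytometry summaries from the same ground truth.

    percent positive = truth fraction x 100 + Gaussian(0, noise_sd), clipped
    to [0, 100]; MFI = affine (monotone) transform of the truth mean signal
    level plus Gaussian noise scaled by 20 x noise_sd. noise_sd = 0 gives
    exact collinearity with the truth summary.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    base = truth_summary(truth)
    if base.empty:
        raise DegenerateDataError("empty truth: nothing to measure")
    rng = substream(seed, STREAM_FLOW)
    pct = np.clip(
        base["percent_positive"] + rng.normal(0.0, noise_sd or 1e-300, len(base)) * (noise_sd > 0),
        0.0,
        100.0,
    )
    mfi = (
        MFI_INTERCEPT
        + MFI_SCALE * base["mean_level"]
        + rng.normal(0.0, 20.0 * noise_sd or 1e-300, len(base)) * (noise_sd > 0)
    )
    table = pd.DataFrame(
        {
            "sample_id": base["group"],
            "target_id": base["target"],
            "percent_positive": pct,
            "mfi": np.clip(mfi, 1e-6, None),
        }
    )
    return FlowSummaryTable(table)


# ---------------------------------------------------------------------------
# On-disk export
# ---------------------------------------------------------------------------


def _config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["positive_fraction"] = {f"{k[0]}|{k[1]}": v for k, v in config.positive_fraction.items()}
    return d


def write_dataset(
    rna: CellByFeatureCounts,
    adt: CellByFeatureCounts,
    hto: CellByFeatureCounts,
    truth: SyntheticTruth,
    path: str | Path,
) -> None:
    """CellRanger-style directory per modality + truth TSV + echoed config JSON."""
    path = Path(path)
    write_counts_dir(rna, path / "rna")
    write_counts_dir(adt, path / "adt")
    write_counts_dir(hto, path / "hto")
    truth.cells.to_csv(path / "truth.tsv", sep="\t")
    with open(path / "generator_config.json", "w") as fh:
        json.dump(_config_to_dict(truth.config), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
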