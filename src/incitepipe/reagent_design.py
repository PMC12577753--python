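"""Antibody-oligonucleotide reagent arithmetic.

Validates the 80-base capture-oligo architecture (PCR handle, random
spacers, unique barcode, bead-capture sequence), computes pairwise
Hamming distances of the barcode set, and derives conjugation
stoichiometry: moles of photo-crosslinkable oligo linker per antibody
mass at a fixed molar ratio, and the mass of E. coli single-stranded-DNA
binding protein (EcoSSB) added at a molar excess to shield the oligos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

# Printed capture-oligo architecture (segment roles in 5'->3' order).
PCR_HANDLE = "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"  # 34 nt
CAPTURE_SEQUENCE = "GCTTTAAGGCCGGTCCTAGCAA"  # 22 nt, ends in 2 phosphorothioated adenines
DEFAULT_BARCODES = {
    "barcode1": "GTCACTACGAG",
    "barcode2": "TGGCTACAAGT",
    "barcode3": "CGACATTGACA",
}

SEGMENT_ROLES = ("pcr_handle", "spacer", "barcode", "capture")


@dataclass(frozen=True)
class OligoSegment:
    role: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in SEGMENT_ROLES:
            raise ConfigError(f"unknown segment role {self.role!r}")
        if self.length <= 0:
            raise ConfigError("segment length must be positive")


@dataclass
class OligoSpec:
    """Ordered segment layout of one capture oligo plus 3' modifications and barcode set."""

    segments: tuple[OligoSegment, ...]
    phosphorothioate_3prime: int = 0
    dideoxy_3prime: bool = False
    barcodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigError("oligo spec needs at least one segment")


def default_oligo_spec() -> OligoSpec:
    """The 80-base design: 34 nt handle + 7 N + 11 nt barcode + 6 N + 22 nt capture."""
    return OligoSpec(
        segments=(
            OligoSegment("pcr_handle", 34, PCR_HANDLE),
            OligoSegment("spacer", 7, "N" * 7),
            OligoSegment("barcode", 11),
            OligoSegment("spacer", 6, "N" * 6),
            OligoSegment("capture", 22, CAPTURE_SEQUENCE),
        ),
        phosphorothioate_3prime=2,
        barcodes=dict(DEFAULT_BARCODES),
    )


@dataclass
class OligoReport:
    total_length: int
    segment_checks: list[dict]
    failures: list[str]

    @property
    def passed(self) -> bool:
        return not self.failures


def validate_oligo(spec: OligoSpec) -> OligoReport:
    """Check each segment's declared length against its sequence; report the total."""
    checks, failures = [], []
    for i, seg in enumerate(spec.segments):
        actual = len(seg.sequence) if seg.sequence is not None else None
        ok = actual is None or actual == seg.length
        checks.append(
            {"index": i, "role": seg.role, "declared": seg.length, "actual": actual, "ok": ok}
        )
        if not ok:
            failures.append(
                f"segment {i} ({seg.role}): declared length {seg.length} "
                f"but sequence has {actual} bases"
            )
    for name, seq in spec.barcodes.items():
        bc_lengths = {s.length for s in spec.segments if s.role == "barcode"}
        if bc_lengths and len(seq) not in bc_lengths:
            failures.append(f"barcode {name}: length {len(seq)} not in declared {sorted(bc_lengths)}")
    return OligoReport(
        total_length=sum(s.length for s in spec.segments),
        segment_checks=checks,
        failures=failures,
    )


def barcode_distances(barcodes: Mapping[str, str] | Sequence[str]):
    """Symmetric Hamming-distance matrix over a barcode set, plus the minimum pairwise distance."""
    if not isinstance(barcodes, Mapping):
        barcodes = {f"barcode{i + 1}": s for i, s in enumerate(barcodes)}
    names = list(barcodes)
    seqs = [str(barcodes[n]) for n in names]
    if len({len(s) for s in seqs}) > 1:
        raise ConfigError("barcodes have unequal lengths")
    n = len(names)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            mat[i, j] = mat[j, i] = d
    dist = pd.DataFrame(mat, index=names, columns=names)
    min_d = int(mat[np.triu_indices(n, 1)].min()) if n > 1 else 0
    return dist, min_d


@dataclass
class ConjugationPlan:
    ab_mass_ug: float
    ab_molar_mass: float
    oyo_molarity: float
    ab_to_oyo_ratio: float
    ecossb_fold: float
    ecossb_monomer_mass: float
    oyo_moles_per_uL: float
    ab_moles: float
    oyo_moles: float
    oyo_volume_uL: float
    ecossb_moles: float
    ecossb_mass_ug: float


def conjugation_plan(
    ab_mass_ug: float,
    ab_molar_mass: float = 150_000.0,
    oyo_molarity: float = 33e-6,
    ab_to_oyo_ratio: float = 5.0,
    ecossb_fold: float = 12.0,
    ecossb_monomer_mass: float = 18_900.0,
) -> ConjugationPlan:
    """Conjugation stoichiometry for one antibody aliquot.

    oyo_molarity is in mol/L (default 33 uM), masses in ug, molar masses in
    g/mol. The oligo linker is dosed at ``ab_to_oyo_ratio`` moles per mole of
    antibody; EcoSSB at ``ecossb_fold`` moles per mole of oligo.
    """
    vals = dict(
        ab_mass_ug=ab_mass_ug,
        ab_molar_mass=ab_molar_mass,
        oyo_molarity=oyo_molarity,
        ab_to_oyo_ratio=ab_to_oyo_ratio,
        ecossb_fold=ecossb_fold,
        ecossb_monomer_mass=ecossb_monomer_mass,
    )
    for k, v in vals.items():
        if not np.isfinite(v) or v <= 0:
            raise ConfigError(f"{k} must be positive and finite, got {v}")
    oyo_moles_per_uL = oyo_molarity * 1e-6  # mol/L x 1e-6 L/uL
    ab_moles = ab_mass_ug * 1e-6 / ab_molar_mass
    oyo_moles = ab_to_oyo_ratio * ab_moles
    oyo_volume_uL = oyo_moles / oyo_moles_per_uL
    ecossb_moles = ecossb_fold * oyo_moles
    ecossb_mass_ug = ecossb_moles * ecossb_monomer_mass * 1e6
    return ConjugationPlan(
        **vals,
        oyo_moles_per_uL=oyo_moles_per_uL,
        ab_moles=ab_moles,
        oyo_moles=oyo_moles,
        oyo_volume_uL=oyo_volume_uL,
        ecossb_moles=ecossb_moles,
        ecossb_mass_ug=ecossb_mass_ug,
    )


def ecossb_ug_per_uL_oyo(
    oyo_molarity: float = 33e-6,
    ecossb_fold: float = 12.0,
    ecossb_monomer_mass: float = 18_900.0,
) -> float:
    """Micrograms of EcoSSB required per microliter of oligo linker solution."""
    if min(oyo_molarity, ecossb_fold, ecossb_monomer_mass) <= 0:
        raise ConfigError("all stoichiometry inputs must be positive")
    return oyo_molarity * 1e-6 * ecossb_fold * ecossb_monomer_mass * 1e6
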