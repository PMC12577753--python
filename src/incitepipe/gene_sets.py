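"""Signed gene-set intersection partitioning (upset-style).

Each differential-expression contrast yields a signed set of
(gene, direction) pairs. The partition assigns every pair in the union
to exactly one *signature* — the exact family of input sets containing
it — so signature sizes sum to the size of the union. A gene significant
up in one contrast and down in another contributes two distinct elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class SignedGeneSet:
    name: str
    elements: frozenset  # of (gene, direction) pairs

    def __post_init__(self) -> None:
        genes_up = {g for g, d in self.elements if d == UP}
        genes_down = {g for g, d in self.elements if d == DOWN}
        both = genes_up & genes_down
        if both:
            raise ConfigError(
                f"set {self.name!r}: genes {sorted(both)} appear with both directions"
            )
        bad = {d for _, d in self.elements} - {UP, DOWN}
        if bad:
            raise ConfigError(f"set {self.name!r}: unknown directions {sorted(bad)}")


def build_signed_sets(
    tables: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    logfc_threshold: float = 0.0,
    signed: bool = True,
) -> list[SignedGeneSet]:
    """Threshold each named DE table into a signed gene set.

    Membership: adjusted p < alpha and |logFC| > logfc_threshold. With
    ``signed=False`` the direction is collapsed (all elements tagged "up"),
    giving gene-only intersection keys.
    """
    names = list(tables)
    if len(set(names)) != len(names):
        raise ConfigError("duplicate table names")
    sets = []
    for name in names:
        df = tables[name]
        if len(df):
            sig = df[(df["p_adj"] < alpha) & (df["logFC_ln"].abs() > logfc_threshold)]
            elements = frozenset(
                (g, d if signed else UP) for g, d in zip(sig["gene"], sig["direction"])
            )
        else:
            elements = frozenset()
        sets.append(SignedGeneSet(name=name, elements=elements))
    return sets


@dataclass
class GeneSetPartition:
    """Exclusive, exhaustive partition of the union into per-signature element sets."""

    signatures: dict  # tuple(sorted set names) -> frozenset of (gene, direction)
    set_names: list[str] = field(default_factory=list)

    @property
    def n_signatures(self) -> int:
        return len(self.signatures)

    def sizes(self) -> dict:
        return {sig: len(members) for sig, members in self.signatures.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "signature": "&".join(sig),
                "n_sets": len(sig),
                "size": len(members),
                "members": ";".join(f"{g}:{d}" for g, d in sorted(members)),
            }
            for sig, members in self.signatures.items()
        ]
        return pd.DataFrame(rows, columns=["signature", "n_sets", "size", "members"])

    def membership_matrix(self) -> pd.DataFrame:
        """Plot-ready 0/1 matrix: one row per signature, one column per input set."""
        rows = {
            "&".join(sig): {name: int(name in sig) for name in self.set_names}
            for sig in self.signatures
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.set_names).fillna(0).astype(int)


def intersect_sets(sets: Sequence[SignedGeneSet]) -> GeneSetPartition:
    """Partition the union of signed sets into exclusive intersection signatures.

    Signatures are ordered by family size, then lexicographically by the
    sorted member-set names.
    """
    if not sets:
        raise ConfigError("need at least one signed gene set")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate set names")
    membership: dict = {}
    for s in sets:
        for elem in s.elements:
            membership.setdefault(elem, set()).add(s.name)
    buckets: dict = {}
    for elem, family in membership.items():
        key = tuple(sorted(family))
        buckets.setdefault(key, set()).add(elem)
    ordered = dict(
        sorted(
            ((k, frozenset(v)) for k, v in buckets.items()),
            key=lambda kv: (len(kv[0]), kv[0]),
        )
    )
    return GeneSetPartition(signatures=ordered, set_names=names)
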