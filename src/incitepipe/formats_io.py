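"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices live in CellRanger-style directories: a Matrix Market
coordinate file (features as rows, 1-based indices) plus tab-separated
feature and barcode tables. In memory everything is cells x features.
Flow-cytometry summaries are a plain TSV keyed by (sample, target).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import FormatError

MODALITIES = ("gene", "adt", "hashtag")

#: 10x-style third column of features.tsv, per modality
_FEATURE_TYPE = {
    "gene": "Gene Expression",
    "adt": "Antibody Capture",
    "hashtag": "Antibody Capture",
}


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate {what} entries")
    for lab in labels:
        if "\t" in lab or "\n" in lab or lab == "":
            raise FormatError(f"{what} entry {lab!r} is empty or contains a delimiter")
    return labels


@dataclass
class CellByFeatureCounts:
    """Sparse non-negative integer count matrix (cells x features) for one modality."""

    cell_barcodes: list[str]
    feature_ids: list[str]
    counts: sp.csr_matrix
    modality: str

    def __post_init__(self) -> None:
        self.cell_barcodes = _check_labels(self.cell_barcodes, "barcode")
        self.feature_ids = _check_labels(self.feature_ids, "feature")
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.cell_barcodes), len(self.feature_ids)):
            raise FormatError(
                f"counts shape {m.shape} does not match "
                f"{len(self.cell_barcodes)} barcodes x {len(self.feature_ids)} features"
            )
        if m.nnz:
            data = m.data
            if not np.all(np.isfinite(data)) or np.any(data < 0):
                raise FormatError("counts contain negative or non-finite entries")
            if not np.all(data == np.floor(data)):
                raise FormatError("counts contain non-integer entries")
        self.counts = m.astype(np.int64)
        self.counts.sum_duplicates()

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def feature_column(self, feature_id: str) -> np.ndarray:
        """Dense count vector for one feature over all cells."""
        try:
            j = self.feature_ids.index(feature_id)
        except ValueError:
            raise FormatError(f"feature {feature_id!r} not present") from None
        return np.asarray(self.counts[:, j].todense()).ravel()

    def equals(self, other: "CellByFeatureCounts") -> bool:
        return (
            self.cell_barcodes == other.cell_barcodes
            and self.feature_ids == other.feature_ids
            and self.modality == other.modality
            and (self.counts != other.counts).nnz == 0
        )


def _find_file(path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            cand = path / name
            if cand.exists():
                return cand
    raise FormatError(f"none of {list(stems)} (or .gz) found in {path}")


def _open_text(p: Path):
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "r")


def _read_column(p: Path) -> list[str]:
    with _open_text(p) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_dir(path: str | Path, modality: str) -> CellByFeatureCounts:
    """Read a CellRanger-style directory into a validated count matrix.

    Orientation is auto-detected from the Matrix Market header against the
    barcode/feature table lengths and normalized to cells x features.
    """
    path = Path(path)
    mtx_file = _find_file(path, ["matrix.mtx"])
    feat_file = _find_file(path, ["features.tsv", "genes.tsv"])
    bc_file = _find_file(path, ["barcodes.tsv"])
    features = _read_column(feat_file)
    barcodes = _read_column(bc_file)
    try:
        if mtx_file.suffix == ".gz":
            with gzip.open(mtx_file, "rb") as fh:
                mat = mmread(fh)
        else:
            mat = mmread(mtx_file)
    except Exception as exc:  # malformed header, 0-based index, etc.
        raise FormatError(f"cannot parse {mtx_file}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    nf, nb = len(features), len(barcodes)
    if mat.shape == (nf, nb):
        mat = mat.T  # 10x convention: features as rows on disk
    elif mat.shape == (nb, nf):
        pass
    else:
        raise FormatError(
            f"{mtx_file}: matrix shape {mat.shape} matches neither "
            f"features x barcodes ({nf} x {nb}) nor its transpose"
        )
    try:
        return CellByFeatureCounts(barcodes, features, sp.csr_matrix(mat), modality)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_counts_dir(m: CellByFeatureCounts, path: str | Path, compress: bool = False) -> None:
    """Write a count matrix as a CellRanger-style directory (features as rows)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""

    def _writer(name: str):
        p = path / (name + suffix)
        return gzip.open(p, "wt") if compress else open(p, "w")

    coo = sp.coo_matrix(m.counts.T)
    if compress:
        import io

        buf = io.BytesIO()
        mmwrite(buf, coo, field="integer")
        with gzip.open(path / ("matrix.mtx" + suffix), "wb") as fh:
            fh.write(buf.getvalue())
    else:
        mmwrite(path / "matrix.mtx", coo, field="integer")
    with _writer("features.tsv") as fh:
        for f in m.feature_ids:
            fh.write(f"{f}\t{f}\t{_FEATURE_TYPE[m.modality]}\n")
    with _writer("barcodes.tsv") as fh:
        for b in m.cell_barcodes:
            fh.write(b + "\n")


FLOW_COLUMNS = ["sample_id", "target_id", "percent_positive", "mfi"]


@dataclass
class FlowSummaryTable:
    """Per-(sample, target) flow-cytometry summaries: percent positive and MFI."""

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FLOW_COLUMNS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = [c for c in FLOW_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"flow table missing columns {missing}")
        df = df[FLOW_COLUMNS].reset_index(drop=True)
        if df.duplicated(["sample_id", "target_id"]).any():
            dup = df[df.duplicated(["sample_id", "target_id"])].iloc[0]
            raise FormatError(
                f"duplicate flow key ({dup['sample_id']}, {dup['target_id']})"
            )
        pct = pd.to_numeric(df["percent_positive"], errors="raise")
        if ((pct < 0) | (pct > 100)).any():
            bad = df.loc[(pct < 0) | (pct > 100)].iloc[0]
            raise FormatError(
                f"percent_positive out of [0, 100] for ({bad['sample_id']}, {bad['target_id']})"
            )
        mfi = pd.to_numeric(df["mfi"], errors="raise")
        if (mfi <= 0).any():
            raise FormatError("mfi values must be positive")
        df["percent_positive"] = pct.astype(float)
        df["mfi"] = mfi.astype(float)
        self.table = df

    def __len__(self) -> int:
        return len(self.table)


def read_flow_table(path: str | Path) -> FlowSummaryTable:
    """Read a TSV of per-(sample, target) flow summaries."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    try:
        return FlowSummaryTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_flow_table(flow: FlowSummaryTable, path: str | Path) -> None:
    flow.table.to_csv(path, sep="\t", index=False)


def write_json_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting, trailing newline."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
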