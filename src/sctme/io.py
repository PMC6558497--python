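"""Reading and writing 10x-style triplet matrices and metadata tables.

On-disk layout is the classic CellRanger export: ``matrix.mtx`` (MatrixMarket
triplet, genes x cells), ``features.tsv`` (symbol, chromosome, position,
mito flag), ``barcodes.tsv`` (one barcode per line) and an optional
``cell_metadata.tsv`` with columns barcode, patient, tissue.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import ExpressionMatrix, FormatError, QCReport

_FEATURE_COLS = ["symbol", "chromosome", "position", "mito"]


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Load an :class:`ExpressionMatrix` from a triplet directory.

    Raises :class:`FormatError` on dimension mismatches or duplicate
    barcodes. Counts are preserved exactly.
    """
    path = Path(path)
    mtx = path / "matrix.mtx"
    features = path / "features.tsv"
    barcodes = path / "barcodes.tsv"
    for f in (mtx, features, barcodes):
        if not f.exists():
            raise FormatError(f"missing input file {f}")
    counts = sp.csr_matrix(scipy.io.mmread(mtx))
    feat = pd.read_csv(features, sep="\t", header=None)
    feat.columns = _FEATURE_COLS[: feat.shape[1]]
    if "mito" in feat.columns:
        feat["mito"] = feat["mito"].astype(bool)
    else:
        feat["mito"] = feat["symbol"].str.startswith("MT-")
    if "chromosome" not in feat.columns:
        feat["chromosome"] = "NA"
    if "position" not in feat.columns:
        feat["position"] = np.arange(len(feat))
    bc = pd.read_csv(barcodes, sep="\t", header=None)[0]
    if counts.shape[0] != len(feat):
        raise FormatError(
            f"matrix has {counts.shape[0]} genes but features.tsv has {len(feat)}"
        )
    if counts.shape[1] != len(bc):
        raise FormatError(
            f"matrix has {counts.shape[1]} cells but barcodes.tsv has {len(bc)}"
        )
    cell_meta = pd.DataFrame({"barcode": bc})
    meta_path = path / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        if "barcode" not in meta.columns:
            raise FormatError("cell_metadata.tsv lacks a 'barcode' column")
        cell_meta = cell_meta.merge(meta, on="barcode", how="left")
    else:
        cell_meta["patient"] = "NA"
        cell_meta["tissue"] = "NA"
    return ExpressionMatrix(counts, feat, cell_meta)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the triplet files + cell metadata under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer")
    feat = matrix.gene_meta.copy()
    for col in _FEATURE_COLS:
        if col not in feat.columns:
            feat[col] = {"mito": False, "chromosome": "NA"}.get(col, 0)
    feat["mito"] = feat["mito"].astype(int)
    feat[_FEATURE_COLS].to_csv(path / "features.tsv", sep="\t", header=False, index=False)
    matrix.cell_meta["barcode"].to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    matrix.cell_meta.to_csv(path / "cell_metadata.tsv", sep="\t", index=False)


def write_qc_report(report: QCReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def load_marker_table(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (cell type, gene) -> {type: [genes]}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError("marker table needs two columns: type, gene")
    out: dict[str, list[str]] = {}
    for t, g in zip(df[0], df[1]):
        out.setdefault(str(t), []).append(str(g))
    return out
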