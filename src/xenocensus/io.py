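"""Cell Ranger-dialect I/O for species-tagged matrices.

A matrix directory holds ``matrix.mtx`` (Matrix Market coordinate, integer,
features x barcodes), ``barcodes.tsv`` (one barcode per line) and
``features.tsv`` (tab-separated: id, display name, feature type).  Display
names carry the species tag as the prefix before the first hyphen
(``hg38-CD3E``); symbols beginning with ``MT-`` are flagged mitochondrial.
Spatial directories additionally hold ``tissue_positions.csv``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import TAG_TO_SPECIES, SpotMatrix, TaggedCountMatrix

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pixel_row",
    "pixel_col",
]


def parse_tagged_name(name: str) -> tuple[str, str]:
    """Split ``<tag>-<symbol>`` into (tag, symbol); raise on unknown tags."""
    tag, sep, symbol = name.partition("-")
    if not sep or tag not in TAG_TO_SPECIES or not symbol:
        raise ValueError(name)
    return tag, symbol


def features_to_var(features: pd.DataFrame) -> pd.DataFrame:
    """Build a gene table from a features frame (columns id, name, type)."""
    tags, symbols, bad = [], [], []
    for name in features["name"]:
        try:
            tag, symbol = parse_tagged_name(str(name))
        except ValueError:
            bad.append(str(name))
            continue
        tags.append(tag)
        symbols.append(symbol)
    if bad:
        raise ValueError(
            f"{len(bad)} feature names lack a valid species tag "
            f"(expected '<tag>-<symbol>'): {bad[:10]}"
        )
    var = pd.DataFrame(
        {
            "gene_id": features["id"].astype(str).to_numpy(),
            "symbol": symbols,
            "species_tag": tags,
            "is_mito": [s.startswith("MT-") for s in symbols],
        },
        index=pd.Index(features["name"].astype(str), name="tagged_name"),
    )
    return var


def read_tagged_matrix(directory) -> TaggedCountMatrix:
    """Read a Cell Ranger-dialect directory into a TaggedCountMatrix."""
    d = Path(directory)
    for fname in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (d / fname).exists():
            raise FileNotFoundError(d / fname)
    mat = scipy.io.mmread(d / "matrix.mtx")  # features x barcodes
    barcodes = pd.read_csv(d / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
    features = pd.read_csv(
        d / "features.tsv", header=None, sep="\t", names=["id", "name", "type"]
    )
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"matrix.mtx is {mat.shape} but features.tsv/barcodes.tsv imply "
            f"{(len(features), len(barcodes))}"
        )
    var = features_to_var(features)
    X = sp.csr_matrix(mat.T).astype(np.int64)
    return TaggedCountMatrix(X, pd.Index(barcodes, name="barcode"), var)


def write_tagged_matrix(matrix: TaggedCountMatrix, directory) -> None:
    """Write the Cell Ranger dialect: matrix.mtx, barcodes.tsv, features.tsv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    coo = matrix.X.T.tocoo()  # features x barcodes
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, coo, field="integer")
    (d / "matrix.mtx").write_bytes(buf.getvalue())
    (d / "barcodes.tsv").write_text("\n".join(matrix.barcodes) + "\n")
    features = pd.DataFrame(
        {
            "id": matrix.var["gene_id"],
            "name": matrix.gene_names,
            "type": "Gene Expression",
        }
    )
    features.to_csv(d / "features.tsv", sep="\t", header=False, index=False)


def write_spot_matrix(spot: SpotMatrix, directory) -> None:
    """Write spot counts plus tissue_positions.csv."""
    write_tagged_matrix(spot.counts, directory)
    pos = spot.positions.reset_index()
    pos.columns = POSITION_COLUMNS
    pos.to_csv(Path(directory) / "tissue_positions.csv", index=False)


def read_spot_matrix(directory) -> SpotMatrix:
    counts = read_tagged_matrix(directory)
    pos = pd.read_csv(Path(directory) / "tissue_positions.csv")
    missing = set(POSITION_COLUMNS) - set(pos.columns)
    if missing:
        raise ValueError(f"tissue_positions.csv missing columns: {sorted(missing)}")
    pos = pos.set_index("barcode")
    pos.index = pos.index.astype(str)
    return SpotMatrix(counts, pos.loc[counts.barcodes])


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path)
    truth["barcode"] = truth["barcode"].astype(str)
    return truth
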