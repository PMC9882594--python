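"""In-memory containers for species-tagged expression data.

A barnyard-style experiment aligns mixed human/pig material against a hybrid
reference in which every gene name carries a species tag (``hg38-CD3E``,
``ss11-CD19``).  :class:`TaggedCountMatrix` is the universal exchange object of
this package: barcodes x species-tagged genes with non-negative integer counts.
:class:`ExpressionMatrix` is the float-valued counterpart produced by
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Species tags used by the hybrid human-pig namespace.
HUMAN_TAG = "hg38"
PIG_TAG = "ss11"

#: Mapping from reference tag to species common name.
TAG_TO_SPECIES = {HUMAN_TAG: "human", PIG_TAG: "pig"}
SPECIES_TO_TAG = {v: k for k, v in TAG_TO_SPECIES.items()}

VAR_COLUMNS = ("gene_id", "symbol", "species_tag", "is_mito")


def _as_csr(X) -> sp.csr_matrix:
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X))


def validate_var(var: pd.DataFrame) -> None:
    """Check a gene table: required columns, unique tagged names, known tags."""
    missing = [c for c in VAR_COLUMNS if c not in var.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if not var.index.is_unique:
        dup = var.index[var.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate tagged gene names: {dup[:10]}")
    unknown = set(var["species_tag"]) - set(TAG_TO_SPECIES)
    if unknown:
        raise ValueError(f"unknown species tags: {sorted(unknown)}")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with a species-tagged gene table.

    Parameters
    ----------
    X
        Sparse (CSR) or dense matrix, cells in rows.
    barcodes
        Unique cell barcodes, one per row.
    var
        Gene table indexed by tagged display name (``<tag>-<symbol>``) with
        columns ``gene_id``, ``symbol``, ``species_tag``, ``is_mito``.
    """

    X: sp.csr_matrix
    barcodes: pd.Index
    var: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = _as_csr(self.X)
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        if not self.barcodes.is_unique:
            raise ValueError("barcodes are not unique")
        if self.X.shape != (len(self.barcodes), len(self.var)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.var)} genes"
            )
        validate_var(self.var)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def gene_names(self) -> pd.Index:
        return self.var.index

    def species_mask(self, species: str) -> np.ndarray:
        """Boolean mask over genes belonging to ``species`` ('human'/'pig')."""
        tag = SPECIES_TO_TAG[species]
        return (self.var["species_tag"] == tag).to_numpy()

    def mito_mask(self) -> np.ndarray:
        return self.var["is_mito"].to_numpy(dtype=bool)

    # -- subsetting --------------------------------------------------------
    def subset(self, cells=None, genes=None) -> "ExpressionMatrix":
        """Return a copy restricted to the given cell/gene selections.

        ``cells``/``genes`` may be boolean masks, integer indices, or (for
        genes) tagged names.
        """
        X, bc, var = self.X, self.barcodes, self.var
        if cells is not None:
            cells = np.asarray(cells)
            X = X[cells]
            bc = bc[cells]
        if genes is not None:
            if (
                isinstance(genes, (list, tuple, pd.Index, np.ndarray))
                and len(genes) > 0
                and isinstance(np.asarray(genes).flat[0], str)
            ):
                genes = var.index.get_indexer(genes)
                if (np.asarray(genes) < 0).any():
                    raise KeyError("unknown gene names in selection")
            genes = np.asarray(genes)
            X = X[:, genes]
            var = var.iloc[genes] if genes.dtype != bool else var.loc[genes]
        return type(self)(X.copy(), bc, var.copy())

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.X.copy(),
            obs=pd.DataFrame(index=self.barcodes),
            var=self.var.copy(),
        )


@dataclass
class TaggedCountMatrix(ExpressionMatrix):
    """Non-negative integer UMI counts over a species-tagged gene panel."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.X.dtype, np.integer):
            data = self.X.data
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            self.X = self.X.astype(np.int64)

    # -- species summaries -------------------------------------------------
    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def species_transcripts(self) -> pd.DataFrame:
        """Per-barcode transcript totals by species (columns human, pig)."""
        out = {}
        for species in ("human", "pig"):
            mask = self.species_mask(species)
            out[species] = np.asarray(self.X[:, mask].sum(axis=1)).ravel()
        return pd.DataFrame(out, index=self.barcodes)

    def species_genes_detected(self) -> pd.DataFrame:
        """Per-barcode number of genes with count >= 1, by species."""
        detected = self.X.copy()
        detected.data = np.ones_like(detected.data)
        out = {}
        for species in ("human", "pig"):
            mask = self.species_mask(species)
            out[species] = np.asarray(detected[:, mask].sum(axis=1)).ravel().astype(int)
        return pd.DataFrame(out, index=self.barcodes)


@dataclass
class SpotMatrix:
    """Visium-style spot counts with array coordinates.

    ``positions`` follows the ``tissue_positions.csv`` dialect: one row per
    spot barcode with ``in_tissue``, ``array_row``, ``array_col``,
    ``pixel_row``, ``pixel_col``.
    """

    counts: TaggedCountMatrix
    positions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"in_tissue", "array_row", "array_col"}
        missing = required - set(self.positions.columns)
        if missing:
            raise ValueError(f"positions table missing columns: {sorted(missing)}")
        if not self.positions.index.equals(self.counts.barcodes):
            self.positions = self.positions.loc[self.counts.barcodes]
        coords = list(zip(self.positions["array_row"], self.positions["array_col"]))
        if len(set(coords)) != len(coords):
            raise ValueError("spot array coordinates are not unique")

    @property
    def n_spots(self) -> int:
        return self.counts.n_cells
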