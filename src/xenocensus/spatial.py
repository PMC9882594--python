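"""Spot-level species-aware census: signatures, deconvolution, markers.

Spot deconvolution estimates per-capture-spot cell-type abundance by
regressing each spot's expression on reference cell-type signatures.  The
estimator here is a deterministic non-negative least squares surrogate:
spot and signature vectors are restricted to shared genes (mitochondrial
genes removed from spots first) and sum-normalized, per-spot NNLS
coefficients are rescaled so they sum to the expected cells-per-spot.
Abundances it reports are surrogate estimates — useful for recovery checks
on synthetic mixtures, not posterior cell counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .containers import SpotMatrix, TaggedCountMatrix


def estimate_cells_per_spot(nuclei_counts) -> float:
    """Mean of manual nuclei counts over sampled capture spots."""
    counts = list(nuclei_counts)
    if not counts:
        raise ValueError("nuclei_counts is empty")
    if any(c < 0 for c in counts):
        raise ValueError("nuclei counts must be non-negative")
    return float(sum(counts) / len(counts))


@dataclass
class SignatureMatrix:
    """Cell types x genes reference signatures (non-negative means).

    ``low_confidence`` lists types estimated from fewer than the minimum
    number of cells.
    """

    values: pd.DataFrame  # types x genes
    low_confidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signatures must be non-negative")
        rowsum = self.values.sum(axis=1)
        if (rowsum == 0).any():
            dead = rowsum.index[rowsum == 0].tolist()
            raise ValueError(f"all-zero signature rows: {dead}")

    @property
    def types(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


class SignatureBuilder(BaseEstimator):
    """Per-type mean of library-size-normalized counts.

    Each cell's counts are divided by its total, and the signature of a type
    is the mean normalized profile of its cells.  Types with fewer than
    ``min_cells`` members are flagged low-confidence.
    """

    def __init__(self, min_cells: int = 10):
        self.min_cells = min_cells

    def fit(
        self, reference: TaggedCountMatrix, type_labels: pd.Series
    ) -> "SignatureBuilder":
        labels = type_labels.reindex(reference.barcodes)
        if labels.isna().any():
            bad = reference.barcodes[labels.isna()].tolist()
            raise ValueError(f"unlabeled reference cells: {bad[:5]}")
        totals = reference.counts_per_cell().astype(float)
        if (totals == 0).any():
            raise ValueError("reference contains zero-count cells; QC-filter first")
        import scipy.sparse as sp

        norm = sp.diags(1.0 / totals) @ reference.X.astype(float)
        rows, low = {}, []
        for t, idx in labels.groupby(labels).groups.items():
            mask = labels.index.isin(idx)
            rows[str(t)] = np.asarray(norm[mask].mean(axis=0)).ravel()
            if mask.sum() < self.min_cells:
                low.append(str(t))
        values = pd.DataFrame.from_dict(rows, orient="index")
        values.columns = reference.gene_names
        self.signatures_ = SignatureMatrix(values, sorted(low))
        return self

    def fit_build(self, reference, type_labels) -> SignatureMatrix:
        return self.fit(reference, type_labels).signatures_


def build_signatures(
    reference: TaggedCountMatrix, type_labels: pd.Series, min_cells: int = 10
) -> SignatureMatrix:
    return SignatureBuilder(min_cells).fit_build(reference, type_labels)


class NNLSDeconvolver(BaseEstimator):
    """Non-negative least squares spot deconvolution.

    Fit stores the signature matrix; :meth:`predict` solves, per spot,
    ``min ||S^T a - y||`` with ``a >= 0`` over sum-normalized shared-gene
    vectors, then rescales ``a`` to sum to ``cells_per_spot``.  Mitochondrial
    genes are removed from the spots before matching
    (``drop_mito=True``).
    """

    def __init__(self, cells_per_spot: float = 1.0, drop_mito: bool = True):
        self.cells_per_spot = cells_per_spot
        self.drop_mito = drop_mito

    def fit(self, signatures: SignatureMatrix) -> "NNLSDeconvolver":
        self.signatures_ = signatures
        return self

    def predict(self, spots: SpotMatrix) -> pd.DataFrame:
        counts = spots.counts
        if self.drop_mito:
            counts = counts.subset(genes=~counts.mito_mask())
        shared = counts.gene_names.intersection(self.signatures_.genes)
        if shared.empty:
            raise ValueError("no shared genes between spots and signatures")
        S = self.signatures_.values[shared].to_numpy(dtype=float)
        srow = S.sum(axis=1, keepdims=True)
        if (srow == 0).any():
            dead = self.signatures_.types[srow.ravel() == 0].tolist()
            warnings.warn(f"signatures with no mass on shared genes: {dead}")
            srow[srow == 0] = 1.0
        S = S / srow
        A = S.T  # genes x types

        idx = counts.gene_names.get_indexer(shared)
        Y = np.asarray(counts.X[:, idx].todense(), dtype=float)
        out = np.zeros((counts.n_cells, S.shape[0]))
        for i in range(counts.n_cells):
            total = Y[i].sum()
            if total == 0:
                continue
            coef, _ = nnls(A, Y[i] / total)
            s = coef.sum()
            if s > 0:
                coef = coef * (self.cells_per_spot / s)
            out[i] = coef
        return pd.DataFrame(
            out, index=counts.barcodes, columns=self.signatures_.types
        )


def deconvolve_spots(
    spots: SpotMatrix,
    signatures: SignatureMatrix,
    cells_per_spot: float,
    drop_mito: bool = True,
) -> pd.DataFrame:
    """Functional wrapper over :class:`NNLSDeconvolver`."""
    return (
        NNLSDeconvolver(cells_per_spot, drop_mito).fit(signatures).predict(spots)
    )


def impute_marker_abundance(
    spots: SpotMatrix, markers: list[str], threshold: int = 1
) -> pd.DataFrame:
    """Per-spot raw counts and detection flags for tagged marker genes.

    Cell types without a reliable signature (e.g. rare human T/B cells) can
    be localized directly from species-tagged markers such as ``hg38-CD3E``
    or ``ss11-CD19``.  Missing markers are reported via a warning, not an
    error.
    """
    names = spots.counts.gene_names
    present = [m for m in markers if m in names]
    missing = [m for m in markers if m not in names]
    if missing:
        warnings.warn(f"markers absent from spot panel: {missing}")
    out = pd.DataFrame(index=spots.counts.barcodes)
    for m in present:
        col = np.asarray(
            spots.counts.X[:, names.get_loc(m)].todense()
        ).ravel().astype(int)
        out[f"{m}_count"] = col
        out[f"{m}_detected"] = col >= threshold
    return out
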