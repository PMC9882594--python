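"""QC filtering, normalization, variable genes, clustering and markers.

The processing chain mirrors the standard droplet scRNA-seq census: strict
QC cutoffs (features < 200 or > 3000, mitochondrial fraction > 12%, doublet
score > 0.3 removed; genes expressed in < 5 retained cells dropped),
log1p normalization at a 10,000 scale factor, top-3000 variable genes ranked
by coefficient of variation, 30 principal components, a KNN graph with
shared-nearest-neighbor (Jaccard) edge weights, modularity-optimizing
community detection, and one-vs-rest Wilcoxon rank-sum marker tests with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, TaggedCountMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level QC cutoffs (all comparisons strict)."""

    min_features: int = 200
    max_features: int = 3000
    max_mito_fraction: float = 0.12
    min_cells_per_gene: int = 5
    max_doublet_score: float = 0.3

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")

    @staticmethod
    def snrna_profile() -> "QCThresholds":
        """Single-nucleus variant: feature cap 2500, mito cap 15%."""
        return QCThresholds(max_features=2500, max_mito_fraction=0.15)


@dataclass
class QCReport:
    """Accounting of a QC pass: every removal with its reason.

    ``cell_reasons`` maps barcode -> list of failed criteria; conservation
    holds: removed + retained = input, for both cells and genes.
    """

    n_cells_in: int
    n_cells_retained: int
    n_genes_in: int
    n_genes_retained: int
    cell_reasons: dict[str, list[str]] = field(default_factory=dict)
    genes_removed: list[str] = field(default_factory=list)

    @property
    def n_cells_removed(self) -> int:
        return len(self.cell_reasons)

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for reasons in self.cell_reasons.values():
            for r in reasons:
                counts[r] = counts.get(r, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_retained": self.n_cells_retained,
            "n_cells_removed": self.n_cells_removed,
            "n_genes_in": self.n_genes_in,
            "n_genes_retained": self.n_genes_retained,
            "reason_counts": self.reason_counts(),
        }


class QCFilter(BaseEstimator):
    """Remove failing cells then under-expressed genes.

    A cell is removed iff features < ``min_features``, features >
    ``max_features``, mito fraction > ``max_mito_fraction``, or doublet
    score > ``max_doublet_score`` — all strict, so a cell at exactly 12%
    mito or score 0.30 is retained.  Genes expressed in fewer than
    ``min_cells_per_gene`` retained cells are then dropped.
    """

    def __init__(self, thresholds: QCThresholds = QCThresholds()):
        self.thresholds = thresholds

    def fit_transform(
        self, matrix: TaggedCountMatrix, doublet_scores: pd.Series | None = None
    ) -> TaggedCountMatrix:
        t = self.thresholds
        X = matrix.X
        detected = X.copy()
        detected.data = np.ones_like(detected.data)
        features = np.asarray(detected.sum(axis=1)).ravel().astype(int)
        totals = matrix.counts_per_cell().astype(float)
        mito = np.asarray(X[:, matrix.mito_mask()].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            mito_frac = np.divide(
                mito, totals, out=np.zeros_like(mito, dtype=float), where=totals > 0
            )
        if doublet_scores is None:
            scores = np.zeros(matrix.n_cells)
        else:
            scores = doublet_scores.reindex(matrix.barcodes).to_numpy(dtype=float)
            if np.isnan(scores).any():
                raise ValueError("doublet_scores missing for some barcodes")

        criteria = {
            "min_features": features < t.min_features,
            "max_features": features > t.max_features,
            "max_mito_fraction": mito_frac > t.max_mito_fraction,
            "max_doublet_score": scores > t.max_doublet_score,
        }
        fail = np.zeros(matrix.n_cells, dtype=bool)
        for mask in criteria.values():
            fail |= mask
        cell_reasons = {
            str(bc): [name for name, mask in criteria.items() if mask[i]]
            for i, bc in enumerate(matrix.barcodes)
            if fail[i]
        }
        keep_cells = ~fail
        if not keep_cells.any():
            self.report_ = QCReport(
                matrix.n_cells, 0, matrix.n_genes, 0, cell_reasons
            )
            raise ValueError(
                f"QC removed all {matrix.n_cells} cells "
                f"(reasons: {self.report_.reason_counts()})"
            )

        kept = matrix.subset(cells=keep_cells)
        gene_cells = np.asarray(
            (kept.X > 0).sum(axis=0)
        ).ravel().astype(int)
        keep_genes = gene_cells >= t.min_cells_per_gene
        removed_genes = kept.gene_names[~keep_genes].tolist()
        out = kept.subset(genes=keep_genes)

        self.report_ = QCReport(
            n_cells_in=matrix.n_cells,
            n_cells_retained=out.n_cells,
            n_genes_in=matrix.n_genes,
            n_genes_retained=out.n_genes,
            cell_reasons=cell_reasons,
            genes_removed=removed_genes,
        )
        return out


def qc_filter(
    matrix: TaggedCountMatrix,
    doublet_scores: pd.Series | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[TaggedCountMatrix, QCReport]:
    f = QCFilter(thresholds)
    out = f.fit_transform(matrix, doublet_scores)
    return out, f.report_


class LogNormalizer(BaseEstimator):
    """Per-cell library-size normalization: log(1 + scale * count / total)."""

    def __init__(self, scale: float = 10_000.0):
        self.scale = scale

    def transform(self, matrix: TaggedCountMatrix) -> ExpressionMatrix:
        totals = matrix.counts_per_cell().astype(float)
        if (totals == 0).any():
            bad = matrix.barcodes[totals == 0].tolist()
            raise ValueError(
                f"cells with zero total counts cannot be normalized: {bad[:5]}"
            )
        X = matrix.X.astype(float).tocsr(copy=True)
        inv = self.scale / totals
        X = sp.diags(inv) @ X
        X.data = np.log1p(X.data)
        return ExpressionMatrix(X.tocsr(), matrix.barcodes, matrix.var.copy())

    fit_transform = transform


def normalize_log1p(
    matrix: TaggedCountMatrix, scale: float = 10_000.0
) -> ExpressionMatrix:
    return LogNormalizer(scale).transform(matrix)


class CVGeneSelector(BaseEstimator):
    """Rank genes by coefficient of variation of normalized expression.

    CV = sd/mean across cells; genes with zero mean get CV 0 and rank last.
    Ties break deterministically by tagged gene name.
    """

    def __init__(self, n_top: int = 3000):
        self.n_top = n_top

    def fit(self, normalized: ExpressionMatrix) -> "CVGeneSelector":
        X = normalized.X
        n = X.shape[0]
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
        sd = np.sqrt(var)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0)
        # descending CV, exact ties broken by gene name (stable two-pass sort)
        order = (
            pd.DataFrame({"cv": cv}, index=normalized.gene_names)
            .sort_index(kind="stable")
            .sort_values("cv", ascending=False, kind="stable")
        )
        self.cv_ = order["cv"]
        n_top = self.n_top
        if n_top > len(order):
            warnings.warn(
                f"only {len(order)} genes available for top-{n_top} selection"
            )
            n_top = len(order)
        self.hvg_ = order.index[:n_top].tolist()
        return self

    def fit_select(self, normalized: ExpressionMatrix) -> list[str]:
        return self.fit(normalized).hvg_


def select_hvg(normalized: ExpressionMatrix, n: int = 3000) -> list[str]:
    return CVGeneSelector(n).fit_select(normalized)


class GraphClusterer(BaseEstimator):
    """PCA embedding plus SNN modularity clustering.

    Variable genes are centered and scaled to unit variance (values clipped
    at +/-``clip``), reduced to ``n_components`` principal components; a KNN
    graph is built in PC space, edges reweighted by the Jaccard overlap of
    neighbor sets (shared nearest neighbors), weak edges pruned, and
    communities found by RB-configuration modularity optimization (Leiden) at
    the given resolution.  Deterministic for a fixed ``random_state``.
    """

    def __init__(
        self,
        n_components: int = 30,
        k_neighbors: int = 20,
        resolution: float = 0.8,
        clip: float = 10.0,
        prune: float = 1 / 15,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.clip = clip
        self.prune = prune
        self.random_state = random_state

    def fit(
        self, normalized: ExpressionMatrix, hvg: list[str]
    ) -> "GraphClusterer":
        if not len(hvg):
            raise ValueError("hvg list is empty")
        sub = normalized.subset(genes=list(hvg))
        Z = np.asarray(sub.X.todense(), dtype=float)
        Z -= Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z = np.clip(Z / sd, -self.clip, self.clip)

        n_cells = Z.shape[0]
        n_comp = min(self.n_components, n_cells - 1, Z.shape[1])
        if n_comp < self.n_components:
            warnings.warn(
                f"reducing n_components from {self.n_components} to {n_comp}"
            )
        pca = PCA(
            n_components=n_comp, svd_solver="full", random_state=self.random_state
        )
        self.embedding_ = pca.fit_transform(Z)
        self.explained_variance_ratio_ = pca.explained_variance_ratio_

        k = min(self.k_neighbors, n_cells - 1)
        nn = NearestNeighbors(n_neighbors=k).fit(self.embedding_)
        knn = nn.kneighbors_graph(self.embedding_, mode="connectivity").tolil()
        knn.setdiag(1)  # each cell is in its own neighbor set
        A = knn.tocsr()
        # SNN: Jaccard overlap of neighbor sets
        shared = (A @ A.T).tocoo()
        set_size = k + 1
        jac = shared.data / (2 * set_size - shared.data)
        keep = jac >= self.prune
        rows, cols, w = shared.row[keep], shared.col[keep], jac[keep]
        off = rows != cols
        self.snn_ = sp.coo_matrix(
            (w[off], (rows[off], cols[off])), shape=(n_cells, n_cells)
        ).tocsr()

        import igraph as ig
        import leidenalg

        snn = sp.triu(self.snn_, k=1).tocoo()
        g = ig.Graph(
            n=n_cells,
            edges=list(zip(snn.row.tolist(), snn.col.tolist())),
            edge_attrs={"weight": snn.data.tolist()},
        )
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=self.resolution,
            seed=self.random_state,
        )
        self.labels_ = np.asarray(part.membership, dtype=int)
        return self

    def fit_predict(self, normalized: ExpressionMatrix, hvg: list[str]) -> np.ndarray:
        return self.fit(normalized, hvg).labels_


def embed_and_cluster(
    normalized: ExpressionMatrix,
    hvg: list[str],
    n_components: int = 30,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    c = GraphClusterer(
        n_components=n_components,
        k_neighbors=k_neighbors,
        resolution=resolution,
        random_state=seed,
    ).fit(normalized, hvg)
    return c.embedding_, c.labels_


def find_markers(
    normalized: ExpressionMatrix,
    cluster_labels: np.ndarray | pd.Series,
    min_cells: int = 2,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    For every cluster and gene: Mann-Whitney U of in-cluster vs rest
    expression, log fold-change of mean (expm1-backtransformed) expression,
    and Benjamini-Hochberg adjusted p-values across genes.  Tables are
    sorted by adjusted p, then descending log fold-change.  Clusters with
    fewer than ``min_cells`` members are skipped with a warning.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=normalized.barcodes)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters to find markers")
    X = np.asarray(normalized.X.todense(), dtype=float)
    expm1 = np.expm1(X)
    eps = 1e-9
    out: dict[str, pd.DataFrame] = {}
    for cluster in uniq:
        mask = (labels == cluster).to_numpy()
        if mask.sum() < min_cells or (~mask).sum() < min_cells:
            warnings.warn(f"cluster {cluster!r} too small for marker testing; skipped")
            continue
        res = stats.mannwhitneyu(
            X[mask], X[~mask], alternative="two-sided", axis=0, method="asymptotic"
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals = np.nan_to_num(pvals, nan=1.0)  # constant genes: no evidence
        lfc = np.log(
            (expm1[mask].mean(axis=0) + eps) / (expm1[~mask].mean(axis=0) + eps)
        )
        padj = multipletests(pvals, method="fdr_bh")[1]
        table = pd.DataFrame(
            {
                "gene": normalized.gene_names,
                "p_value": pvals,
                "p_adj": padj,
                "log_fc": lfc,
                "statistic": np.asarray(res.statistic, dtype=float),
            }
        ).sort_values(
            ["p_adj", "log_fc"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
        out[str(cluster)] = table
    return out
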