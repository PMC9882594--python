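"""Per-cell species classification and purity diagnostics.

Two complementary classifiers assign each barcode to human or pig:

* **Majority transcript species** — the species owning the larger share of a
  cell's transcripts under the hybrid reference.  The cell's *purity* is that
  share, so purity >= 0.5 whenever the cell has any counts.
* **Gene-ratio classifier** — the number of genes detected under each
  species' *modified* reference; a cell is called porcine when the
  human:porcine detected-gene ratio falls below ``low`` (default 0.75) and
  human when it exceeds ``high`` (default 1.33).  Cells in between are
  ambiguous and excluded from analysis.

Dataset-level purity summaries, inter-method concordance, and per-cluster
cross-mapping reports (which opposite-species genes soak up reads in a
cluster, and how much) complete the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import TAG_TO_SPECIES, TaggedCountMatrix
from .reference import ModifiedReference

PROFILE_COLUMNS = [
    "transcripts_human",
    "transcripts_pig",
    "genes_detected_human",
    "genes_detected_pig",
    "total",
    "purity",
    "majority_species",
]


def compute_species_profiles(matrix: TaggedCountMatrix) -> pd.DataFrame:
    """Per-barcode species evidence under the hybrid reference.

    Returns a frame indexed by barcode with transcript and detected-gene
    totals per species, overall total, purity (max species transcript
    fraction), and ``majority_species`` in {human, pig, tie}.  Barcodes with
    zero total counts get ``purity`` NaN and majority ``undetermined``; they
    are excluded from downstream summaries.
    """
    tx = matrix.species_transcripts()
    genes = matrix.species_genes_detected()
    total = tx["human"] + tx["pig"]

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_h = tx["human"] / total
    purity = np.maximum(frac_h, 1.0 - frac_h)

    majority = np.where(
        tx["human"] > tx["pig"], "human", np.where(tx["pig"] > tx["human"], "pig", "tie")
    ).astype(object)
    zero = (total == 0).to_numpy()
    majority[zero] = "undetermined"
    purity = purity.where(~zero, np.nan)

    return pd.DataFrame(
        {
            "transcripts_human": tx["human"].astype(int),
            "transcripts_pig": tx["pig"].astype(int),
            "genes_detected_human": genes["human"],
            "genes_detected_pig": genes["pig"],
            "total": total.astype(int),
            "purity": purity,
            "majority_species": majority,
        },
        index=matrix.barcodes,
    )


@dataclass
class PuritySummary:
    """Dataset-level transcript purity statistics.

    ``single_species_transcript_fraction`` is the share of all transcripts
    that belong to their cell's majority species (ties contribute nothing to
    the numerator: a 50/50 cell has no single species).
    ``cells_above_purity_threshold_fraction`` is the share of cells whose
    purity strictly exceeds ``purity_threshold``.
    """

    total_transcripts: int
    single_species_transcript_fraction: float
    cells_above_purity_threshold_fraction: float
    purity_threshold: float = 0.90
    n_cells: int = 0

    def __post_init__(self) -> None:
        for f in (
            self.single_species_transcript_fraction,
            self.cells_above_purity_threshold_fraction,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("purity fractions must lie in [0, 1]")


def summarize_purity(
    profiles: pd.DataFrame, purity_threshold: float = 0.90
) -> PuritySummary:
    """Summarize species purity over a profile table from
    :func:`compute_species_profiles`.  Zero-count barcodes are excluded."""
    valid = profiles[profiles["total"] > 0]
    if valid.empty:
        raise ValueError("no cells with nonzero counts to summarize")

    majority_tx = np.where(
        valid["majority_species"] == "human",
        valid["transcripts_human"],
        np.where(valid["majority_species"] == "pig", valid["transcripts_pig"], 0),
    )
    total = int(valid["total"].sum())
    return PuritySummary(
        total_transcripts=total,
        single_species_transcript_fraction=float(majority_tx.sum() / total),
        cells_above_purity_threshold_fraction=float(
            (valid["purity"] > purity_threshold).mean()
        ),
        purity_threshold=purity_threshold,
        n_cells=int(len(valid)),
    )


@dataclass
class RatioCall:
    """Species call for one barcode under the gene-ratio rule."""

    barcode: str
    ratio: float  # human genes detected / pig genes detected; may be +inf
    label: str  # porcine | human | ambiguous
    unassignable: bool = False  # both detected-gene counts were zero


class RatioSpeciesClassifier(BaseEstimator):
    """Gene-ratio species classifier over modified-reference detections.

    The decision regions partition [0, +inf]: ratio < ``low`` -> porcine,
    ratio > ``high`` -> human, otherwise ambiguous.  A zero pig-gene
    denominator with human genes present gives ratio +inf (human); zero human
    genes with pig genes present gives 0 (porcine); both zero is flagged
    unassignable and labeled ambiguous.

    Parameters
    ----------
    low, high
        The ambiguous band is the closed interval [low, high]
        (defaults 0.75 and 1.33).
    """

    def __init__(self, low: float = 0.75, high: float = 1.33):
        self.low = low
        self.high = high

    def _check(self) -> None:
        if not (0 < self.low <= self.high):
            raise ValueError("need 0 < low <= high")

    def call_one(self, genes_detected_human: int, genes_detected_pig: int) -> RatioCall:
        self._check()
        h, p = int(genes_detected_human), int(genes_detected_pig)
        if h < 0 or p < 0:
            raise ValueError("detected-gene counts must be non-negative")
        if h == 0 and p == 0:
            return RatioCall("", math.nan, "ambiguous", unassignable=True)
        ratio = math.inf if p == 0 else h / p
        if ratio < self.low:
            label = "porcine"
        elif ratio > self.high:
            label = "human"
        else:
            label = "ambiguous"
        return RatioCall("", ratio, label)

    def predict(self, detected: pd.DataFrame) -> pd.DataFrame:
        """Vectorized calls for a frame with columns
        ``genes_detected_human`` / ``genes_detected_pig`` (barcode index)."""
        self._check()
        h = detected["genes_detected_human"].to_numpy(dtype=float)
        p = detected["genes_detected_pig"].to_numpy(dtype=float)
        if (h < 0).any() or (p < 0).any():
            raise ValueError("detected-gene counts must be non-negative")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.divide(h, p)
        ratio[(p == 0) & (h > 0)] = np.inf
        unassignable = (h == 0) & (p == 0)
        ratio[unassignable] = np.nan
        label = np.full(len(h), "ambiguous", dtype=object)
        label[ratio < self.low] = "porcine"
        label[ratio > self.high] = "human"
        return pd.DataFrame(
            {"ratio": ratio, "label": label, "unassignable": unassignable},
            index=detected.index,
        )


def classify_by_ratio(
    genes_detected_human: int,
    genes_detected_pig: int,
    low: float = 0.75,
    high: float = 1.33,
) -> RatioCall:
    """Single-cell wrapper over :class:`RatioSpeciesClassifier`."""
    return RatioSpeciesClassifier(low, high).call_one(
        genes_detected_human, genes_detected_pig
    )


def detected_genes_under_references(
    matrix: TaggedCountMatrix,
    modified_human: ModifiedReference,
    modified_pig: ModifiedReference,
) -> pd.DataFrame:
    """Per-barcode detected-gene counts under each species' modified reference.

    A gene counts as detected when its count is >= 1 and its gene_id is
    retained in the corresponding modified reference.  This emulates mapping
    the sample to the two modified references without re-aligning reads.
    """
    detected = matrix.X.copy()
    detected.data = np.ones_like(detected.data)
    out = {}
    for species, modref in (("human", modified_human), ("pig", modified_pig)):
        mask = matrix.species_mask(species) & matrix.var["gene_id"].isin(
            modref.retained_set
        ).to_numpy()
        out[f"genes_detected_{species}"] = (
            np.asarray(detected[:, mask].sum(axis=1)).ravel().astype(int)
        )
    return pd.DataFrame(out, index=matrix.barcodes)


def ratio_calls(
    matrix: TaggedCountMatrix,
    modified_human: ModifiedReference,
    modified_pig: ModifiedReference,
    low: float = 0.75,
    high: float = 1.33,
) -> pd.DataFrame:
    """End-to-end gene-ratio species calls for every barcode."""
    detected = detected_genes_under_references(matrix, modified_human, modified_pig)
    calls = RatioSpeciesClassifier(low, high).predict(detected)
    return detected.join(calls)


@dataclass
class ConcordanceReport:
    """Agreement between two per-barcode species call tables."""

    agreement: float  # on barcodes unambiguous in both tables
    n_compared: int
    confusion: pd.DataFrame  # labels of A (rows) x labels of B (columns)
    per_cluster: pd.Series | None = None


_SPECIES_SYNONYM = {"pig": "porcine", "porcine": "porcine", "human": "human"}


def _canonical_labels(labels: pd.Series) -> pd.Series:
    return labels.map(lambda s: _SPECIES_SYNONYM.get(s, "ambiguous"))


def concordance(
    calls_a: pd.Series,
    calls_b: pd.Series,
    clusters: pd.Series | None = None,
) -> ConcordanceReport:
    """Compare two species call tables barcode-wise.

    ``agreement`` is computed on the barcodes where *both* methods produced a
    species call (neither ambiguous); the confusion matrix covers all shared
    barcodes over {human, porcine, ambiguous}.  Majority-method labels
    ("pig") and ratio-method labels ("porcine") are treated as synonyms.
    """
    shared = calls_a.index.intersection(calls_b.index)
    if shared.empty:
        raise ValueError("no shared barcodes between call tables")
    a = _canonical_labels(calls_a.loc[shared])
    b = _canonical_labels(calls_b.loc[shared])

    cats = ["human", "porcine", "ambiguous"]
    confusion = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    confusion.index.name, confusion.columns.name = "calls_a", "calls_b"

    decided = (a != "ambiguous") & (b != "ambiguous")
    n = int(decided.sum())
    agreement = float((a[decided] == b[decided]).mean()) if n else math.nan

    per_cluster = None
    if clusters is not None:
        cl = clusters.loc[shared]
        rows = {}
        for c, idx in cl.groupby(cl).groups.items():
            d = decided.loc[idx]
            rows[c] = float((a[idx][d] == b[idx][d]).mean()) if d.any() else math.nan
        per_cluster = pd.Series(rows, name="agreement")

    return ConcordanceReport(agreement, n, confusion, per_cluster)


@dataclass
class ClusterCrossmapReport:
    """Opposite-species read usage within one cluster.

    ``offending_genes`` ranks opposite-species genes by descending count with
    a cumulative fraction over all nonzero opposite-species counts;
    ``panel_fraction`` is the share of the opposite panel with any counts.
    """

    cluster_id: str
    assigned_species: str
    opposite_fraction: float
    offending_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    panel_fraction: float = 0.0
    total_counts: int = 0


def cluster_crossmap_report(
    matrix: TaggedCountMatrix,
    cluster_labels: pd.Series,
    cluster_species: dict[str, str],
) -> dict[str, ClusterCrossmapReport]:
    """Per-cluster cross-mapping diagnostics.

    For each cluster with a known species assignment, report what fraction of
    its reads landed on the opposite species' genes and which genes absorb
    them — e.g. a pig macrophage cluster whose reads leak onto a handful of
    homologous human genes.
    """
    labels = cluster_labels.loc[matrix.barcodes]
    reports: dict[str, ClusterCrossmapReport] = {}
    for cluster in pd.unique(labels):
        species = cluster_species.get(str(cluster))
        if species is None:
            warnings.warn(f"cluster {cluster!r} has no species assignment; skipped")
            continue
        if species not in ("human", "pig"):
            species = TAG_TO_SPECIES.get(species)
            if species is None:
                warnings.warn(f"cluster {cluster!r}: unknown species; skipped")
                continue
        opposite = "pig" if species == "human" else "human"
        cells = (labels == cluster).to_numpy()
        sub = matrix.X[cells]
        total = int(sub.sum())
        opp_mask = matrix.species_mask(opposite)
        opp_counts = np.asarray(sub[:, opp_mask].sum(axis=0)).ravel()
        opp_total = int(opp_counts.sum())

        opp_names = matrix.gene_names[opp_mask]
        nz = opp_counts > 0
        order = np.argsort(-opp_counts[nz], kind="stable")
        ranked_names = opp_names[nz][order]
        ranked_counts = opp_counts[nz][order].astype(int)
        cum = (
            np.cumsum(ranked_counts) / opp_total if opp_total else np.array([])
        )
        offending = pd.DataFrame(
            {"gene": ranked_names, "count": ranked_counts, "cumulative_fraction": cum}
        )
        reports[str(cluster)] = ClusterCrossmapReport(
            cluster_id=str(cluster),
            assigned_species=species,
            opposite_fraction=opp_total / total if total else 0.0,
            offending_genes=offending,
            panel_fraction=float(nz.sum() / opp_mask.sum()) if opp_mask.sum() else 0.0,
            total_counts=total,
        )
    return reports
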