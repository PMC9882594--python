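"""Species-tagged hybrid gene namespace and modified species-specific references.

Two operations from the hybrid-reference workflow live here.  First, two
species' gene panels are merged into a single namespace in which every display
name carries its species tag, so the same symbol can exist once per species
(``hg38-CD19`` and ``ss11-CD19`` are distinct genes).  Second, a *modified*
species-specific reference is built by mapping a pure sample of the opposite
species against a panel and removing every gene that spuriously attracts more
than ``removal_threshold`` summed counts — those genes are homology artifacts
that would blur per-cell species calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import TAG_TO_SPECIES, TaggedCountMatrix


@dataclass(frozen=True)
class GeneRecord:
    """One gene of a species panel."""

    gene_id: str
    symbol: str
    species_tag: str
    is_mito: bool = False

    def __post_init__(self) -> None:
        if self.species_tag not in TAG_TO_SPECIES:
            raise ValueError(f"unknown species tag: {self.species_tag!r}")

    @property
    def tagged_name(self) -> str:
        return f"{self.species_tag}-{self.symbol}"


def panel_to_var(panel: list[GeneRecord]) -> pd.DataFrame:
    """Gene table (indexed by tagged name) from a list of records."""
    var = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel],
            "symbol": [g.symbol for g in panel],
            "species_tag": [g.species_tag for g in panel],
            "is_mito": [g.is_mito for g in panel],
        },
        index=pd.Index([g.tagged_name for g in panel], name="tagged_name"),
    )
    return var


def merge_namespaces(
    panel_a: list[GeneRecord], panel_b: list[GeneRecord]
) -> list[GeneRecord]:
    """Concatenate two species panels into a hybrid namespace.

    Raises
    ------
    ValueError
        If any tagged display name would collide.  Identical *symbols* across
        species are fine — the tags keep them distinct.
    """
    merged = list(panel_a) + list(panel_b)
    names = [g.tagged_name for g in merged]
    seen: set[str] = set()
    dup = [n for n in names if n in seen or seen.add(n)]
    if dup:
        raise ValueError(f"tagged name collision in hybrid namespace: {sorted(set(dup))}")
    return merged


@dataclass
class ModifiedReference:
    """Retained/removed partition of one species' panel.

    ``removed`` lists ``(gene_id, opposite_species_count)`` pairs for genes
    whose summed counts in a pure opposite-species sample exceeded the
    threshold.
    """

    species_tag: str
    retained: list[str]
    removed: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed_ids = {g for g, _ in self.removed}
        if removed_ids & set(self.retained):
            raise ValueError("retained and removed sets overlap")

    @property
    def retained_set(self) -> set[str]:
        return set(self.retained)

    @property
    def removed_ids(self) -> set[str]:
        return {g for g, _ in self.removed}

    def report(self, panel: list[GeneRecord] | None = None) -> pd.DataFrame:
        """Removed-gene report (gene_id, symbol, species, cross_count)."""
        symbols = {g.gene_id: g.symbol for g in panel} if panel else {}
        rows = [
            {
                "gene_id": gid,
                "symbol": symbols.get(gid, ""),
                "species": TAG_TO_SPECIES[self.species_tag],
                "cross_count": n,
            }
            for gid, n in self.removed
        ]
        return pd.DataFrame(rows, columns=["gene_id", "symbol", "species", "cross_count"])


class ModifiedReferenceBuilder(BaseEstimator):
    """Build a modified species reference by the cross-mapping removal rule.

    A pure sample of the *opposite* species is mapped against the panel of
    interest; any gene attracting more than ``removal_threshold`` summed
    counts across the whole sample is removed.  The threshold comparison is
    strict: a gene with exactly ``removal_threshold`` counts is retained.

    Parameters
    ----------
    removal_threshold
        Summed opposite-species count above which a gene is removed
        (default 3, i.e. ">3 counts" removes).

    Attributes
    ----------
    reference_ : ModifiedReference
        The retained/removed partition after :meth:`fit`.
    cross_counts_ : pandas.Series
        Summed opposite-species counts per panel gene.
    """

    def __init__(self, removal_threshold: int = 3):
        self.removal_threshold = removal_threshold

    def fit(
        self,
        own_panel: list[GeneRecord],
        opposite_species_sample: TaggedCountMatrix,
    ) -> "ModifiedReferenceBuilder":
        """Partition ``own_panel`` given counts from the opposite species.

        The caller asserts that every cell of ``opposite_species_sample``
        truly belongs to the opposite species (e.g. a pre-transplant,
        single-species specimen).
        """
        if not own_panel:
            raise ValueError("own_panel is empty")
        tags = {g.species_tag for g in own_panel}
        if len(tags) != 1:
            raise ValueError(f"own_panel mixes species tags: {sorted(tags)}")
        (tag,) = tags

        names = [g.tagged_name for g in own_panel]
        totals = pd.Series(0, index=pd.Index(names), dtype=np.int64)
        if opposite_species_sample.n_cells == 0:
            warnings.warn(
                "empty opposite-species sample: all genes retained", stacklevel=2
            )
        else:
            present = opposite_species_sample.gene_names.intersection(totals.index)
            if len(present):
                idx = opposite_species_sample.gene_names.get_indexer(present)
                sums = np.asarray(
                    opposite_species_sample.X[:, idx].sum(axis=0)
                ).ravel()
                totals.loc[present] = sums.astype(np.int64)

        removed, retained = [], []
        for g, name in zip(own_panel, names):
            n = int(totals[name])
            if n > self.removal_threshold:
                removed.append((g.gene_id, n))
            else:
                retained.append(g.gene_id)
        self.cross_counts_ = totals
        self.reference_ = ModifiedReference(tag, retained, removed)
        return self

    def fit_build(self, own_panel, opposite_species_sample) -> ModifiedReference:
        return self.fit(own_panel, opposite_species_sample).reference_


def build_modified_reference(
    own_panel: list[GeneRecord],
    opposite_species_sample: TaggedCountMatrix,
    removal_threshold: int = 3,
) -> ModifiedReference:
    """Functional wrapper over :class:`ModifiedReferenceBuilder`."""
    return ModifiedReferenceBuilder(removal_threshold).fit_build(
        own_panel, opposite_species_sample
    )
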