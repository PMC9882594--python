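"""Synthetic mixed-species (barnyard) data with known ground truth.

The generator emulates the statistical structure a xenograft immune census
has to cope with:

* two species' gene panels merged into one species-tagged namespace, with a
  configurable number of homologous gene pairs between them;
* per-cell counts drawn from overdispersed type-specific expression programs
  (gamma-perturbed gene weights, multinomial totals with lognormal library
  sizes);
* homolog cross-mapping — a read emitted by one species' gene lands on its
  partner gene of the other species with probability ``cross_map_prob``;
* ambient "soup" contamination — a share of each cell's counts is resampled
  from the pooled profile of all cells;
* doublets — two cells' counts summed under one barcode, flagged by an
  externally-styled doublet score;
* a small "dying" subpopulation with elevated mitochondrial fraction, so
  mito-based QC has both pass and fail cases.

Every barcode is paired with a :class:`CellTruth` row; the truth table is the
oracle for all recovery tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    HUMAN_TAG,
    PIG_TAG,
    SPECIES_TO_TAG,
    SpotMatrix,
    TaggedCountMatrix,
)
from .reference import GeneRecord, merge_namespaces, panel_to_var

TRUTH_COLUMNS = [
    "barcode",
    "species",
    "cell_type",
    "is_doublet",
    "doublet_score",
    "soup_fraction_realized",
    "is_dying",
]


@dataclass(frozen=True)
class CellTypeProgram:
    """One cell type's expression program.

    ``program_genes`` are indices into the species panel whose baseline
    weight is multiplied by ``fold_change``; ``extra`` adds further
    index -> fold multipliers (e.g. an M2 skew on top of a macrophage
    identity program).  ``species`` is 'human', 'pig' or 'both';
    ``proportion`` is the relative frequency among cells of an eligible
    species.
    """

    name: str
    species: str = "both"
    program_genes: tuple[int, ...] = ()
    fold_change: float = 8.0
    extra: tuple[tuple[int, float], ...] = ()
    proportion: float = 1.0

    def __post_init__(self) -> None:
        if self.species not in ("human", "pig", "both"):
            raise ValueError(f"bad species availability: {self.species!r}")
        if self.fold_change <= 0 or self.proportion <= 0:
            raise ValueError("fold_change and proportion must be positive")

    def fold_map(self) -> dict[int, float]:
        folds = {int(g): float(self.fold_change) for g in self.program_genes}
        for g, f in self.extra:
            folds[int(g)] = folds.get(int(g), 1.0) * float(f)
        return folds


def default_cell_types() -> tuple[CellTypeProgram, ...]:
    """A small immune census: T/B/NK/monocyte plus an M2-skewed macrophage.

    Identity programs sit on disjoint gene blocks outside the homolog and
    mitochondrial regions; macrophages additionally carry a 4-fold boost on
    the M2 block (indices 200-207) while the M1 block (220-227) stays at
    baseline, emulating an anti-inflammatory polarization state.
    """
    return (
        CellTypeProgram("T_cell", "both", tuple(range(100, 110)), proportion=0.30),
        CellTypeProgram("B_cell", "both", tuple(range(120, 130)), proportion=0.20),
        CellTypeProgram("NK_cell", "both", tuple(range(140, 150)), proportion=0.10),
        CellTypeProgram("monocyte", "both", tuple(range(160, 170)), proportion=0.20),
        CellTypeProgram(
            "macrophage",
            "both",
            tuple(range(180, 190)),
            extra=tuple((g, 4.0) for g in range(200, 208)),
            proportion=0.20,
        ),
    )


def default_polarization_indices() -> dict[str, tuple[int, ...]]:
    """Panel indices of the M1/M2 blocks used by :func:`default_cell_types`."""
    return {"M2": tuple(range(200, 208)), "M1": tuple(range(220, 228))}


@dataclass
class GeneratorConfig:
    """All knobs of the barnyard generator.

    Defaults describe the study conditions the package is validated under:
    ~2% ambient contamination, 2% homolog cross-mapping, 5% doublets, an even
    human/pig mix, and lognormal library sizes around 5,000 UMIs.
    """

    n_genes_per_species: int = 1000
    n_homolog_pairs: int = 17
    cross_map_prob: float = 0.02
    n_cells: int = 2000
    species_mix: float = 0.5  # fraction human
    cell_type_table: tuple[CellTypeProgram, ...] = field(
        default_factory=default_cell_types
    )
    library_size_log_mean: float = float(np.log(5000.0))
    library_size_log_sd: float = 0.4
    soup_fraction: float = 0.02
    doublet_rate: float = 0.05
    doublet_score_noise_sd: float = 0.08
    seed: int = 0
    # shape of the expression model
    dispersion: float = 0.25  # gamma CV^2 of per-cell gene weights
    base_expression_log_sd: float = 1.0
    # mitochondrial structure
    n_mito_genes: int = 10
    mito_base_fraction: float = 0.05
    dying_cell_fraction: float = 0.02
    dying_mito_fraction: float = 0.30

    def __post_init__(self) -> None:
        for name in ("cross_map_prob", "species_mix", "soup_fraction", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_cells <= 0 or self.n_genes_per_species <= 0:
            raise ValueError("n_cells and n_genes_per_species must be positive")
        if self.n_homolog_pairs > self.n_genes_per_species - self.n_mito_genes:
            raise ValueError(
                "n_homolog_pairs must leave room outside the mitochondrial block"
            )
        if self.doublet_score_noise_sd <= 0:
            raise ValueError("doublet_score_noise_sd must be positive")
        if not self.cell_type_table:
            raise ValueError("cell_type_table is empty")
        n_regular = self.n_genes_per_species - self.n_mito_genes
        for t in self.cell_type_table:
            bad = [g for g in t.fold_map() if not 0 <= g < n_regular]
            if bad:
                raise ValueError(
                    f"cell type {t.name!r} references genes outside the "
                    f"non-mitochondrial panel: {bad}"
                )

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def build_panels(config: GeneratorConfig) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Human and pig gene panels sharing symbols (homology-friendly).

    Symbols are ``GENE0000`` ... with the last ``n_mito_genes`` named
    ``MT-ND0000`` ... and flagged mitochondrial.  The first
    ``n_homolog_pairs`` indices form the homologous pairs between species.
    """
    n, n_mito = config.n_genes_per_species, config.n_mito_genes
    panels = []
    for tag in (HUMAN_TAG, PIG_TAG):
        panel = []
        for i in range(n):
            if i >= n - n_mito:
                sym = f"MT-ND{i:04d}"
                mito = True
            else:
                sym = f"GENE{i:04d}"
                mito = False
            panel.append(GeneRecord(f"{tag}_g{i:04d}", sym, tag, is_mito=mito))
        panels.append(panel)
    return panels[0], panels[1]


def polarization_gene_sets(config: GeneratorConfig) -> dict[str, dict[str, list[str]]]:
    """Tagged M1/M2 gene names per species for the default panel layout."""
    idx = default_polarization_indices()
    out: dict[str, dict[str, list[str]]] = {}
    for species, tag in SPECIES_TO_TAG.items():
        out[species] = {
            name: [f"{tag}-GENE{i:04d}" for i in genes] for name, genes in idx.items()
        }
    return out


def expected_type_profile(
    config: GeneratorConfig, species: str, cell_type: str, dying: bool = False
) -> pd.Series:
    """Expected relative expression of one (species, type) over the hybrid panel.

    Reconstructs the generating weights for the given config (the panel
    stream is the first child of the config seed, as in
    :func:`generate_barnyard`) and returns them normalized to sum 1, indexed
    by tagged gene name.  This is the ground-truth profile that signature
    estimators should recover.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_panel = np.random.default_rng(ss.spawn(6)[0])
    sampler = _CellSampler(config, rng_panel)
    w = sampler.type_weights(species, cell_type, dying)
    return pd.Series(w / w.sum(), index=sampler.var.index)


class _CellSampler:
    """Draws single-cell count vectors over the full hybrid gene space.

    Precomputes, per (species, cell type, dying-flag), a weight vector over
    the 2n hybrid genes; a cell is sampled by gamma-perturbing the weights
    (shape 1/d, scale d, so the mean is preserved and CV^2 = d) and drawing a
    multinomial with a lognormal total.
    """

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        n = config.n_genes_per_species
        self.n = n
        human_panel, pig_panel = build_panels(config)
        self.panel = merge_namespaces(human_panel, pig_panel)
        self.var = panel_to_var(self.panel)

        # species baseline weights (shared across types within a species)
        base = {}
        mito = np.zeros(n, dtype=bool)
        mito[n - config.n_mito_genes :] = True
        for species in ("human", "pig"):
            w = rng.lognormal(0.0, config.base_expression_log_sd, size=n)
            base[species] = self._rescale_mito(w, mito, config.mito_base_fraction)
        self.base = base
        self.mito_mask_panel = mito

        # eligible types and normalized proportions per species
        self.types_by_species: dict[str, list[CellTypeProgram]] = {}
        self.type_probs: dict[str, np.ndarray] = {}
        for species in ("human", "pig"):
            types = [
                t for t in config.cell_type_table if t.species in (species, "both")
            ]
            if not types:
                raise ValueError(f"no cell types available for species {species!r}")
            p = np.array([t.proportion for t in types], dtype=float)
            self.types_by_species[species] = types
            self.type_probs[species] = p / p.sum()

        self._weights_cache: dict[tuple[str, str, bool], np.ndarray] = {}

    @staticmethod
    def _rescale_mito(w: np.ndarray, mito: np.ndarray, target: float) -> np.ndarray:
        """Scale mitochondrial weights so their expected share equals target."""
        w = w.copy()
        m, r = w[mito].sum(), w[~mito].sum()
        if m > 0 and 0 < target < 1:
            w[mito] *= target * r / ((1.0 - target) * m)
        return w

    def type_weights(self, species: str, type_name: str, dying: bool) -> np.ndarray:
        """Expected gene-weight vector over the 2n hybrid genes (unnormalized)."""
        key = (species, type_name, dying)
        if key in self._weights_cache:
            return self._weights_cache[key]
        types = {t.name: t for t in self.types_by_species[species]}
        t = types[type_name]
        w = self.base[species].copy()
        for g, f in t.fold_map().items():
            w[g] *= f
        if dying:
            w = self._rescale_mito(
                w, self.mito_mask_panel, self.config.dying_mito_fraction
            )
        full = np.zeros(2 * self.n)
        offset = 0 if species == "human" else self.n
        full[offset : offset + self.n] = w
        self._weights_cache[key] = full
        return full

    def sample_assignments(
        self, n_cells: int, rng: np.random.Generator
    ) -> pd.DataFrame:
        """Draw (species, cell_type, is_dying) for ``n_cells`` cells."""
        species = np.where(
            rng.random(n_cells) < self.config.species_mix, "human", "pig"
        )
        cell_type = np.empty(n_cells, dtype=object)
        for sp_name in ("human", "pig"):
            idx = np.flatnonzero(species == sp_name)
            if idx.size:
                types = self.types_by_species[sp_name]
                choice = rng.choice(
                    len(types), size=idx.size, p=self.type_probs[sp_name]
                )
                cell_type[idx] = [types[c].name for c in choice]
        dying = rng.random(n_cells) < self.config.dying_cell_fraction
        return pd.DataFrame(
            {"species": species, "cell_type": cell_type, "is_dying": dying}
        )

    def sample_counts(
        self, assignments: pd.DataFrame, rng: np.random.Generator
    ) -> np.ndarray:
        """Dense (cells x 2n) integer count matrix, no contamination applied."""
        cfg = self.config
        n_cells = len(assignments)
        counts = np.zeros((n_cells, 2 * self.n), dtype=np.int64)
        totals = np.maximum(
            1,
            np.round(
                rng.lognormal(
                    cfg.library_size_log_mean, cfg.library_size_log_sd, size=n_cells
                )
            ).astype(np.int64),
        )
        shape = 1.0 / cfg.dispersion if cfg.dispersion > 0 else None
        for i, row in enumerate(assignments.itertuples(index=False)):
            w = self.type_weights(row.species, row.cell_type, row.is_dying)
            live = w > 0
            wl = w[live]
            if shape is not None:
                wl = wl * rng.gamma(shape, cfg.dispersion, size=wl.size)
            p = wl / wl.sum()
            counts[i, live] = rng.multinomial(totals[i], p)
        return counts

    def homolog_columns(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.config.n_homolog_pairs
        return np.arange(k), self.n + np.arange(k)


def _apply_cross_mapping(
    counts: np.ndarray,
    sampler: _CellSampler,
    prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reassign homolog-pair reads to the partner gene with probability ``prob``.

    Conserves the total count of every cell: reads only move between the two
    partner columns.
    """
    if prob <= 0 or sampler.config.n_homolog_pairs == 0:
        return counts
    h_cols, p_cols = sampler.homolog_columns()
    out = counts.copy()
    moved_hp = rng.binomial(counts[:, h_cols], prob)
    moved_ph = rng.binomial(counts[:, p_cols], prob)
    out[:, h_cols] += moved_ph - moved_hp
    out[:, p_cols] += moved_hp - moved_ph
    return out


def _apply_soup(
    counts: np.ndarray, soup_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a binomial share of each cell's counts with ambient draws.

    The ambient profile is the library-size-weighted mean of all cells'
    profiles (i.e. the pooled count vector, normalized).  Totals per cell are
    conserved; the realized per-cell soup fraction is returned.
    """
    totals = counts.sum(axis=1)
    if soup_fraction <= 0 or counts.sum() == 0:
        return counts, np.zeros(len(counts))
    pool = counts.sum(axis=0).astype(float)
    pool_p = pool / pool.sum()
    out = counts.copy()
    realized = np.zeros(len(counts))
    for i in range(len(counts)):
        total = int(totals[i])
        if total == 0:
            continue
        n_soup = int(rng.binomial(total, soup_fraction))
        if n_soup == 0:
            continue
        removed = rng.multivariate_hypergeometric(
            out[i], n_soup, method="marginals"
        )
        out[i] -= removed
        out[i] += rng.multinomial(n_soup, pool_p)
        realized[i] = n_soup / total
    return out, realized


def generate_barnyard(
    config: GeneratorConfig,
) -> tuple[TaggedCountMatrix, pd.DataFrame]:
    """Generate a mixed-species single-cell dataset with ground truth.

    Returns the species-tagged count matrix and a truth table aligned to its
    barcodes (columns: barcode, species, cell_type, is_doublet,
    doublet_score, soup_fraction_realized, is_dying).  Fully reproducible
    from ``config.seed``; the base counts, cross-mapping, soup, doublet and
    score draws use independent child streams, so e.g. changing
    ``cross_map_prob`` alone never changes any cell's total.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_panel, rng_base, rng_cross, rng_soup, rng_doub, rng_score = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    sampler = _CellSampler(config, rng_panel)
    n_doublets = int(rng_doub.binomial(config.n_cells, config.doublet_rate))
    n_draws = config.n_cells + n_doublets

    assignments = sampler.sample_assignments(n_draws, rng_base)
    counts = sampler.sample_counts(assignments, rng_base)
    counts = _apply_cross_mapping(counts, sampler, config.cross_map_prob, rng_cross)
    counts, soup_realized = _apply_soup(counts, config.soup_fraction, rng_soup)

    # last n_doublets draws are merged into randomly chosen host barcodes
    hosts = (
        rng_doub.choice(config.n_cells, size=n_doublets, replace=False)
        if n_doublets
        else np.array([], dtype=int)
    )
    for j, host in enumerate(hosts):
        extra = config.n_cells + j
        t_host, t_extra = counts[host].sum(), counts[extra].sum()
        counts[host] += counts[extra]
        denom = t_host + t_extra
        if denom:
            soup_realized[host] = (
                soup_realized[host] * t_host + soup_realized[extra] * t_extra
            ) / denom
    counts = counts[: config.n_cells]

    is_doublet = np.zeros(config.n_cells, dtype=bool)
    is_doublet[hosts] = True
    scores = np.clip(
        np.abs(rng_score.normal(0.0, config.doublet_score_noise_sd, config.n_cells)),
        0.0,
        1.0,
    )
    scores[is_doublet] = 1.0

    barcodes = pd.Index(
        [f"BC{i:06d}" for i in range(config.n_cells)], name="barcode"
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "species": assignments["species"].to_numpy()[: config.n_cells],
            "cell_type": assignments["cell_type"].to_numpy()[: config.n_cells],
            "is_doublet": is_doublet,
            "doublet_score": scores,
            "soup_fraction_realized": soup_realized[: config.n_cells],
            "is_dying": assignments["is_dying"].to_numpy()[: config.n_cells],
        }
    )
    matrix = TaggedCountMatrix(sp.csr_matrix(counts), barcodes, sampler.var)
    return matrix, truth


def generate_visium_like(
    config: GeneratorConfig,
    grid,
    abundance_truth: pd.DataFrame,
    sampling: str = "poisson",
) -> tuple[SpotMatrix, pd.DataFrame]:
    """Generate Visium-style spot counts from known cell-type abundances.

    Parameters
    ----------
    grid
        Either ``(n_rows, n_cols)`` (spots laid out row-major) or an explicit
        sequence of ``(array_row, array_col)`` pairs, one per spot.
    abundance_truth
        Spots x cell-type non-negative reals.  Columns may be plain type
        names (species chosen per cell by ``species_mix``) or
        ``"<species>:<type>"`` to pin the species.
    sampling
        ``"poisson"`` draws the per-spot number of cells of each type as
        Poisson with the given mean; ``"exact"`` places exactly the (integer)
        abundance.

    Returns the spot matrix (coordinates on the grid) and the *realized*
    spots x types cell-count table — the ground truth for deconvolution
    checks.  Cells are generated as in :func:`generate_barnyard` including
    homolog cross-mapping, but without droplet artifacts (soup, doublets),
    which have no analogue on a capture spot.
    """
    if sampling not in ("poisson", "exact"):
        raise ValueError("sampling must be 'poisson' or 'exact'")
    coords = (
        [(r, c) for r in range(grid[0]) for c in range(grid[1])]
        if isinstance(grid, tuple) and len(grid) == 2 and np.isscalar(grid[0])
        else [tuple(rc) for rc in grid]
    )
    ab = np.asarray(abundance_truth, dtype=float)
    if ab.ndim != 2 or ab.shape[0] != len(coords):
        raise ValueError(
            f"abundance_truth has {ab.shape[0]} rows but the grid has "
            f"{len(coords)} spots"
        )
    if (ab < 0).any():
        raise ValueError("abundance_truth must be non-negative")
    type_cols = list(abundance_truth.columns)

    # the panel (baseline expression weights) is a function of the config
    # alone, shared with generate_barnyard; only the cell draws use an
    # independent spatial stream
    rng_panel = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[0])
    ss = np.random.SeedSequence([config.seed, 0x5107])
    rng_cells, rng_cross = (np.random.default_rng(s) for s in ss.spawn(2))
    sampler = _CellSampler(config, rng_panel)

    n_spots = len(coords)
    counts = np.zeros((n_spots, 2 * sampler.n), dtype=np.int64)
    realized = pd.DataFrame(
        0, index=range(n_spots), columns=type_cols, dtype=int
    )
    known = {t.name for t in config.cell_type_table}

    for s in range(n_spots):
        for j, col in enumerate(type_cols):
            species_pin, _, type_name = (
                col.partition(":")[0:3] if ":" in col else (None, None, col)
            )
            if type_name not in known:
                raise KeyError(f"unknown cell type in abundance columns: {type_name!r}")
            mean = ab[s, j]
            n_cells = (
                int(rng_cells.poisson(mean))
                if sampling == "poisson"
                else int(round(mean))
            )
            if n_cells == 0:
                continue
            realized.iloc[s, j] += n_cells
            if species_pin:
                species = np.full(n_cells, species_pin, dtype=object)
            else:
                species = np.where(
                    rng_cells.random(n_cells) < config.species_mix, "human", "pig"
                )
            assign = pd.DataFrame(
                {
                    "species": species,
                    "cell_type": [type_name] * n_cells,
                    "is_dying": [False] * n_cells,
                }
            )
            cell_counts = sampler.sample_counts(assign, rng_cells)
            cell_counts = _apply_cross_mapping(
                cell_counts, sampler, config.cross_map_prob, rng_cross
            )
            counts[s] += cell_counts.sum(axis=0)

    barcodes = pd.Index([f"SPOT{i:05d}" for i in range(n_spots)], name="barcode")
    positions = pd.DataFrame(
        {
            "in_tissue": 1,
            "array_row": [r for r, _ in coords],
            "array_col": [c for _, c in coords],
            "pixel_row": [float(r) * 100.0 for r, _ in coords],
            "pixel_col": [float(c) * 100.0 for _, c in coords],
        },
        index=barcodes,
    )
    realized.index = barcodes
    spot = SpotMatrix(
        TaggedCountMatrix(sp.csr_matrix(counts), barcodes, sampler.var), positions
    )
    return spot, realized
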