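"""End-to-end orchestration of the xenograft census pipeline.

``run_pipeline`` chains the stages — synthetic data, modified references,
species demultiplexing, QC/cluster census, polarization scoring, spatial
deconvolution — under a single :class:`RunConfig`, records a provenance log
(parameters, input digests, seeds, counts in/out per stage), and optionally
writes every artifact to an output directory.  All randomness derives from
``RunConfig.seed``, so a config reruns bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census as census_mod
from . import demux as demux_mod
from . import io as io_mod
from . import polarization as pol_mod
from . import spatial as spatial_mod
from .containers import TaggedCountMatrix
from .reference import build_modified_reference
from .simulate import (
    CellTypeProgram,
    GeneratorConfig,
    build_panels,
    generate_barnyard,
    generate_visium_like,
    polarization_gene_sets,
)

ALL_STAGES = ("simulate", "reference", "demux", "census", "polarize", "spatial")

#: Default manual nuclei counts per sampled capture spot (10 spots).
DEFAULT_NUCLEI_COUNTS = (7, 6, 7, 6, 7, 7, 6, 7, 6, 7)


@dataclass
class RunConfig:
    """Every numeric parameter of the pipeline in one serializable object."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qc: census_mod.QCThresholds = field(default_factory=census_mod.QCThresholds)
    # demux
    ratio_low: float = 0.75
    ratio_high: float = 1.33
    gene_removal_threshold: int = 3
    purity_threshold: float = 0.90
    n_reference_cells: int = 400
    # census
    norm_scale: float = 10_000.0
    n_hvg: int = 3000
    n_components: int = 30
    k_neighbors: int = 20
    resolution: float = 0.8
    # polarization
    n_bins: int = 24
    n_ctrl: int = 100
    # spatial
    spatial_grid: tuple[int, int] = (8, 8)
    nuclei_counts: tuple[int, ...] = DEFAULT_NUCLEI_COUNTS

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.ratio_low <= self.ratio_high:
            raise ValueError("need 0 < ratio_low <= ratio_high")
        if not 0.5 <= self.purity_threshold < 1.0:
            raise ValueError("purity_threshold must lie in [0.5, 1)")
        if self.gene_removal_threshold < 0:
            raise ValueError("gene_removal_threshold must be non-negative")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: clean(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (list, tuple)):
                return [clean(x) for x in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            g = dict(d["generator"])
            if "cell_type_table" in g:
                g["cell_type_table"] = tuple(
                    CellTypeProgram(
                        name=t["name"],
                        species=t.get("species", "both"),
                        program_genes=tuple(t.get("program_genes", ())),
                        fold_change=t.get("fold_change", 8.0),
                        extra=tuple(tuple(x) for x in t.get("extra", ())),
                        proportion=t.get("proportion", 1.0),
                    )
                    for t in g["cell_type_table"]
                )
            d["generator"] = GeneratorConfig(**g)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = census_mod.QCThresholds(**d["qc"])
        for key in ("stages", "spatial_grid", "nuclei_counts"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _digest(matrix: TaggedCountMatrix) -> str:
    h = hashlib.sha256()
    X = matrix.X.tocsr()
    for arr in (X.indptr, X.indices, X.data):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update("|".join(matrix.barcodes).encode())
    h.update("|".join(matrix.gene_names).encode())
    return h.hexdigest()


def _child_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the configured stages and return a result bundle.

    The bundle maps stage outputs (matrices, truth, call tables, summaries)
    plus ``provenance`` (one record per stage) and ``evaluation``
    (truth-based accuracy metrics).  Stages absent from ``config.stages``
    are skipped and logged as such; the synthetic dataset is always
    generated, since every other stage consumes it.
    """
    provenance: list[dict] = []
    bundle: dict = {"provenance": provenance, "evaluation": {}}

    # provenance carries no wall-clock fields so a rerun is byte-identical
    def log(stage: str, status: str = "ok", **info) -> None:
        provenance.append({"stage": stage, "status": status, **info})

    def wants(stage: str) -> bool:
        if stage in config.stages:
            return True
        log(stage, status="skipped")
        return False

    # -- simulate ---------------------------------------------------------
    gen = config.generator.with_(seed=config.seed)
    matrix, truth = generate_barnyard(gen)
    truth = truth.set_index("barcode")
    bundle["matrix"], bundle["truth"] = matrix, truth
    log(
        "simulate",
        seed=config.seed,
        n_cells=matrix.n_cells,
        n_genes=matrix.n_genes,
        digest=_digest(matrix),
        params={"soup": gen.soup_fraction, "cross_map": gen.cross_map_prob,
                "doublet_rate": gen.doublet_rate},
    )

    # -- modified references ----------------------------------------------
    human_panel, pig_panel = build_panels(gen)
    if wants("reference"):
        pure = {}
        for species, mix, offset in (("human", 1.0, 1), ("pig", 0.0, 2)):
            pure_cfg = gen.with_(
                seed=_child_seed(config.seed, offset),
                species_mix=mix,
                n_cells=config.n_reference_cells,
                doublet_rate=0.0,
            )
            pure[species], _ = generate_barnyard(pure_cfg)
        modified_human = build_modified_reference(
            human_panel, pure["pig"], config.gene_removal_threshold
        )
        modified_pig = build_modified_reference(
            pig_panel, pure["human"], config.gene_removal_threshold
        )
        bundle["modified_human"], bundle["modified_pig"] = (
            modified_human,
            modified_pig,
        )
        log(
            "reference",
            n_removed_human=len(modified_human.removed),
            n_removed_pig=len(modified_pig.removed),
            threshold=config.gene_removal_threshold,
        )

    # -- demux --------------------------------------------------------------
    if wants("demux"):
        profiles = demux_mod.compute_species_profiles(matrix)
        purity = demux_mod.summarize_purity(profiles, config.purity_threshold)
        bundle["profiles"], bundle["purity"] = profiles, purity
        if "modified_human" in bundle:
            calls = demux_mod.ratio_calls(
                matrix,
                bundle["modified_human"],
                bundle["modified_pig"],
                config.ratio_low,
                config.ratio_high,
            )
            bundle["ratio_calls"] = calls
            bundle["concordance"] = demux_mod.concordance(
                profiles["majority_species"], calls["label"]
            )
        singlet = truth["doublet_score"] <= config.qc.max_doublet_score
        scored = profiles.loc[singlet[singlet].index]
        scored = scored[scored["total"] > 0]
        accuracy = float(
            (scored["majority_species"] == truth.loc[scored.index, "species"]).mean()
        )
        bundle["evaluation"]["majority_accuracy"] = accuracy
        log(
            "demux",
            n_cells=len(profiles),
            single_species_fraction=purity.single_species_transcript_fraction,
            majority_accuracy=accuracy,
        )

    # -- census -------------------------------------------------------------
    if wants("census"):
        filtered, qc_report = census_mod.qc_filter(
            matrix, truth["doublet_score"], config.qc
        )
        normalized = census_mod.normalize_log1p(filtered, config.norm_scale)
        hvg = census_mod.select_hvg(normalized, config.n_hvg)
        embedding, labels = census_mod.embed_and_cluster(
            normalized,
            hvg,
            n_components=config.n_components,
            k_neighbors=config.k_neighbors,
            resolution=config.resolution,
            seed=config.seed,
        )
        markers = census_mod.find_markers(normalized, labels)
        clusters = pd.Series(labels, index=normalized.barcodes, name="cluster")
        bundle.update(
            filtered=filtered,
            qc_report=qc_report,
            normalized=normalized,
            hvg=hvg,
            embedding=embedding,
            clusters=clusters,
            markers=markers,
        )
        from sklearn.metrics import adjusted_rand_score

        truth_types = (
            truth.loc[normalized.barcodes, "species"]
            + ":"
            + truth.loc[normalized.barcodes, "cell_type"]
        )
        ari = float(adjusted_rand_score(truth_types, labels))
        bundle["evaluation"]["clustering_ari"] = ari
        log(
            "census",
            digest_in=_digest(matrix),
            n_cells_retained=filtered.n_cells,
            n_genes_retained=filtered.n_genes,
            n_clusters=int(len(np.unique(labels))),
            ari_vs_truth=ari,
        )

    # -- polarization -------------------------------------------------------
    if wants("polarize"):
        if "normalized" not in bundle:
            raise RuntimeError("polarize requires the census stage")
        normalized = bundle["normalized"]
        sets = polarization_gene_sets(gen)
        frames = []
        cells = truth.loc[normalized.barcodes]
        for species in ("human", "pig"):
            species_mask = (cells["species"] == species).to_numpy()
            macro = (
                species_mask & (cells["cell_type"] == "macrophage").to_numpy()
            )
            if macro.sum() == 0:
                warnings.warn(f"no {species} macrophages passed QC")
                continue
            # bins and scores over the whole species population (the set
            # genes' bin-matched controls only carry signal relative to the
            # full census, not within an already-polarized subpopulation)
            sub = normalized.subset(
                cells=species_mask, genes=normalized.species_mask(species)
            )
            scores = pol_mod.score_m1_m2(
                sub,
                pol_mod.GeneSet("M1", tuple(sets[species]["M1"])),
                pol_mod.GeneSet("M2", tuple(sets[species]["M2"])),
                n_bins=config.n_bins,
                n_ctrl=config.n_ctrl,
                seed=config.seed,
            )
            frames.append(scores.loc[normalized.barcodes[macro]])
        scores = pd.concat(frames)
        summary = pol_mod.compare_polarization(
            scores, truth.loc[scores.index, "species"]
        )
        bundle["polarization_scores"] = scores
        bundle["polarization_summary"] = summary
        frac = {g: s.fraction_m2_gt_m1 for g, s in summary.items()}
        bundle["evaluation"]["fraction_m2_gt_m1"] = frac
        log("polarize", n_macrophages=len(scores), fraction_m2_gt_m1=frac)

    # -- spatial ------------------------------------------------------------
    if wants("spatial"):
        if "filtered" not in bundle:
            raise RuntimeError("spatial requires the census stage")
        filtered = bundle["filtered"]
        type_labels = (
            truth.loc[filtered.barcodes, "species"]
            + ":"
            + truth.loc[filtered.barcodes, "cell_type"]
        )
        signatures = spatial_mod.build_signatures(filtered, type_labels)
        cells_per_spot = spatial_mod.estimate_cells_per_spot(config.nuclei_counts)

        rows, cols = config.spatial_grid
        n_spots = rows * cols
        rng = np.random.default_rng(_child_seed(config.seed, 3))
        types = sorted(type_labels.unique())
        weights = rng.dirichlet(np.ones(len(types)), size=n_spots)
        abundance = pd.DataFrame(
            weights * cells_per_spot, columns=types
        )
        spots, realized = generate_visium_like(
            gen.with_(seed=_child_seed(config.seed, 4)),
            (rows, cols),
            abundance,
        )
        estimated = spatial_mod.deconvolve_spots(
            spots, signatures, cells_per_spot
        )
        marker_table = spatial_mod.impute_marker_abundance(
            spots, ["hg38-GENE0100", "ss11-GENE0120", "hg38-GENE0120"]
        )
        bundle.update(
            signatures=signatures,
            spots=spots,
            spot_truth=realized,
            abundance=estimated,
            spot_markers=marker_table,
        )
        shared = realized.columns.intersection(estimated.columns)
        corr = float(
            np.corrcoef(
                realized[shared].to_numpy().ravel(),
                estimated[shared].to_numpy().ravel(),
            )[0, 1]
        )
        bundle["evaluation"]["spatial_abundance_correlation"] = corr
        log(
            "spatial",
            n_spots=n_spots,
            cells_per_spot=cells_per_spot,
            abundance_correlation=corr,
        )

    if out_dir is not None:
        write_bundle(bundle, out_dir, config)
    return bundle


def write_bundle(bundle: dict, out_dir, config: RunConfig) -> None:
    """Persist a result bundle as plain-text artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    io_mod.write_tagged_matrix(bundle["matrix"], out / "matrix")
    bundle["truth"].reset_index().to_csv(out / "truth.csv", index=False)
    if "profiles" in bundle:
        bundle["profiles"].to_csv(out / "species_profiles.csv")
        p = bundle["purity"]
        (out / "purity_summary.json").write_text(
            json.dumps(dataclasses.asdict(p), indent=2)
        )
    if "ratio_calls" in bundle:
        bundle["ratio_calls"].to_csv(out / "ratio_calls.csv")
        c = bundle["concordance"]
        (out / "concordance.json").write_text(
            json.dumps(
                {
                    "agreement": c.agreement,
                    "n_compared": c.n_compared,
                    "confusion": c.confusion.to_dict(),
                },
                indent=2,
            )
        )
    if "modified_human" in bundle:
        for name in ("modified_human", "modified_pig"):
            bundle[name].report().to_csv(out / f"{name}_removed.csv", index=False)
    if "clusters" in bundle:
        bundle["clusters"].to_csv(out / "clusters.csv")
        (out / "qc_report.json").write_text(
            json.dumps(bundle["qc_report"].to_dict(), indent=2)
        )
        mdir = out / "markers"
        mdir.mkdir(exist_ok=True)
        for cluster, table in bundle["markers"].items():
            table.to_csv(mdir / f"cluster_{cluster}.csv", index=False)
    if "polarization_scores" in bundle:
        bundle["polarization_scores"].to_csv(out / "polarization_scores.csv")
        (out / "polarization_summary.json").write_text(
            json.dumps(
                {
                    g: dataclasses.asdict(s)
                    for g, s in bundle["polarization_summary"].items()
                },
                indent=2,
            )
        )
    if "abundance" in bundle:
        io_mod.write_spot_matrix(bundle["spots"], out / "spots")
        bundle["abundance"].to_csv(out / "spot_abundance.csv")
        bundle["spot_truth"].to_csv(out / "spot_truth.csv")
        bundle["spot_markers"].to_csv(out / "spot_markers.csv")
    (out / "evaluation.json").write_text(
        json.dumps(bundle["evaluation"], indent=2)
    )
    (out / "provenance.json").write_text(json.dumps(bundle["provenance"], indent=2))
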