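# xenocensus

Species demultiplexing and immune census for mixed-species (pig-to-human
xenograft) single-cell and spatial transcriptomics.

When tissue from a xenograft is sequenced, every droplet may contain human
or pig material — or a mixture of both. Aligning reads against a *hybrid*
reference (human hg38 + pig ss11) gives every gene a species tag
(`hg38-CD3E`, `ss11-CD19`), and the whole transcriptome of a cell then
carries its species signal. `xenocensus` implements the computations that
sit on top of such species-tagged count matrices:

- **Per-cell species classification**, two ways:
  - *majority transcript species*: a cell's purity is
    `p = max(t_h, t_p) / (t_h + t_p)` over its human/pig transcript totals,
    and the majority species is the argmax;
  - *modified-reference gene ratio*: genes that attract more than 3 summed
    counts from a pure sample of the *opposite* species are removed from
    each panel (homology artifacts); a cell with `r = g_h / g_p` detected
    genes under the two modified references is called porcine if
    `r < 0.75`, human if `r > 1.33`, and ambiguous in between.
- **Purity summaries and cross-mapping diagnostics**: the fraction of all
  transcripts that belong to their cell's majority species, the fraction of
  cells above a purity threshold (default strict `> 0.90`), inter-method
  concordance, and per-cluster reports of which opposite-species genes
  absorb reads.
- **A droplet census**: strict QC (features `< 200` or `> 3000`, mito
  fraction `> 12%`, doublet score `> 0.3` removed; genes in `< 5` cells
  dropped), log1p normalization at scale 10,000, top-3,000 variable genes by
  coefficient of variation, 30 principal components, a KNN graph with
  shared-nearest-neighbor (Jaccard) weights, modularity (Leiden)
  clustering, and one-vs-rest Wilcoxon rank-sum markers with
  Benjamini–Hochberg correction.
- **M1/M2 macrophage polarization scoring**: per-cell module scores —
  mean expression of a gene set minus the mean of expression-bin-matched
  control genes — computed per species, and an M2-vs-M1 comparison.
- **Spot-level mapping**: cells-per-spot as the mean of manual nuclei
  counts, per-type reference signatures (mean library-size-normalized
  expression), a deterministic non-negative least squares surrogate for
  spot deconvolution, and direct species-tagged marker imputation for cell
  types too rare to deconvolve.
- **A synthetic barnyard generator** with full ground truth: two species'
  panels with homologous gene pairs and a cross-mapping probability,
  overdispersed type-specific expression programs (including an M2-skewed
  macrophage program), ambient "soup" contamination, doublets with a score
  column, dying cells with elevated mitochondrial fraction, and
  Visium-style spot mixtures at known cell-type abundance.

All estimators follow scikit-learn conventions (`fit`/`transform`/`predict`,
`get_params`, fitted attributes with trailing underscores) with thin
functional wrappers.

## Worked example

```python
from xenocensus import (GeneratorConfig, generate_barnyard,
                        compute_species_profiles, summarize_purity,
                        classify_by_ratio)

cfg = GeneratorConfig(seed=1)          # 2,000 cells, 2% soup, 2% cross-mapping
matrix, truth = generate_barnyard(cfg)
profiles = compute_species_profiles(matrix)
s = summarize_purity(profiles)
print(f"{100*s.single_species_transcript_fraction:.1f}% of "
      f"{s.total_transcripts:,} transcripts associated with a single species")
print(f"{100*s.cells_above_purity_threshold_fraction:.1f}% of cells possessed "
      f">{100*s.purity_threshold:.0f}% of transcripts from one species")
call = classify_by_ratio(74, 100)
print(f"ratio {call.ratio:.2f} -> {call.label}")
```

prints

```
97.5% of 11,118,049 transcripts associated with a single species
98.0% of cells possessed >90% of transcripts from one species
ratio 0.74 -> porcine
```

The first two lines are dataset-level purity statistics: even with 2%
ambient contamination and homologous gene pairs, nearly every transcript
sits in a cell dominated by its own species. The third line is the
gene-ratio classifier at its boundary: 74 human genes against 100 pig genes
is a ratio of 0.74, just below the 0.75 cutoff, so the cell is called
porcine.

The full pipeline (simulation → modified references → demultiplexing →
census → polarization → spatial) runs under one config:

```python
from xenocensus import RunConfig, run_pipeline
bundle = run_pipeline(RunConfig(seed=1), out_dir="out")
print(bundle["evaluation"])
```

or from the shell: `xenocensus run --out out --seed 1`.

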