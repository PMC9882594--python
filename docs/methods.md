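# Methods

This note documents the models and procedures implemented in `xenocensus`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data checks do and do not demonstrate.

## The species-tagged namespace

Two species' gene panels are concatenated into one namespace in which every
display name is `<tag>-<symbol>` with tags `hg38` (human) and `ss11` (pig).
The same symbol may appear once per species (`hg38-CD19` and `ss11-CD19` are
distinct genes); a collision of *tagged* names is an error. Symbols with the
`MT-` prefix carry the mitochondrial flag; the flag is set by the reader and
by the generator, which keeps `features.tsv` at the standard three Cell
Ranger columns (id, name, feature type).

## Synthetic barnyard generator

The generator emulates the statistical structure of a mixed-species droplet
experiment; it is the oracle for every recovery test, so its construction is
spelled out in full.

**Expression model.** Each species has baseline gene weights
`w_g ~ LogNormal(0, σ_base)` (σ_base = 1 by default). A cell type multiplies
a block of program genes by a fold change (default 8 for identity programs);
the macrophage type additionally carries a 4-fold boost on an M2 gene block
while its M1 block stays at baseline, emulating an anti-inflammatory
polarization state. A cell of type *t* draws per-gene weights
`w_g · Gamma(1/d, d)` (dispersion d = 0.25, mean-preserving, CV² = d) and a
multinomial count vector with total `~ LogNormal(log 5000, 0.4)`. The gamma
perturbation makes marginal counts overdispersed (negative-binomial-like),
which is what gives the coefficient-of-variation gene ranking something real
to rank.

**Homolog cross-mapping.** The first `n_homolog_pairs` indices of the two
panels are partners (default 17 pairs of 1,000 genes per species). After
base counts are drawn, each count on a partnered gene moves to its partner
with probability `cross_map_prob` (default 0.02), by a binomial split in
each direction. Reassignment moves counts between partner columns and never
creates or destroys them, so per-cell totals are conserved — this is tested
directly, which is why the generator draws its base counts, cross-mapping,
soup, doublet and score randomness from independent child streams of the
seed: changing one knob cannot perturb another channel's draws.

**Ambient soup.** The ambient profile is the pooled (library-size-weighted
mean) profile of all cells. For each cell, `n ~ Binomial(total, soup)`
counts (soup = 0.02) are removed by a multivariate hypergeometric draw from
the cell's own counts and replaced by a multinomial draw from the pool;
totals are conserved and the realized per-cell fraction is recorded in the
truth table. Soup is simulated, not corrected: the package deliberately
contains no ambient-RNA removal.

**Doublets and scores.** A binomial number of doublets (rate 0.05) is
formed by summing an extra, independently drawn cell into a host barcode.
True doublets receive score 1.0; singlets receive `|N(0, 0.08)|` clipped to
[0, 1], a calibrated stand-in for an external doublet-scoring tool — the
census consumes the score column and applies only the 0.3 cutoff, it does
not implement doublet detection. The truth species of a doublet is the
host cell's; a cross-species doublet has no single true species, so
truth-based accuracy is evaluated on barcodes passing the score filter.

**Dying cells.** A small subpopulation (2%) has its mitochondrial weight
share rescaled to 30% (healthy cells: 5%), so the 12% mitochondrial QC
filter has both pass and fail cases.

**Spatial spots.** `generate_visium_like` places cells on a spot grid at
given per-type abundances, drawing the number of cells per spot-type either
`Poisson(abundance)` (default) or exactly (`sampling="exact"`, for
single-cell-resolution checks). Spot cells share the barnyard expression
model and cross-mapping, but not soup or doublets, which are droplet
phenomena with no analogue on a capture spot. The panel's baseline weights
are a function of the config seed alone and are shared between the
single-cell and spatial generators, so reference signatures and spot
content describe the same synthetic biology.

## Species demultiplexing

**Majority method.** Per-cell transcript totals by species; purity is the
majority share (≥ 0.5 whenever the cell has counts); exact 50/50 is a tie
and contributes nothing to the single-species transcript numerator, since a
tied cell is not associated with a single species. Zero-count barcodes are
flagged undetermined and excluded from summaries. The purity-threshold
comparison is strict (`> 0.90`).

**Modified-reference ratio method.** The removal rule sums a gene's counts
over the *whole* pure opposite-species sample and removes the gene iff the
sum is strictly greater than 3 (a gene at exactly 3 is retained); a per-cell
reading would make the rule depend trivially on sample size. "Genes
detected" under a modified reference means count ≥ 1 among that species'
retained genes — gene-level detection is robust to library size, which is
the point of a ratio of mapped genes. The decision regions partition
[0, ∞]: ratio < 0.75 porcine, > 1.33 human, the closed band in between
ambiguous. A zero pig denominator with human genes present is +∞ (human);
the symmetric case is 0 (porcine); both zero is unassignable and labeled
ambiguous. The rule is applied to QC-passing cells by the pipeline; the
builder itself accepts any matrix the caller asserts is pure.

**Diagnostics.** Concordance is the agreement fraction on barcodes where
both methods produced a species call, with a 3×3 confusion matrix over
{human, porcine, ambiguous}; it is symmetric by construction. The
per-cluster cross-mapping report ranks opposite-species genes by count with
a cumulative fraction (both the count ranking and the panel fraction are
reported, since the inclusion criterion for "offending genes" is a matter
of convention), quantifying how few homologous genes absorb most
cross-species reads. Counts are never corrected for homolog misassignment.

## Census

Defaults follow the standard droplet workflow: strict QC cutoffs
(features < 200 or > 3000, mitochondrial fraction > 12%, doublet score
> 0.3; genes in < 5 retained cells dropped — all comparisons strict, so a
cell at exactly 12% or 0.30 is retained), log1p normalization
`log(1 + 10^4 · c/total)`, CV ranking of normalized expression with zero-mean
genes ranked last and ties broken by gene name, centering/unit-scaling of
variable genes clipped at ±10, 30 principal components (full SVD, hence
deterministic), a KNN graph (k = 20) reweighted by Jaccard overlap of
neighbor sets including self, edges below 1/15 pruned, and Leiden
RB-configuration modularity optimization at resolution 0.8 with a fixed
seed. k, resolution, the clip value and the prune threshold are not
prescribed by the workflow's printed parameters; they follow common
single-cell toolchain defaults and are exposed in the config. A
single-nucleus QC profile (feature cap 2,500, mito 15%) is provided as a
preset. Markers are one-vs-rest Mann–Whitney U (asymptotic, tie- and
continuity-corrected), log fold-change of expm1-backtransformed means, and
Benjamini–Hochberg adjustment per cluster.

## Polarization scores

A module score for gene set *S* is `mean_g∈S(x_cg) − mean_g∈C(x_cg)` where
the control pool *C* draws `n_ctrl` genes (default 100) from each set gene's
average-expression bin (24 equal-frequency bins). Bin-matching cancels
depth and abundance effects: if every gene behaved like its bin's average
the score would be zero. Scoring is species-stratified — human cells with
hg38-tagged lists, pig cells with ss11-tagged lists — because cross-species
expression levels are not directly comparable, and the bins are computed
over the whole species' census, not within an already-polarized
subpopulation (controls drawn from a population in which the set genes are
uniformly high would cancel the very signal being measured). The package
ships no fixed M1/M2 lists; lists are configuration (two-column text), and
the generator exposes the tagged names of its planted M1/M2 blocks. The
M2-vs-M1 comparison reports per-group means, the fraction of cells with
strictly `score_M2 > score_M1` (ties count against, which is conservative),
and a Wilcoxon signed-rank test of the per-cell difference.

## Spatial mapping

Cells-per-spot is the arithmetic mean of manual nuclei counts over sampled
spots. Reference signatures are per-type means of library-size-normalized
single-cell profiles, with types under 10 cells flagged low-confidence; this
is a deliberate deterministic surrogate for regression-based signature
estimation. Deconvolution is per-spot non-negative least squares on shared
genes (mitochondrial genes removed from spots first), both sides
sum-normalized, with coefficients rescaled to sum to cells-per-spot — a
convex, deterministic surrogate for Bayesian deconvolution. It recovers
*count-mass* composition: a type's coefficient is proportional to the count
mass it contributes, which equals cell numbers only insofar as library
sizes are comparable; with ~6 cells per spot the per-spot estimate is
noisy, and recovery checks therefore aggregate replicate spots. Abundances
are surrogate estimates, not posterior cell counts. Cell types too rare to
contribute a reliable signature are localized directly by species-tagged
marker counts per spot with a detection threshold (default ≥ 1 count) —
the species tag is what makes a single marker informative in mixed tissue.

## Numerical and design choices

- Strict inequalities everywhere a rule is printed as strict
  (> 3 counts, < 200 / > 3000 features, > 12% mito, > 0.3 score, < 0.75 /
  > 1.33 ratio, > 0.90 purity).
- Deterministic tie-breaks: CV ties by gene name; marker tables sorted by
  adjusted p then descending log fold-change with stable sorts; Leiden and
  PCA seeded; module-score control draws seeded.
- Degenerate inputs: zero-count cells are flagged and excluded from purity
  summaries, rejected by normalization (they should have been QC-filtered);
  an empty opposite-species sample retains all genes with a warning; an
  all-zero spot deconvolves to an all-zero row; fewer cells than requested
  components reduces the PCA rank with a warning.
- The provenance log of `run_pipeline` records parameters, seeds, matrix
  digests and counts per stage and contains no wall-clock fields, so a
  rerun of the same config writes byte-identical artifacts.

## What the synthetic checks show — and what they do not

Test and acceptance runs use 200–2,000 cells with 300–1,000 genes per
species, 10–17 homolog pairs, and 16–100 spots; these sizes keep the full
suite fast while leaving every statistic well inside its asymptotic regime.
Passing them shows that the decision rules are implemented at their printed
boundaries, that each statistic equals an independent brute-force
recomputation, and that the pipeline recovers planted structure (species,
cell types, polarization skew, spot mixtures) under calibrated
contamination. It does not show performance on real xenograft data: the
generator's programs are cleaner and better separated than real cell types,
its homology is a binary pairing rather than a continuum of sequence
similarity, soup is drawn from the true pooled profile, and alignment
itself (read-level mapping to a hybrid genome) is upstream of this package
entirely — the artifact starts from species-tagged counts.

## Known limitations

- The ratio method's detected-gene counts are derived from the hybrid-
  reference matrix restricted to retained genes, not from a re-alignment to
  each modified reference; with real data the two can differ for reads
  whose best alignment changes when genes are removed.
- NNLS deconvolution has no detection-sensitivity term and no uncertainty;
  collinear signatures (types differing in few genes) spread mass among
  themselves.
- The M1/M2 defaults in the generator are synthetic blocks, not curated
  immunology lists; real analyses must supply their own sets.
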