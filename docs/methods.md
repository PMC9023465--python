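# Methods

## Scope and model

`senindex` identifies senescent tumor cells in single-cell RNA-seq by the
co-occurrence of two transcriptional features: overexpression of canonical
senescence markers and loss of cell-cycle activity. Neither feature alone
is specific — marker genes are noisy at single-cell depth, and quiescent
cells also score low on cell-cycle sets — so the classifier requires both,
three times over (one composite score per cell-cycle collection), and takes
the intersection of the three fourth-quartile calls.

### Senescence signature (module score)

The marker signature is scored with a binned-control module score. Genes
are ranked by mean expression across cells and split into `n_bins`
equal-size bins (default 25; on panels smaller than `10 × n_bins` genes the
bin count is reduced so bins hold ≥ 10 genes on average). For each
signature gene, `n_ctrl_per_gene` control genes (default 100) are drawn
from its bin, excluding signature genes; when the requested draws meet or
exceed the pool size the entire pool is used deterministically, otherwise
draws are with replacement from a seeded generator. The score is the
per-cell mean over signature genes minus the mean over the pooled control
draws. Subtracting expression-matched controls removes the depth/abundance
component that would otherwise dominate a raw signature mean; under a
random signature the score is zero in expectation.

The marker set is *Cdkn2a, Cdkn2b, Cdkn1a, Cdkn1b, Serpine1*. p16^INK4a
and p19^Arf are distinct protein products of the *Cdkn2a* locus and cannot
be separated in gene-level counts; the locus appears once.

### Cell-cycle arrest (ssGSEA) and the composite score

Each cell is scored against three cell-cycle gene sets (K, R, WP) with a
single-sample GSEA: genes are ranked by expression within the cell
(ascending average-tie ranks, so the top gene has rank G); walking the list
in descending expression order, the in-set running sum accumulates
rank^α / Σ rank^α (α = 0.25 by default) and the out-of-set running sum
accumulates 1/(G − |set|); the raw score is the sum over all positions of
their difference. Being rank-based, the score is invariant to monotone
transforms of a cell's profile. When several sets are scored in one call,
raw scores are divided by the global (max − min) of the whole score matrix,
mirroring the usual multi-set normalization; this rescaling is immaterial
for classification because each composite term is min–max normalized anyway.

Arrest is the negation of the cell-cycle score, and the composite score per
collection is

    S_i = minmax(arrest_i) + minmax(senescence_signature),  i ∈ {K, R, WP},

with min–max taken over the full scored population (a per-sample mode
exists for datasets whose arms must be scored separately). A constant
vector min–max-normalizes to all zeros.

### Classification

Q3 of each S_i is the type-7 (linear-interpolation) quantile, the default
of the common statistical environments; a score equal to Q3 counts as
fourth quartile, so each marginal passes at least 25% of cells. A cell is
senescent iff it passes all three marginals. Consequences tested as
invariants: the labeled fraction never exceeds 0.25 + 1/n; permuting cells
permutes labels; raising one cell's senescence signature never lowers its
scores or flips it from senescent to non-senescent.

## Quality control

Cells are kept when mito-fraction ≤ 0.25 and detected genes ≥ 100 —
boundary cells are retained because the removal rules are strict
inequalities. Fractions are computed on the full original gene panel (via
the `reference` argument when gene filtering runs first), so QC sees total
RNA content regardless of filter order. Non-protein-coding genes are then
dropped; genes lacking a biotype count as non-coding with a warning.
Normalization is ln(1 + count/total × 10⁴) per cell. The epithelial gate
removes cells with any *Ptprc* (CD45) detection and no *Epcam* detection;
positivity is detection-based (> 0) because no threshold is better
justified at this depth. Compartment annotation (luminal / basal /
seminal-vesicle markers) is per cell by highest mean marker expression,
ties resolving to the fixed order with a flag; per-cell labels are strictly
finer than cluster-level annotation and keep the package free of a
clustering dependency.

## Differential expression and the survival screen

DE between senescent and non-senescent cells is a two-sided Wilcoxon
rank-sum per gene, tested only where the gene is detected in ≥ 30% of at
least one group (the detection filter is one-group — "at least 30% of
cells" read in the permissive direction). Groups with ≤ 10 cells each use
exact enumeration over rank assignments (ties handled by average ranks);
larger groups use the tie-corrected normal approximation with continuity
correction. Log fold change is ln of the ratio of group means of
expm1(normalized expression) with a 1e-9 pseudocount; BH adjustment runs
across tested genes.

The survival screen computes Pearson r (two-sided t-test p) of each
candidate pro-survival gene against S_K, S_R and S_WP across all cells,
BH-adjusts within each score family, and passes genes with r > 0.4 and
FDR < 0.05 on all three. Zero-variance genes report NA and never pass. The
default candidate panel is the union of the built-in apoptosis,
necroptosis, ferroptosis, parthanatos and pyroptosis lists (48 genes); the
curated panel used in any given study should be supplied explicitly, and
pass counts are sensitive to that choice.

Stratification of senescent cells: Bcl2+ means expression strictly above
the median over senescent cells; Mcl1+ means strictly above Q1 ("the upper
three quartile intervals" — consistent with Mcl1 being broadly expressed;
the opposite reading, at-or-below Q3, is available by flag). Strict
inequalities make boundary and constant-expression cases deterministic
(they classify negative, with a warning when expression is constant).

## Synthetic data

The generator draws negative-binomial counts via a gamma–Poisson mixture:
gene-level baseline means are log-normal (σ_log = 1) around `nb_mean`, with
a shared dispersion θ (`nb_dispersion`); NB variance is μ + μ²/θ. Defaults
— 2000 cells, 1000 genes, 20% senescent, nb_mean 0.5, θ 2.0 — give
per-cell depths and detection rates typical of 10x tumor epithelium at
desk scale. Effects are multiplicative on NB means, applied in senescent
cells only: e^2 on the five senescence markers and the 27 SASP genes,
e^-2 on 60 synthetic cell-cycle genes (three overlapping stand-in
collections K/R/WP of 40 genes each mimic the partial overlap of the
public cell-cycle sets), e^1 on *Mcl1*, and e^1 on *Bcl2* in a
configurable half of the senescent cells. A few baselines are pinned
rather than drawn: compartment markers (8 counts; canonical keratins are
abundant, and a shared baseline makes the planted 4-fold compartment
elevation, not baseline lottery, decide the annotation), *Epcam* (2),
mitochondrial genes (≥ 1), *Mcl1* (3; broadly and highly expressed) and
*Bcl2* (0.5; detected in a subset of cells). *Ptprc* is silent — the
simulated population is purified epithelium. Optional extra dropout is a
separate Bernoulli layer so its effect can be isolated from the NB noise.

Gene roles reuse the real signature symbols so scoring exercises the
actual symbol-intersection code paths. Truth (per-cell senescence,
compartment, Bcl2 subset; per-gene role and realized lfc) aligns
index-for-index with the emitted matrix.

What the generator does **not** emulate: batch effects and integration,
doublets and ambient RNA, imputation artifacts, trajectory structure,
gene–gene correlation beyond the planted group effects, and the scale of a
real 20k-gene panel. Passing recovery tests therefore demonstrates the
correctness and calibration of the pipeline's statistics under its own
assumptions, not performance on any particular real dataset.

## Problem sizes and numerical choices

Test and acceptance runs use 2000 × 1000 for the main recovery analysis,
500 × 400 for each of the 20 zero-effect null calibrations, 800 × 400 for
screen behavior, and a pinned 200 × 300 fixture (strong effects, seed
fixed) for documentation and golden tests; these sizes make the entire
suite run in well under a minute while leaving every statistic far from its
small-sample regime. Oracle comparisons are at 1e-9 (scorers vs brute
force) and 1e-12 (composite-score algebra). One seed fans out to every
random step (control sampling, simulation); all RNG paths go through
numpy's `default_rng`, which is platform-stable. ssGSEA walk order within
exactly tied expression values follows gene index (stable sort) for
determinism; tie interleaving can shift the running sum only at exactly
equal values, which are common in counts but resolved reproducibly.

## Known limitations

- The fourth-quartile rule labels ≈ 20–25% of any population, including
  one with no senescent cells; the classifier is a ranking device, not a
  prevalence estimator. The null-calibration test verifies that such labels
  carry no association with planted structure, but downstream analyses on
  null data still receive ~20% "senescent" cells.
- Quartile cutpoints, min–max ranges and the module-score bins are
  population-dependent: adding or removing cells changes every score.
  Subset analyses must re-run the full scoring, and cross-dataset score
  values are not comparable.
- The DE fold-change convention (expm1 means with pseudocount) differs
  across ecosystems; compare ranks, not magnitudes, against other tools.
- Pro-survival screen results depend on the candidate panel; the built-in
  default is a reasonable union of death-pathway genes, not a curated
  senolytic-target list.
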