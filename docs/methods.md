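# Methods

This note documents the models and procedures implemented in `timeatlas`,
the parameters that matter, the synthetic-data generative model, and the
numerical and design choices made where the procedure was genuinely open.

## Immune subtyping from single-cell events

**Preprocessing.** Raw cytometry intensities are scaled with
`x ↦ asinh(x / cofactor)`; the cofactor defaults to 5, the mass-cytometry
convention (flow data typically uses 150). Transforming twice is an error.
No bead normalization, debarcoding, doublet removal, or spillover
compensation is performed — inputs are assumed cleaned.

**Density-dependent downsampling** runs per sample. Local density is a
k-NN estimate (k = 15): `density_i = k / r_k(i)` with `r_k` the distance to
the k-th neighbour on the clustering markers. Cells are kept with
probability `min(1, target / density_i)`, `target` being the
`target_fraction` quantile (default 0.5) of that sample's densities; sparse
cells are always retained, dense regions are thinned toward the target.
Each sample's random stream is derived from `(seed, sample_id)`, so kept
sets are invariant to which other samples are present. A sample with fewer
cells than k is kept whole with a warning.

**Clustering into nodes.** Pooled downsampled cells are partitioned by
k-means (fixed seed, `n_init=4`) on lineage markers only; activation
markers are reserved for differential statistics. The choice of a
centroid partition (rather than an agglomerative density-normalized
variant) is deliberate: it is deterministic under a seed and directly
oracle-testable. `k` is exposed in configuration (default 500, matching
the conventional cluster-count setting for dense panels); the realized
number of non-empty nodes is reported and may be lower. Node medians and
per-sample cell fractions are computed over **all** cells after assigning
each to its nearest centroid, so per-sample fractions always sum to 1.

**Phenotype annotation.** Fifteen phenotypes are defined by hi/lo gates on
lineage markers (T-cell subsets incl. Tregs and PD-1⁺CTLA-4⁺ exhausted
CD8s, monocyte/macrophage/DC subsets, neutrophils, NK, cancer, cancer
stem, fibroblast, mesothelial, stromal). The representative (landmark)
node per phenotype is the best gate match among nodes satisfying the gate
(positives above, negatives below an arcsinh threshold of 1.0); the score
mildly penalizes off-gate lineage expression (weight 0.25) so nested gates
(CD4 T vs Treg, CD8 T vs exhausted CD8) resolve to distinct landmarks.
Remaining nodes inherit the phenotype of the landmark in their
average-linkage cluster; clusters without a unique landmark fall back to
the nearest landmark in marker space. An unsatisfiable gate raises an
error naming the phenotype.

**Scaffold graph.** The complete graph over node median vectors with
cosine-similarity weights; zero vectors get similarity 0 with a warning.
Exports (node-link JSON) can prune edges below a weight quantile; landmark
flags travel with the nodes so a downstream layout can pin them.
Force-directed layout itself is out of scope.

**Subtyping.** Average-linkage hierarchical clustering of samples on
1 − Pearson correlation between node-fraction profiles, cut at two
clusters. Orientation is content-based: the cluster with the higher mean
partially-exhausted-CD8 fraction is subtype I (the "good" TiME). Without
an orientation score the labels are still deterministic (anchored to the
lexicographically smallest sample id) but semantically arbitrary. Fewer
than 4 samples, or an all-equal profile, is an error.

**Differential statistics.** Per-phenotype paired *t* tests pair
corresponding nodes across the two group-pooled maps; phenotypes with
fewer than two nodes are flagged undefined. The Z ratio z-scores each
feature across all samples in the comparison, takes the difference of
group means of those z-scores, and divides by the SD (ddof 1) of all such
differences *within that comparison*; |Z| ≥ 1.96 is significant. The SD's
scope is exactly the feature set passed in — callers choosing a feature
set choose the comparison. Degenerate comparisons (zero SD of
differences) raise. Raw p-values are primary throughout; a
Benjamini–Hochberg column is optional.

## Neoantigen identification and quantification

**Mutation database.** Source tables (`gene, accession, protein_change,
source`) are unioned; `p.<WT><pos><MUT>` strings are parsed, synonymous
and malformed rows dropped with counts logged, and duplicate sites
collapsed keeping all source tags.

**Windows and candidates.** Each mutation yields a ≤ 29-residue mutant
window (14 flanking residues each side, truncated at protein termini with
the offset preserved — truncation keeps every enumerable sub-peptide). A
reference mismatch at the mutated position is an error. Candidates are
all distinct mutation-containing substrings of length 8–14 (MHC-I) or 15
(MHC-II); a full centered window yields 77 class-I and 15 class-II
candidates.

**Tiers.** With mutant and WT percentile ranks (lower = stronger), class I:
potential ⇔ mutant ≤ 2 and WT > 2; within potential, high ⇔ mutant ≤ 1 and
WT > 1 (the WT clause is implied by potential but kept explicit); others
intermediate. Class II uses 10 and 5. Boundary semantics are exactly
≤ / >. Ranks outside (0, 100] are errors.

**Calling.** A detected mutated peptide becomes a neoantigen call for a
class iff at least one legal-length sub-peptide containing the mutated
residue is tiered intermediate/high on at least one of the patient's typed
alleles of that class ("high"-only mode is available). One call per
(mutation, class, sample): abundance is attributed to the mutation once,
never per sub-peptide, and multiple detected peptides for one mutation sum
their AUCs. Removing alleles can only remove calls. Peaks matching no
window are logged as unassigned. DQ/DP heterodimer pairing is simplified
to per-locus ranks behind the predictor seam.

**Quantification.** Peak AUC is the trapezoidal integral of (time,
intensity) points — exact for the piecewise-linear fixtures used in tests;
negative intensities are errors and unsorted times are sorted with a
warning. iFOT divides each AUC by the sample total and scales by 10⁵ (a
common fraction-of-total convention; configurable). Average neoantigen
abundance is the per-patient, per-class mean AUC over calls; zero calls
yield a missing value with a warning.

**Concordance quadrants.** Each (call, supporting-locus) pair is split
high/low on abundance (cohort-median split over pair AUCs) and high/low on
that locus's protein expression (per-locus cohort-median split across
samples); the median split is a documented stand-in for unstated quadrant
thresholds and the quantile is configurable. The 2×2 of high/high pairs
vs others between subtypes is tested by Pearson χ² without continuity
correction (matching the closed-form oracle in the tests).

**Predictor seam.** Real percentile-rank predictors plug in as
`rank(peptide, allele) → (0, 100]`. The bundled `HashRankPredictor` is
deterministic: background pairs hash into (10.2, 100] — strictly above
every binder threshold — while known true binders are served from an
override table. This makes planted ground truth exactly recoverable and
keeps runs reproducible without network access; it is a toy, not a model
of binding.

## Dual-level signature

Per-gene two-sample Welch *t* (unequal variances — groups of ~6 make
pooling fragile) at each molecular level; genes with raw P below the
threshold (default 0.05) at **both** levels and concordant direction form
the signature. Direction concordance is required by default (switchable):
a gene moving opposite ways at mRNA and protein is not a coherent marker.
Zero-variance genes get t = 0, P = 1, flagged. Centroids are per-subtype
means of row-standardized mRNA over signature genes. Classification is
nearest centroid by Pearson correlation of the within-sample standardized
profile — an ArrayTools-era convention adopted because the original
cross-cohort classifier is not specified; ties break to bad_TiME
(conservative). At least 50% of signature genes must be present
(configurable), with an alias table available for cross-species symbol
mapping. ROC AUC is Mann–Whitney U over positive/negative pairs with ties
counted ½.

## Outcomes

Kaplan–Meier estimation and the log-rank test come from lifelines, as does
the Cox model (Efron tie handling, lifelines' default and the standard
choice for tied event times). Variables pass from univariable fits into
one multivariable model when univariable P < 0.2. The response test is
the two-tailed Fisher exact (probability-mass rule); responders are
mRECIST CR/PR by default, with SD inclusion configurable because the
source narrative never dichotomizes explicitly. Censoring is treated as
alive at last follow-up.

## Synthetic cohort model

Two latent subtypes (I/II, default 6 + 6 of 12 samples) drive every table.

- **Cells.** Each phenotype has a hi/lo archetype on the arcsinh scale
  (hi 3.5, lo 0.3, activation baseline 1.0, noise SD 0.4) — gate-style
  templates without spillover modeling. Sample compositions are Dirichlet
  (concentration 5) with log-linear subtype tilt
  `α_p ∝ exp(0.4 · shift · ±tilt_p)` on immunogenic (+) vs suppressive (−)
  phenotypes; activation programs add `shift × SD` to specific markers in
  specific phenotypes (CD40/CD86 on pDC and GranzymeB/CD27/CD28 on
  exhausted CD8s in subtype I; ICOS on Tregs, PD-L1 on macrophages,
  CXCR4/TIM-3/LAG-3 on CD8s in subtype II). `activation_shift` defaults
  to 3 (strong separation); at 0 no signal exists and downstream recovery
  is at chance.
- **Peptidome.** Random 120-residue proteins; one catalog of missense
  sites (default 40) placed uniformly; one fixed 15–20-mer detected
  peptide per mutation, detected per sample with `detect_prob` (default
  0.5); log-normal AUC (log-mean 9, SD 1) with the log-mean raised by
  `abundance_shift` (default 2) in subtype-I samples. Per mutation one
  9-mer (rank ≤ 1 on HLA-A\*01:01) and one 15-mer (rank ≤ 5 on
  HLA-DRB1\*08:01) are planted on alleles carried by every synthetic
  patient, so truth calls are patient-independent and exactly enumerable.
  MHC locus expression is log-normal per sample × locus with HLA-A/-B and
  HLA-DRB1 predominant and a half-`abundance_shift` bump in subtype I.
- **Expression.** Default 2,000 genes with 137 planted signature genes
  separating subtypes by `signature_effect` (default 3) noise-SD units at
  both levels, random direction per gene; mRNA/protein noise correlated at
  `mrna_protein_corr` (default 0.6); non-signature genes null.
- **Outcomes.** Exponential survival (baseline median 24 months, hazard ×
  `hazard_ratio` = 1.74 for subtype II), independent uniform censoring on
  [0, 72] months, Bernoulli response (0.8 good / 0.1 bad) with mRECIST
  split CR:PR = 3:1 and PD:SD = 4:1.

Identical configurations (including seed) produce byte-identical tables,
verified by content hash. All distributions are plausibility stand-ins:
no spillover or batch structure in cytometry, no spectrum-level MS (peaks
arrive AUC-ready), no sequencing reads, independent genes, exponential
hazards. Passing tests therefore demonstrate correctness of the
*procedures* under a known generative model, not performance on real
tumors.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale as the package's
own defaults for simulation studies: 12-sample cohorts with 100–300 cells
per sample and k = 40 nodes for subtyping; 200 seeded replicates for null
calibration (log-rank, abundance *t*, Cox Wald, Fisher) plus one
20,000-gene global-null screen; 50 replicates for subtype/signature
recovery and 100 for Cox bias (n = 330) and abundance power. Tolerances:
statistical oracles agree to ≤ 1e−9 (cosine to 1e−12); trapezoid AUC is
exact on piecewise-linear input; iFOT totals to 10⁵ within 1e−6 relative.
Tie-breaks: signature ties go to bad_TiME; k-means uses a fixed seed with
4 restarts; subtype orientation falls back to a deterministic anchor when
no phenotype score is given. Degenerate inputs (zero-variance features,
empty margins, < 2 pairs) are flagged or raised rather than silently
propagated.

## Known limitations

FCS files are not read — event tables travel as CSV (cells × markers with
a `sample_id` column). The bundled rank predictor is a reproducibility
device, not a binding model; plug in a real predictor for biological use.
Spectral search, FDR control of identifications, retention-time alignment,
batch correction, and competing-risks survival are out of scope. The
500-cluster setting and the published node count of comparable analyses
need not coincide: the realized non-empty node count is data-dependent,
which is why it is reported rather than asserted.
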