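# Methods

This note documents the statistical machinery, the defaults and the design
choices behind `gsel`, in the order data flows through the package.

## Genotype handling and quality control

Genotypes are biallelic dosages (0/1/2 copies of the alternate allele) with
a single missing sentinel; markers carry a (chromosome, position) map and
are kept sorted with chromosome labels compared naturally. Four input
dialects are read (VCF via cyvcf2, HapMap tab format, PLINK additive `.raw`,
dosage CSV); PLINK `.raw` and bare dosage CSV carry no physical map, so
markers are placed on pseudo-chromosome "0" at their column order, and the
dosage-CSV writer emits a `<file>.map.tsv` sidecar that the reader picks up
to round-trip coordinates exactly.

QC applies two filters in a fixed order so the removal tallies are
well-defined: first markers with missing rate strictly above 10% are
dropped, then markers with MAF at or below 5% (monomorphic markers fall
under the MAF filter but are tallied separately). Both boundaries are
deliberate: *retention* requires MAF > 0.05 and missing rate ≤ 0.10, since
an off-by-boundary choice changes retained counts. The sample set is never
filtered.

### LD-kNNi imputation

Each missing cell is filled from the k nearest samples, with nearness
measured only where it matters: for a target marker, the `l` markers in
highest LD with it (|Pearson r| over pairwise-complete samples) define the
local panel, the distance between two samples is the mean absolute dosage
difference over their shared non-missing panel markers, and the k nearest
samples with an observed genotype at the target vote with weight
1/distance. The weighted mean vote is rounded to the nearest of {0, 1, 2}.
Defaults k = 5, l = 20 follow the published defaults of the method this
scheme implements; ties in distance break toward the lower sample index,
and a cell with no usable neighbour falls back to the marker mode (logged).
Observed cells are never altered. Imputation runs after QC.

## LD, blocks and decay

LD between two markers is the signed Pearson correlation `r` of their
dosage columns, computed within a chromosome and a window (default 1 Mb and
500 markers; pairs outside the window are treated as r = 0). Two uses, two
statistics:

* **Block pruning** thresholds |r|: markers connected by |r| ≥ T edges form
  a haplotype block (connected components of the windowed LD graph), and
  exactly one representative per block is retained — the lowest-position
  marker, ties broken by id. This guarantees the retained-panel size is
  non-increasing as T decreases, pruning is idempotent, and every pruned
  marker has an |r| ≥ T path to its representative.
* **Decay profiling** bins r² by physical distance and reports the distance
  at which mean r² falls to 0.25, linearly interpolated between bin
  mid-points; a profile already below 0.25 in the first bin is flagged as
  such rather than extrapolated.

## GWAS scans and significance subsets

`mlm_scan` is a kinship-corrected single-marker scan. Variance components
are estimated once by REML on the marker-free null model and reused for all
marker tests (the population-parameters-previously-determined shortcut);
each marker is then a generalized-least-squares t-test in the rotated
(eigen) basis, with the residual scale re-estimated per marker so that with
the additive variance forced to zero the test reduces exactly to the OLS
t-test. Raw p-values are reported; the nominal subsets SNP_5 / SNP_1 /
SNP_05 collect markers at p < 0.5 / 0.1 / 0.05 and SNP_NS is the p ≥ 0.05
complement, so SNP_05 and SNP_NS partition the panel and the sweep subsets
are nested.

`farmcpu_scan` is a deliberately simplified re-implementation of the
iterative fixed/random idea: alternate (a) a fixed-effect scan with the
current pseudo-QTN markers as covariates (each pseudo-QTN is tested with
itself excluded from the covariates) and (b) re-selection of pseudo-QTNs
among markers passing a Bonferroni entry rule (p < 0.01/m) with greedy
|r| < 0.7 de-duplication, until the set stabilizes or 10 iterations pass.
It recovers planted independent QTL reliably in simulation but is not the
published algorithm, and no claim of output equivalence is made.

Marker subsets for cross-validation are, by default, computed once on the
full data — replicating common practice — which leaks test-phenotype
information into the subset choice and optimistically biases testing
accuracy. The harness therefore also accepts a per-fold `subset_builder`
(leakage-safe mode), which is the recommended design; the leakage audit in
the test suite verifies that in this mode no test phenotype can influence
training artifacts.

## Prediction models

All families centre dosages by training-set allele frequencies; test-set
centring reuses the training statistics (no leakage through centring).

**REML families.** The single-kernel mixed model is profiled over
δ = σ²ₑ/σ²_g on the eigendecomposition of the kernel, maximizing the REML
log-likelihood with a bounded scalar search on log δ ∈ [−6 ln 10, 6 ln 10];
an optimum within 1e-3 of a bound is flagged as a boundary fit. `rrblup`
builds the kernel from the centred marker cross-product and back-transforms
to marker effects; `gblup` keeps breeding values and predicts held-out
samples through the train–test relationship block. With the same kernel the
two are algebraically identical, which the test suite asserts to 1e-6 (in
practice they agree to machine precision) — the package's central
linear-algebra correctness check. `rkhs` plugs the Gaussian kernel
`exp(−d²/(h·mean d²))` (bandwidth h = 1 on the mean-squared-distance-
normalized kernel, configurable) into the same machinery. Kinship is the
centred cross-product rescaled to mean diagonal exactly 1.

**Samplers.** The Bayesian alphabet runs a single-site Gibbs sampler
(numba-compiled): intercept, marker effects, slab variances, residual
variance; spike-and-slab indicators for bayesB/bayesC with prior inclusion
probability π = 0.05 by default (the benchmark's setting; π is fixed, not
estimated). Defaults: 12,000 iterations, 2,000 burn-in, thinning 5; prior
degrees of freedom 5 for all variances; prior scales set from the sample
phenotypic variance assuming a 50% genomic share a priori (divided by π for
the spike-and-slab slabs). The Bayesian lasso uses the
inverse-Gaussian scale-mixture update with a Gamma(1, 1) hyperprior on λ².
Excluded bayesB markers have their slab variance refreshed from the prior,
the standard device that keeps the indicator chain mixing. Posterior
summaries come from thinned post-burn-in draws; σ²ₑ and slab-scale chains
are stored for calibration checks. Sampler correctness is pinned two ways:
BRR with both variances fixed reproduces the closed-form ridge solution,
and bayesB at π = 1 collapses to bayesA.

## Heritability

`estimate_h2` runs the same REML machinery on the kinship of the chosen
marker subset (mean diagonal 1, intercept-only fixed effects) and reports
σ²ₐ, σ²ₑ and h² = σ²ₐ/(σ²ₐ+σ²ₑ). It shares its likelihood with the gblup
fit, and the two entry points agree to 1e-6 on identical inputs. h² is
invariant to rescaling the phenotype. When estimated inside
cross-validation, h² is computed per training partition and averaged over
repeats.

## Cross-validation design

Training:testing proportions 90:10, 70:30 and 50:50 with 10 random repeats
are the benchmark design; any proportion in (0,1) is accepted. Test size is
round-half-away-from-zero of (1−p)·n. Splits are drawn once per proportion
and shared across models and subsets (a paired, fairer comparison), fully
reproducible from the seed. Accuracy is the Pearson correlation of
predicted GEBVs with observed test phenotypes; the cell value is the
arithmetic mean over repeats, never a pooled-prediction correlation. A
failed fold is recorded and excluded from means, not imputed. Training
phenotypes are re-standardized within each fold. The F-test for comparing
accuracy variances between marker sets is the two-sample variance-ratio
test with a two-sided p.

## The simulator

Genotypes: a first-order Markov latent process per haplotype. Along each
chromosome a standard-normal AR(1) field is generated with step correlation
`exp(−d/L)` for gap d, and thresholded at each marker to an allele at that
marker's target frequency (drawn uniformly from the configured MAF band,
with the alternate allele equally likely to be the major one); two
independent haplotypes sum to the dosage. The length scale L is calibrated
numerically — through bivariate-normal orthant probabilities averaged over
the frequency spectrum, including opposite-side threshold pairs — so that
the expected dosage r² between markers separated by `ld_decay_bp` bases is
0.25. Empirically the realized crossing lands within ~10% of the target
(e.g. ~1 kb for the maize-like preset, ~150 kb for the soybean-like one).
Markers failing the MAF floor are re-thresholded on the same latent field,
preserving LD. This process produces tunable monotone decay cheaply; it is
a structural simplification — no coalescent genealogy, no population
structure or admixture, no mutation/recombination hotspots — so passing
tests demonstrate correct method behaviour under clean additive LD, not
robustness to real-panel pathologies such as stratification or genotyping
error.

Traits are strictly additive: QTL sampled uniformly among markers, effects
Gaussian, Laplace or equal-magnitude, and the residual orthogonalized
against the genetic values and scaled so the realized h² (Var(g)/Var(y))
equals the target exactly in-sample. The ground truth (QTL positions,
effects, genetic values, realized h²) is returned for every trait.

Three fixture presets emulate the benchmark's crop panels in shape and
contrast, not in content: soybean-like (350 × 2,000, slow decay 150 kb,
20 QTL, traits at h² 0.8/0.6), maize-like (280 × 3,000, fast decay 1 kb,
150 QTL, h² 0.85/0.65) and rice-like (350 × 2,200, decay 123 kb, 60 QTL,
h² 0.8/0.55). Genome lengths are chosen so the marker spacing makes each
preset's decay measurable from its own data.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is statistically
stable: the rrblup/gblup identity at 300 × 1,500; heritability recovery at
n = 500, m = 2,000, 20 replicates; the architecture comparison at n = 300,
m = 2,000 with 20 seeds per arm and 1,500-iteration chains (the
spike-and-slab posterior means stabilize well before that for these sizes).
The architecture arms share one panel density — markers many-fold more
numerous than QTL, as on real genome-wide chips — because a panel where
most markers are causal puts fixed-π variable selection in a regime no real
chip produces. Other conventions: eigenvalues clipped at zero;
REML search bounds act as the estimate's support, with boundary fits
flagged rather than hidden; degenerate marker tests (zero dosage variance
given covariates) report effect 0 and p = 1; pruning ties break
deterministically (position, then id); all stochastic components consume
explicit integer seeds and are bit-reproducible.

## Known limitations

* FarmCPU is a simplified re-implementation; real-data subset counts will
  not match the published tool's.
* No multi-allelic sites, phasing, genotype likelihoods, dominance or
  epistasis, multi-trait models, or population-structure inference.
* π is fixed for bayesB/bayesC; no hyperparameter estimation for it.
* No standard errors or profile intervals for h².
* The simulator's LD is stationary along chromosomes; real panels mix
  euchromatic and heterochromatic decay regimes that it does not emulate.
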