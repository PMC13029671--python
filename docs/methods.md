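# Methods

This note documents the models, estimators, numerical choices and known
limitations of rhizonet.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed

Three halophyte plant groups (KC, NT, RS) with six composite rhizosphere
soil samples each; one bacterial (16S) and one fungal (ITS) OTU count
table over the same samples; a soil metadata table with physical
variables (pH, SWC, optional EC, Na⁺, K⁺), chemical variables (TC, TOC,
optional TIC, TN, TP, AN, OP) and fumigation-derived microbial biomass
pools (MBC, MBN, MBP).  Sample ids are matched across tables by exact
string equality; silent intersection must be requested explicitly.

## Soil metrics

Microbial biomass pools follow the fumigation–extraction difference
formulas MB_E = (E_fum − E_nonfum)/k_E with efficiency coefficients
k_C = 0.45, k_N = 0.54, k_P = 0.40.  Negative differences are retained
(they occur in real data through extraction noise) but raise a
`NegativeBiomassWarning` rather than being truncated, since truncation
would bias group means.

Group comparisons use one-way ANOVA plus Tukey HSD at α = 0.05 with a
compact letter display assigned by the insert-and-absorb algorithm in
descending-mean order (largest mean = "a").  The letter display is
consistent in both directions: groups share a letter iff their Tukey p
exceeds α.

`ratio_excess(a, b, mode)` expresses how much larger one group mean is
than another, as a multiple (a/b − 1) or percentage.  This is the
arithmetic behind "X was N times / P% higher" statements and is what the
acceptance script recomputes from the published group means.

## Diversity and ordination

- Shannon entropy uses natural log (nats); a base switch is provided.
  ACE uses the standard abundance-based coverage estimator with rare
  threshold 10 (via scikit-bio); when every rare individual is a
  singleton the estimator is undefined and Chao1 is substituted with an
  explicit flag.
- No rarefaction is applied by default; a seeded subsample-to-depth
  helper exists for users who want depth normalisation.  Spearman-based
  downstream steps are insensitive to per-sample monotone scaling, so
  the default works on relative abundances.
- NMDS minimises Kruskal stress-1 by SMACOF with isotonic regression
  (scikit-learn), best of 20 random restarts by default, coordinates
  mean-centred.  A genuinely information-free matrix (all zero
  distances) short-circuits to a flagged zero configuration; equal
  *nonzero* distances (a simplex) are embedded normally and report
  their true positive stress.
- The Mantel test correlates the upper triangles of two distance
  matrices (Spearman by default) and permutes one matrix's rows and
  columns jointly.  For n ≤ 6 samples every permutation is enumerated
  and the p-value is the exact null fraction; otherwise p =
  (1 + hits)/(n_perm + 1) over sampled permutations.  A PERMANOVA
  pseudo-F group-separation test (scikit-bio, 999 permutations) is
  reported alongside NMDS stress, since ordination stress itself is not
  a significance test.

## Exact small-sample Spearman inference

All Spearman p-values in the package (axis–environment, taxa–
environment, network edges, subnetwork–environment) go through one
routine: tie-corrected ρ (Pearson on mid-ranks), with an exactly
enumerated permutation null for n ≤ 7 (≤ 5040 arrangements, cached by
the rank multisets so tie structure is respected) and the t
approximation above that.  At the design's n = 6, only |ρ| = 1 reaches
two-sided p < 0.01 (2/720 ≈ 0.0028); the t approximation would claim
far smaller p-values and must not be used there.

## Co-occurrence networks

Edges join OTU pairs (within and across kingdoms) with |ρ| > 0.9 and
p < 0.01 on relative abundances over the shared samples.  OTUs present
in fewer than 3 samples are excluded before testing: with few samples,
zero-dominated pairs produce spurious perfect rank correlations.
Isolated nodes are dropped.  Edge distance weight defaults to 1 − |ρ|
(stronger correlation = shorter); unit and 1/|ρ| weights are available.

Topology statistics: modularity and module count from deterministic
greedy (CNM) agglomeration on the unweighted graph; average path length
and diameter from distance weights over *connected pairs only*
(disconnected pairs are excluded, not infinite); density and global
transitivity unweighted; betweenness centralization is Freeman's
Σ(b_max − b_i)/(n − 1) on normalized unweighted betweenness, which is 1
for a star.  Every one of these is validated against independent
brute-force oracles (exhaustive simple-path enumeration, triple
counting, direct evaluation of Q on the returned partition) on random
graphs of up to 15 nodes.

Per-sample subnetworks are induced subgraphs on the OTUs with count ≥ 1
in that sample; their parameter rows (nodes, edges, density,
transitivity, diameter, average path length) feed the NCI.

## Network complexity index

The NCI is the first principal component score of the z-scored
per-sample subnetwork parameter matrix (SVD-based PCA pooled over all
samples of all groups).  Constant columns are dropped with a warning;
samples with missing metrics are dropped with a warning.  PC1's sign is
fixed by requiring positive correlation with edge count so that "higher
NCI = more complex" is stable across runs.  The NCI is invariant to
affine rescaling of any input metric.

## Variation partitioning and random forests

Variation partitioning Hellinger-transforms the community response,
computes the Ezekiel-adjusted multivariate redundancy R² for each of the
seven unions of the three predictor sets, and solves the Venn fractions
by inclusion–exclusion; the seven fractions plus the residual sum to 1
(individual fractions may be negative, as adjusted fractions do).
Collinear predictor columns are dropped with a warning.  Default set
membership: physical {pH, SWC, EC, Na, K}, chemical {TC, TOC, TN, TP,
AN, OP}, biomass {MBC, MBN, MBP}; configurable.

Random-forest explanatory power models each dominant taxon's relative
abundance as the response and the environmental variables as predictors
(500 trees); the reported percentage is the out-of-bag pseudo-R² × 100
floored at 0, with significance by response permutation.  Because the
forest's bootstrap draws depend on row order through the seed, rows are
sorted canonically before fitting, making the result invariant to
sample ordering.  The direction of the model (taxon as response) is a
documented choice; the reverse is expressible by passing swapped
arguments.

## Synthetic data

The generators' defaults are the study conditions; they are not tuned
per experiment.

- **Soil**: each variable is drawn per group from Normal(mean, SE·√6)
  truncated at zero by resampling (not clipping), with the published
  group means ± SEs (n = 6) as the default generative parameters.
  Fumigation pairs are emitted around plausible non-fumigated baselines
  so that applying the biomass formulas reproduces the drawn MBC/MBN/MBP
  exactly.
- **OTU tables**: latent log-abundance per OTU = baseline (SD 0.5) +
  Σ block strength × loading sign × block factor (factor SD 1) +
  Gaussian noise (SD 0.1), optionally plus per-group offsets; counts are
  multinomial per sample from softmax(latent) at a log-normal library
  size (median 10⁵, σ 0.25).  Defaults are 200 bacterial + 100 fungal
  OTUs.  The pool size and depth were chosen together so that the count
  layer does not destroy planted associations: with a small pool the
  compositional closure term (the log total) becomes a large shared
  noise source that systematically weakens planted *negative* pairs,
  and at shallow depth low-baseline members sit at ~15 counts where
  multinomial noise alone drags rank correlations below the 0.9 edge
  threshold.  A median of 10⁵ reads matches merged MiSeq-class
  libraries.  Truth tables record exactly the within-block pairs with
  sign = product of member loading signs, the latent matrix, and any
  group offsets.
- **Path-model data**: latent scores are generated recursively along a
  strictly lower-triangular coefficient matrix with Gaussian
  disturbances, each endogenous latent rescaled to unit variance so the
  prescribed coefficients are directly standardized paths; indicators
  are loading × latent + Gaussian noise.

What the generators do *not* emulate: taxonomic misassignment, chimeric
reads, overdispersion beyond the log-normal/multinomial layers,
phylogenetic correlation among OTUs, and the field study's compositing
of three cores per sample (only its SE convention is reproduced).
Passing tests therefore demonstrate correctness of the estimators under
a clean compositional model, not robustness to every artefact of real
amplicon data.

## PLS path modeling

Lohmöller iteration: outer weights start equal; latent = standardized
weighted sum of its indicators; inner proxies by the centroid (default),
factorial or path scheme; mode-A outer update (weight ∝ correlation of
indicator with inner proxy); convergence when the largest outer-weight
change is below 1e-7 (max 300 iterations, error on failure).  Blocks
with no inner connections self-proxy, which makes their weights a power
iteration converging to the block's first principal axis.  After
convergence each latent is oriented so the sum of its outer loadings is
positive; with multi-indicator blocks this pins the solution so that
negating one indicator flips only that indicator's loading.  For a
single-indicator block the latent is (±) the indicator itself, so
negating the indicator necessarily flips its paths; this is inherent,
not a bug.  Structural coefficients come from OLS of each endogenous
latent on its predecessors, and R² from the same regression.

Bootstrap: rows resampled with replacement, the model refitted, each
replicate's latent orientations aligned to the full-sample solution via
the sign of the outer-weight inner product (preventing artifactual
bimodality), percentile CIs, and a two-sided normal-approximation
p-value from the bootstrap SE.  More than 20% failed replicates is an
error.

The default inner structure (physical → chemical, biomass, diversity;
chemical → biomass, diversity; biomass, diversity, dominant phyla →
network complexity; diversity → dominant phyla) is a configuration
default, not hard-coded: any block/edge set can be passed.

PLS-PM composites attenuate structural paths relative to the true
latent coefficients (a composite built from five loadings-0.9
indicators correlates ≈ 0.97–0.98 with its latent, so a true path of
0.6 is estimated near 0.57).  The recovery checks use five indicators
per block for this reason; with fewer indicators the attenuation grows.

## Problem sizes in the checks

The acceptance-level checks run at deliberately small, fixed sizes
chosen as the smallest that make each property statistically clear:
200 random graphs of ≤ 15 nodes for the topology oracles; 50 random
pairs at n = 6 against full 720-permutation enumeration; 10 replicate
datasets for edge precision/recall and 100 seeds for the NCI ordering;
1000 null simulations for calibration; 50 seeds for path recovery.

## Known limitations

- Spearman thresholding is not compositionality-aware (no SparCC/
  SPIEC-EASI); at n = 6 only perfect monotone pairs can become edges,
  so per-group networks at the study's sample size are extremely
  sparse unless abundances are nearly deterministic.
- The CNM modularity partition is one local optimum; Q is reported for
  the returned partition, not a global maximum.
- Whole-network statistics from only three networks cannot support a
  PCA; the NCI is therefore defined on per-sample subnetwork rows, the
  only statistically workable reading.
- PLS-PM is a composite method: path estimates are attenuated under
  measurement error and are not maximum-likelihood SEM estimates; no
  global fit indices are provided.
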