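# Methods

This note documents the statistical model behind `milknet`, the choices
made where the design was genuinely open, and what the synthetic cohort
does and does not establish about real data.

## Preprocessing

**Prevalence filter.** Features observed in strictly more than
`min_present_fraction` (default 0.5) of samples are retained, after
dropping contaminant/reverse entries. The strict inequality generalizes
the ">150 of 300 samples" rule: at n = 300 a feature seen exactly 150
times is removed. Zeros in MaxQuant intensity columns are treated as
missing, not as measured zeros.

**Outlier samples.** A sample is flagged when its log10 total peptide
intensity is at least `outlier_log10_margin` (default 2.0 decades) above
the cohort median — an operationalization of "several orders of
magnitude", as produced by, e.g., mastitis. The margin is configurable;
the flag list is reported, and flagged samples are dropped from both
tables.

**MNAR imputation.** Intensities are missing because they fell below a
feature-specific detection floor (left-censored, missing-not-at-random),
so imputation must place values *below* what was observed. The imputer
works on the log2 scale in two phases:

1. *Censored-normal initialization (QRILC-style).* For a feature with
   missing fraction π, the sorted observed values are matched to the
   standard-normal quantiles of the probability range (π, 1); the
   regression slope and intercept estimate the uncensored (μ, σ).
   Missing cells are drawn from N(μ, σ²) truncated above at the observed
   minimum.
2. *Gibbs refinement* (default 10 sweeps). Each sweep re-draws every
   feature's missing cells from a ridge regression (α = 1) of that
   feature on its 10 most-correlated features, again truncated above at
   the observed minimum. The regression is trained on the *completed*
   matrix (observed plus current imputations): training only on rows
   where the target is observed would inherit the censoring bias of the
   observed subsample and systematically over-predict; the
   completed-matrix update is the Gibbs-consistent choice and reproduces
   the closed-form truncated-normal mean on censored Gaussian features
   (verified in the test suite).

Observed cells are never modified; a fixed seed fixes the output.

## Shrinkage Gaussian graphical model

All modeling happens on log2 intensities. Raw label-free intensities are
approximately log-normal; a Gaussian model on the raw scale would be
dominated by the abundance tail. The log2 transform is exposed as the
single place where scale enters — the estimator itself standardizes each
feature, making the result invariant to positive rescaling.

With p features and n samples (here p may exceed n), the sample
correlation matrix R is shrunk toward the identity target:

    R* = λ* I + (1 − λ*) R,
    λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²   (clipped to [0, 1]),

where Var̂(r_ij) is the empirical variance of the per-sample products of
standardized scores (w_kij = x_ki x_kj). Large estimation variance
relative to signal drives λ* up; any λ* > 0 makes R* positive definite.
Partial correlations come from the precision matrix Ω = (R*)⁻¹ as
ρ_ij = −ω_ij/√(ω_ii ω_jj), symmetrized and clipped to [−1, 1] with unit
diagonal. If λ* = 0 and p > n the Moore–Penrose pseudo-inverse is used so
the λ-sweep stays total.

Known behavior worth stating: shrinkage *attenuates* partial correlations
that live in small-eigenvalue directions of R. A hub feature with many
tightly-coupled neighbors (a precursor with dozens of near-duplicate
peptides) has its true partial correlations capped near 1/√k for k
neighbors and further attenuated by λ*; this is a property of the
estimator class, not a bug, and shapes what the synthetic cohort can
plant detectably (see below).

## Empirical-Bayes edge calibration

Off-diagonal ρ̂ values are modeled as a two-group mixture
f(r) = η₀ f₀(r; κ) + (1 − η₀) f_A(r) with null density

    f₀(r; κ) = Γ(κ/2) / (√π Γ((κ−1)/2)) · (1 − r²)^((κ−3)/2),

equivalently r² ~ Beta(1/2, (κ−1)/2). Numerical choices:

- **κ** is fit by *truncated* maximum likelihood on the central body of
  the distribution (|r| below its 90th percentile), with the density
  renormalized to the truncation window. Fitting the untruncated
  likelihood to a truncated sample would bias κ upward (the discarded
  tails make the data look narrower). κ is fit empirically rather than
  set to n − p + 1, which is negative when p > n.
- **η₀** by central-mass matching: the observed fraction of |r| inside
  the interval that holds the central 25% of f₀ mass, divided by 0.25,
  clipped to [0, 1]. Alternative hypotheses concentrated away from zero
  leave this neighborhood nearly pure-null.
- **f̂** by Gaussian kernel density estimation with Silverman's
  bandwidth, reflected at ±1 so boundary mass is not lost, tabulated on a
  2001-point grid and renormalized.
- **lfdr(r) = min(1, η₀ f₀(r)/f̂(r))**, post-processed by isotonic
  regression to be non-increasing in |r| (a larger association magnitude
  never gets a larger false-discovery estimate).
- **Significance** is strict: lfdr < 0.1, equivalently presence
  probability 1 − lfdr > 0.9. An edge at exactly 0.1 is not drawn.
- Degenerate input (all ρ̂ ≈ 0) returns η₀ = 1 with a fallback κ = 1000;
  fits on fewer than 100 values warn.

## Community detection

The significant-edge network (edge weight |ρ̂| by default) is clustered
with the Leiden algorithm under the Constant Potts Model,

    H = Σ_c [ W_c − γ n_c(n_c−1)/2 ],   γ = 10⁻³ by default,

via the `leidenalg`/`igraph` backend, which provides the Leiden
guarantees (connected communities, non-decreasing quality). CPM quality
is always recomputed independently in this package, and the test suite
checks the optimizer against exhaustive partition enumeration on 6-node
graphs. The configured iteration budget (default 1000) is spent as seeded
restarts with early stop after three restarts without improvement; each
restart already loops local-move/refine/aggregate to stability, and
restarts escape the rare local optima of greedy local moves on small
graphs. The refinement-randomness parameter β (default 0.01) is accepted
for interface parity; the backend fixes its own refinement temperature.
Whether the original milk analysis used weighted CPM is unknowable from
its description, so both modes are provided (`use_weights`); count-based
benchmarks in the tests use unweighted mode.

Clusters of more than 3 nodes (`min_cluster_size = 4`) are retained and
labeled by composition (protein-only, peptide-only, or mixed).

## Overrepresentation analysis

For a retained cluster, only its protein members are tested, against the
background of all identified (post-filter) proteins. For each GO term
annotating b ≥ 1 cluster proteins out of B background proteins, the
p-value is the exact hypergeometric upper tail; Benjamini–Hochberg
adjustment pools terms within one (cluster, GO-domain) pair, mirroring
per-domain reporting (a cross-cluster pool is available). Annotations are
consumed as a flat gene → term table (TSV or a minimal GAF 2.x subset)
and must be pre-propagated along the GO hierarchy by the provider — no
DAG handling is done here, keeping the module offline and deterministic.
Significance is strict: adjusted p < 0.05.

## Peptidome analysis

Peptide coordinates are 1-based inclusive on the full precursor sequence,
signal peptide included. Within a cluster and precursor, two peptides
*overlap* iff their position ranges intersect in at least one residue; a
**ladder** is a connected component of the overlap graph with ≥ 5
members (reported with union span, count, and mean length to 1 decimal).
Connected components permit several ladders per (cluster, precursor).
**Trimming steps** are ordered peptide pairs differing by exactly one
residue at exactly one terminus — the elementary aminopeptidase /
carboxypeptidase events. **Cleavage sites** are the bonds flanking
observed peptide termini (protein N-/C-termini excluded; the
mature-protein start bond counts, since signal peptidase action is a
genuine cleavage), deduplicated by (precursor, bond position); a site
matches a protease rule iff its P1 residue is allowed and its P1′
residue is allowed (plasmin: P1 ∈ {K, R}, any P1′). Per-terminus counting
(no deduplication) is available behind a flag, because published
"x out of y cleavage sites" counts do not always disambiguate the basis.
**Precursor contribution** is reported both count-based and
abundance-based, each summing to 100%.

## The synthetic cohort

`SyntheticScenario` defaults define the study conditions: 297 samples;
40 proteins of which 16 form four partial-correlation blocks of 4 at
ρ = +0.3 (a block of size k with constant partial correlation ρ is
positive definite only for ρ < 1/(k−1), so 4 at 0.3 is comfortably
valid); two precursor proteins of 150 residues digested at K/R bonds
(cleavage probability 0.7 per bond, peptide length window 8–25) with up
to two single-residue trims per terminus; 20% left-censored missingness
per feature. Latent Gaussian scores become intensities as 2^(μ_f + score)
with per-feature baselines μ_f uniform on [20, 30] log2 units (a
realistic LFQ dynamic range), so the downstream log2 transform recovers
exact Gaussianity.

**Abundance coupling is a cascade.** A base fragment's per-sample
intensity is precursor × yield × log-normal noise; each trimmed variant's
is its *parent peptide's* × decay (0.5 per residue) × noise — trimming
acts on the peptide product, not the precursor, so ladder neighbors are
directly coupled, which is what exoproteolysis implies mechanistically.
The planted conditional-independence graph is therefore: protein blocks;
one star-plus-chains tree per base fragment, attached to its precursor by
a single coupling edge. Planted cluster labels follow that graph: each
block is a cluster, each trim family (ladder) is a cluster.

**Coupling noise.** The digest default noise is σ = 0.3 log2 units,
giving peptide–precursor per-sample correlations ≈ 0.95. For the
end-to-end scenario the noise is σ = 1.0 log2 units (peptide–precursor
correlation ≈ 0.7, sibling–sibling ≈ 0.5), chosen on realism grounds:
MS peptide intensities carry large peptide-specific variation, and
near-duplicate siblings (σ → 0) create a near-singular correlation
structure in which hub partial correlations are strongly attenuated by
any shrinkage estimator — a regime no method could resolve and real
cohorts do not present. The coupling magnitude is a free parameter of the
generator, not an empirical claim. Precursors are drawn from the
unstructured background proteins: the heavily degraded milk precursors
(caseins, PIGR-like secreted proteins) are not members of the
transport-driven protein clusters.

**What the generator does not emulate:** acquisition and search-engine
identification error, missed/nonspecific cleavages, post-translational
modifications, sample covariates, batch structure, and
intensity-dependent (rather than purely left-censored) missingness.
Passing recovery tests on this cohort demonstrates correctness of the
estimators under their own assumptions — not that a real milk cohort
meets those assumptions.

## Problem sizes and reproducibility

Simulation-backed checks use: pure-null calibration at p = 100 features ×
n = 297 samples × 10 replicates; planted-edge recovery at p = 40 (ten
blocks of 4, ρ = 0.3) × n = 297 × 10 seeds; mixture recovery at 10⁵ draws;
the end-to-end cohort at its default scale × 10 seeds. These sizes give
stable averages for rate and recovery statistics while keeping the full
suite and the acceptance script fast. All randomness flows from explicit
integer seeds through named `numpy` generators; repeated runs with the
same seed produce byte-identical run reports (verified by hash).

## Known limitations

- The empirical-null κ is a single global width; heteroscedastic edge
  nulls (e.g., differing missingness per feature pair) are not modeled.
- Hub attenuation (above) means dense star structures are recovered as
  their strongly-coupled periphery (ladders) plus, at best, a weak link
  to the hub; expected mixed protein–peptide clusters are accordingly
  sensitive to cohort size.
- The imputer is a documented stand-in honoring the MNAR/left-censored
  contract, not a reimplementation of any specific published package.
- GO annotations are consumed pre-propagated; results depend on the
  annotation release supplied by the user.
- Adjusted p-values from the original web-tool-based milk analysis are
  not reproducible bit-for-bit (annotation release and internal pooling
  differ); the hypergeometric/BH machinery itself is exact and tested
  against enumeration.
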