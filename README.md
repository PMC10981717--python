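# milknet

Integrated association-network analysis of the human milk proteome and
peptidome.

Human milk contains hundreds of proteins and, because milk carries its own
active proteolytic systems (plasmin, kallikrein, aminopeptidases), more
than a thousand endogenous peptides cut from a few dozen precursor
proteins. Which proteins travel into milk together, which peptides are
formed from which precursors, and which proteases did the cutting are all
questions about *associations* between abundance profiles measured across
hundreds of milk samples. `milknet` infers those associations as a
Gaussian graphical model over the combined protein + peptide abundance
matrix, clusters the resulting network, and interrogates the peptide
clusters for proteolysis signatures. It is aimed at proteomics /
peptidomics researchers working with MaxQuant-style label-free
quantification output from large milk (or other biofluid) cohorts.

## The model

Let `X` be the samples × features matrix of log2 intensities (proteins
and peptides together). The analysis proceeds in five stages:

1. **Preprocessing** — contaminant/reverse removal, retention of features
   observed in strictly more than half of the samples, removal of samples
   whose total peptide signal is orders of magnitude above the cohort
   median, and Gibbs-sampler imputation of the remaining missing values
   under a left-censored MNAR model (missing ⇒ below the feature's
   detection floor).

2. **Shrinkage GGM** — the sample correlation matrix `R` is shrunk toward
   the identity, `R* = λ*I + (1−λ*)R`, with the analytic intensity
   `λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²` (Schäfer–Strimmer), making
   `R*` invertible even with more features than samples. Partial
   correlations follow from its inverse `Ω = (R*)⁻¹`:
   `ρ_ij = −ω_ij / √(ω_ii ω_jj)` — the association between features *i*
   and *j* after accounting for all other features.

3. **Edge calibration** — off-diagonal `ρ̂` values are modeled as a
   two-group mixture `f(r) = η₀ f₀(r; κ) + (1−η₀) f_A(r)` with the null
   `f₀(r; κ) ∝ (1−r²)^((κ−3)/2)` (κ fit empirically, η₀ by central-mass
   matching, the marginal by kernel density estimation). Each edge gets a
   local false discovery rate `lfdr(r) = η₀ f₀(r)/f̂(r)`; edges with
   `lfdr < 0.1` (presence probability > 0.9) enter the network.

4. **Community detection** — the significant-edge network is clustered
   with the Leiden algorithm under the Constant Potts Model,
   `H = Σ_c [W_c − γ n_c(n_c−1)/2]`, at resolution `γ = 10⁻³` with `|ρ|`
   edge weights; clusters of more than 3 nodes are retained and labeled
   protein-only / peptide-only / mixed.

5. **Interpretation** — protein clusters are tested for GO term
   overrepresentation (hypergeometric upper tail against the
   all-identified-proteins background, Benjamini–Hochberg adjusted,
   significant below 0.05); peptide clusters are scanned for peptide
   ladders (connected components of the interval-overlap graph on
   precursor coordinates, ≥ 5 members), single-residue exoproteolytic
   trimming steps, protease cleavage specificity per unique peptide bond
   (plasmin: K/R at P1), and per-precursor peptidome contributions.

A first-class synthetic-data module generates cohorts with planted
partial-correlation blocks, an in-silico K/R digest with exoproteolytic
trim cascades, and left-censored missingness — carrying full ground truth
(edges, clusters, cleavage sites) so every stage of the pipeline is
testable for recovery, calibration, and false-discovery control.

## Worked example

Generate a synthetic 297-sample cohort (4 planted protein blocks, 2
digested precursors) and run the full pipeline:

```python
from milknet import pipeline

study = pipeline.simulate_study(pipeline.SyntheticScenario(), seed=1)
result = pipeline.run_pipeline(
    study.protein_table, study.peptide_table,
    pipeline.PipelineConfig(seed=1),
    precursor_sequences=study.precursor_sequences,
)
print(pipeline.summarize_counts(result.report))
print("ARI vs planted clusters:",
      round(pipeline.cluster_recovery_ari(result.retained, study.truth), 3))
```

which prints

```
samples used: 297 (dropped 0 outliers)
features: 40 proteins + 95 peptides
network: 112 edges connecting 116 nodes (21 proteins + 95 peptides)
density: 1.7% of all possible edges
same-kind edges: 99.1%
clusters retained: 22 = 1 mixed + 3 protein-only + 18 peptide-only
peptide ladders: 19
```

```
ARI vs planted clusters: 0.951
```

Reading this: of the 12,720 possible feature pairs, 112 partial
correlations were credible at local fdr < 0.1 — a sparse network, almost
all of whose edges connect features of the same kind (protein–protein
within planted blocks, peptide–peptide along trim ladders). Leiden/CPM
recovers the planted blocks and each proteolysis ladder as separate
communities; the adjusted Rand index of 0.95 against the planted labels
says the community structure was recovered almost exactly. The 19
detected ladders are the exoproteolytic trim families the digest planted.

The same stages are available from the shell via the `milknet` CLI
(`simulate`, `preprocess`, `network`, `cluster`, `enrich`, `peptidome`,
`run`), each reading/writing plain TSV/JSON/GraphML artifacts.

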