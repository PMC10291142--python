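# Methods

## Model and assumptions

The package treats a metabolic map as a bipartite factor graph: metabolite
nodes C₁…C_K and reaction-module nodes R₁…R_M, connected by directed
consume/produce edges. A *reaction module* is a lumped run of consecutive
reactions carrying a single flux, annotated with the genes encoding its
enzymes and transporters. Two modeling assumptions underpin everything:

1. **Approximate flux balance.** Over a tissue sample, the total
   production of each *intermediate* metabolite roughly equals its total
   consumption. *End* metabolites (boundary sources and sinks such as
   extracellular glucose, exported lactate, or biomass-bound amino acids)
   are exempt.
2. **A latent monotone link from transcripts to rates.** Each module's
   flux is an unknown (generally nonlinear) function of the expression of
   its genes — an implicit, data-driven stand-in for the module's lumped
   Michaelis–Menten kinetics. It is represented by a small fully
   connected network per module.

All stoichiometric coefficients are ±1: modules are curated at the
one-unit-in/one-unit-out level, and reversible reactions appear once in a
canonical direction (the loss penalizes negative flux, which presumes
directed modules).

The per-module networks are trained jointly on the whole cohort by
minimizing

    L = Σ_j Σ_k (influx_{k,j} − outflux_{k,j})²          (balance, intermediates only)
      + Σ_j Σ_m (Flux_{m,j} − |Flux_{m,j}|)²             (negativity penalty, = 4·Flux² when Flux < 0)
      + λ Σ_j (Σ_m Flux_{m,j} − TA_j)²                    (scale anchor)

There is no expression→flux supervision term: with many samples, the
balance constraints across the network are what identify the predictors.
TA_j, the per-sample total-activity surrogate, is either the summed
expression of the union of network genes (`metabolic_total`, the default)
or a user constant (`constant:c`). No data imputation and no sparse-input
loss term are used; inputs are dense bulk log(FPKM+1) matrices.

## The packaged network

`central_metabolism_fixture()` ships a curated central-metabolism graph:
glycolysis, the upper and lower TCA cycle, glutaminolysis,
glutamine/glutamate metabolism and glutathione metabolism, plus six minor
branches (G3P→nucleotides, 3PG→serine, the aspartate–malate shuttle,
citrate→fatty-acid synthesis, mitochondrial→cytosolic 2OG transport, and
2OG→2HG), across cytosol/mitochondria/extracellular compartments:
42 modules, 27 intermediates, 15 ends, 118 genes. The decomposition and
gene rosters are a best-effort manual curation; validation enforces the
structural counts and that every intermediate has at least one producer
and one consumer, not the gene roster size. One curation choice worth
flagging: glutathione reductase returns GSSG to the *cytosolic* GSH pool,
so that mitochondrial glutathione — whose only non-cycle fate here is
peroxidase oxidation — sits on a balanced route to the amino-acid sink;
a GPX/GSR pair closed inside mitochondria would force both fluxes to zero
under balance. The 2OG→2HG module carries the wild-type enzymes only;
mutant-enzyme kinetics are outside the model.

## Estimator numerics

- **Architecture.** Per module: input dimension = number of module genes,
  two tanh hidden layers (8 and 4 units by default, configurable), scalar
  linear output. Small networks deliberately: tens of parameters per
  module keeps the unknown count far below the K_int × N balance
  constraints even for modest cohorts.
- **Initialization.** Weights ~ N(0, 1/√fan_in) from a single seeded
  generator; hidden biases 0. The output bias is initialized at
  mean(TA)/M so the summed flux starts near the scale anchor — without
  this, first-order optimization spends most of its budget walking the
  output scale up from zero.
- **Optimization.** Full-batch Adam (β = 0.9/0.999), learning rate 0.008,
  up to 100 epochs by default; the gradient of L/N is used so the step
  size is cohort-size-invariant. Early stopping when the relative change
  of the total loss stays below `convergence_tol` (1e-4) for `patience`
  (10) consecutive epochs. A non-finite loss raises a training error
  naming the epoch. Runs are bit-deterministic given the seed.
- **Non-negativity** is enforced only through the loss term (the fitted
  attribute `negative_fraction_` reports entries < −1e-6); an optional
  `clamp_nonnegative` flag clips reported fluxes at zero and is off by
  default.
- **Missing genes** are zero-filled with a warning; a module with *no*
  observed genes has its flux pinned to 0; no overlap at all between data
  and network genes is an error.
- λ defaults to 1.0. With `metabolic_total` TA the three terms are then
  on comparable scales for log-expression inputs; both are exposed.

On small identity-link problems (one gene per module, expression equal to
flux), the trained fluxes agree with the direct non-negative least-squares
minimizer of the same loss to well under 5% relative Frobenius error —
but only where that minimizer is unique. On a parallel-path graph
(diamond), the loss Hessian SᵀS + λ11ᵀ is singular along the
"shift flux between the two branches" direction, so only chain-shaped
graphs are used for that equivalence check; recovery on the diamond is
instead assessed against the generator's ground truth, which the gene
inputs do disambiguate.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions under
which every quantitative claim is measured.

- **Flux modes.** For each module a minimum-total-flux LP over
  {f ≥ 0 : S f = 0, f_m = 1} is solved (HiGHS); vertices are sparse
  balanced flows from boundary sources to sinks, including the cycle
  flows needed to balance multi-substrate modules (e.g. a unit TCA-cycle
  flow accompanies citrate synthase). On chains and diamonds these are
  exactly the 0/1 path indicators. The packaged network yields 15 modes
  covering all 42 modules.
- **Sampling.** Per sample, each mode receives an independent log-normal
  load (meanlog 0, sdlog 0.5 — right-skewed positive magnitudes, roughly
  mimicking flux variability across tissues; the magnitude of real
  cross-cohort flux variation is unknown, so this is a modeling choice,
  not a calibration). Fluxes are the load-weighted mode sums, optionally
  plus a per-module Gaussian slack (sd `slack_sd`) truncated at zero;
  `slack_sd = 0` (the default) gives exactly zero balance loss.
- **Expression link.** Each gene of a module reports
  `expr = log(1 + w·flux) + ε`, w log-normal (sdlog 0.25; 0 gives w = 1),
  ε ~ N(0, `noise_sd`), clipped at zero — values live directly on the
  log(FPKM+1) scale. A gene shared by several modules responds to the
  weighted sum of their fluxes.
- **Two-group studies.** Tumor-group loads of every mode through a
  perturbed module are multiplied by its fold change, so that module's
  expected flux scales exactly while balance is preserved; modules
  sharing those modes shift proportionally (unavoidable under balance —
  doubling one chain step and nothing else would be unbalanced by
  construction), and disjoint modes are untouched. An empty perturbation
  list gives exchangeable groups.

What the generator does *not* emulate: counts-level sampling noise
(expression is Gaussian on the log scale, not Poisson/NB), batch effects,
cell-type mixtures, unmodeled side fluxes, or nonlinear saturating
gene–flux links beyond log1p. Passing recovery tests therefore shows the
estimator inverts the generator's monotone link under balanced truth —
not that real-tissue fluxes are recovered at that fidelity.

## Downstream statistics

- **Differential testing**: two-sided Mann–Whitney U per module (or per
  intermediate for abundance changes), raw p < 0.001, *no* multiplicity
  correction — the cutoff is part of the method's definition. Exact
  enumeration p-values when the pooled size is ≤ 20 with no ties;
  otherwise the normal approximation with midrank tie correction and
  continuity correction. Direction is the sign of the median difference.
- **Z-score fluxome**: (flux − mean of normal controls)/sd (n−1), per
  module within a cancer type; constant controls give z = 0 with a
  warning, fewer than two controls an error.
- **PCA**: column-centered, full SVD, component signs fixed so each
  component's largest-magnitude loading is positive (determinism).
- **t-SNE**: 2D, perplexity 30 by default (the conventional default of
  the reference implementations), PCA initialization, seeded; requires
  n > 3·perplexity.
- **SNN clustering**: k-nearest-neighbor graph (k = 20), edges
  reweighted by neighborhood Jaccard overlap, pruned below 1/15, then
  resolution-weighted modularity communities (Leiden, resolution 0.8,
  seeded) — the standard analogs of the usual single-cell pipeline
  defaults. All-identical input returns one cluster with a warning.
- **Stage enrichment**: the per-cluster stage distribution is summarized
  directly; a chi-square test on the non-missing stage × cluster table is
  attached when the table is at least 2×2.
- **Enrichment scores** (ssGSEA-style): per sample, genes ranked by
  descending expression with stable tie-breaking; the score is the sum
  over rank positions of (weighted in-set cumulative fraction − out-set
  cumulative fraction), with in-set weights |r|^α, r the descending-rank
  statistic n…1 and α = 0.75 by default. Using ranks (not raw values)
  makes scores invariant under any strictly increasing per-sample
  transform. Sets without overlap score NA with a warning.
- **Flux–stress correlation**: Spearman per (module, gene-set) pair over
  shared samples (≥ 3 required).

## Pipeline

`run_pipeline` executes network → simulate (or load) → estimate → diff →
phenotype, each stage writing its outputs before the next starts. One
global seed fans out to per-stage seeds by fixed offsets. Tables are TSV
with 6-significant-digit floats, so identical configs produce
byte-identical tables; the manifest records the config hash, package
version, per-stage output SHA-256 checksums and timestamps (the manifest
itself, carrying timestamps, is the one non-reproducible file). Config
validation returns the exhaustive error list, not the first error.

## Problem sizes used by the test suite and acceptance script

Experiments run on deliberately small instances: oracle-equivalence on
3–4-module chains (n = 150, 1,500 epochs), recovery on chain/diamond
graphs (n = 200, 3 genes/module, 600 epochs, noise_sd ∈ {0.05, 0.1, 0.2,
0.5}), calibration on the packaged 42-module network with 200 null
replicates at n = 50/group on generator truth, and end-to-end determinism
at n = 40/group with 25 epochs. These sizes make the whole suite run in
seconds while leaving every measured property comfortably clear of its
threshold.

## Known limitations

- Flux estimates are identified only up to the information content of the
  balance constraints and TA anchor; parallel routes with identical gene
  signals are not separable.
- The ±1 lumped stoichiometry ignores true reaction stoichiometry and
  cofactors; abundance changes are trends, not concentrations.
- No thermodynamic feasibility, isotope-tracing constraints, or
  reversible-flux direction inference.
- The curated gene rosters are smaller than an exhaustive annotation;
  estimates for modules whose genes are absent from a dataset are pinned
  to zero rather than inferred.
- Raw (unscaled) fluxes are used for embedding and clustering; whether to
  rescale before cross-cohort comparison is left to the user.
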