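# Methods

## Problem setting and model

`omicbridge` treats diagonal multi-omic integration as a generative
problem. Each modality *m* of a study is given as a low-dimensional
embedding X⁽ᵐ⁾ ∈ ℝ^{n_m × C} (typically PCA/SVD scores) plus a weighted
kNN graph over its cells. Nothing is assumed shared across modalities —
neither cells nor features — except that all embeddings describe the
same underlying population of cell states. The model learns a
distribution over joint blocks (M × C): one embedding vector per
modality per synthetic cell. Sampling it yields paired pseudo-cells in
the *same coordinate systems as the inputs*, which is what makes them
usable as bridges for kNN-based transfer of labels and features.

Embeddings are used as provided; an optional per-column standardization
exists but is off by default, since the model trains directly on the
embedding scale. The common width C is never raised above the smallest
embedding width or the smallest numerical matrix rank across modalities.

## Mini-batch pre-matching

Adversarial training sees data only through mini-batches, so the
(unobserved) cross-modality correspondence has to be injected at the
mini-batch level. Two requirements: batches should be locally coherent
(cells of similar state), and batches paired across modalities should
describe similar states.

*Local coherence.* Cells are ordered by the first nontrivial eigenvector
of the symmetric-normalized Laplacian L = I − D^{−1/2} W D^{−1/2} of the
affinity graph. Candidate mini-batches are contiguous windows of N cells
in this ordering, drawn at uniformly random offsets (a `random`-subset
strategy is available for ablation; subsets are still sorted internally
by eigenmap value). Windows of the Fiedler ordering are dominated by
single clusters, and the ordering is rotation-invariant: it depends only
on the graph, not on the embedding orientation.

*Cross-modality pairing.* For each training tensor a source window is
drawn from the reference modality (index 0 by convention, e.g. RNA), a
Bayesian ridge regressor is fit to predict its eigenmap values from its
embedding rows (evidence maximization, tolerance 1e-3, ≤ 300
iterations), and 50 candidate windows per other modality are scored by
the regressor's coefficient of determination on their own
(embedding, eigenmap) pairs; the argmax wins, ties to the first drawn.
The R² is the canonical score of a fitted regressor and bounded above
by 1; a zero-variance candidate target is scored 0. This transfer of a
regressor across embedding spaces is meaningful exactly to the extent
the spaces are comparable — the same assumption the shared-embedding
premise already makes.

*Eigenvector sign.* The Fiedler vector is defined only up to sign, and
its plain sum is numerical noise (it is D^{1/2}-orthogonal to the
trivial eigenvector), so no intrinsic per-modality rule reliably orients
two modalities consistently; we observed mutually negated eigenmaps with
same-signed skewness on otherwise well-behaved fixtures. Per modality,
the sign is canonicalized deterministically (third central moment ≥ 0,
then sum ≥ 0, then first nonzero entry positive). At the study level, a
deterministic harmonization step (`pairing.harmonize_eigenmap_signs`,
run automatically before unpaired training) probes both orientations of
each non-reference modality with the same ridge scoring used for
matching — evenly spaced source windows against evenly spaced candidate
windows — and keeps the better-scoring orientation. Without this step
the pre-match inverts on a substantial fraction of simulated studies.

*Degenerate graphs.* A disconnected neighbor graph makes the Fiedler
vector arbitrary within the component null space, so `eigenmap_order`
raises by default; with `regularize=True` (exposed as
`TrainConfig.regularize_graph`) a uniform affinity of 1e-8 is added and
the leading block structure of the regularized Laplacian still orders
components coherently. The eigenproblem is solved densely
(LAPACK, two lowest eigenpairs) up to a few thousand cells and by
shift-invert Lanczos with a seeded start vector above that.

Paired studies skip all of this: cells are sorted lexicographically by
barcode and one shared random index set samples every modality, giving
tensors of identical shape so the downstream code path is shared.

## The adversarial model

Generator: noise z ∈ ℝ^{64} → affine layer → reshape to an M-position
sequence → Conv1D(512) → BN → ReLU → Conv1D(128) → BN → ReLU →
Conv1D(C, linear). All convolutions run along the modality axis with
kernel 2, stride 1 and same-length zero padding (valid padding would
collapse M = 2 to length 1). The output convolution is linear because
embedding coordinates are signed; a rectifier there could never cover
PCA-score space. Batch normalization uses momentum 0.99, ε 1e-3;
generation runs in inference mode on running statistics, so output is a
deterministic function of the noise draw.

Critic: Conv1D(128) → ReLU → Conv1D(512) → ReLU → flatten → one affine
unit. The critic carries no normalization layers — the gradient penalty
is defined per individual input, and batch-coupled statistics would
invalidate it.

Losses: critic minimizes mean f(fake) − mean f(real) + λ·GP with λ = 10
and GP = E[(‖∇_x̂ f(x̂)‖₂ − 1)²] at x̂ = ε·real + (1 − ε)·fake,
ε ~ U(0,1) per sample, the norm over the full (M, C) block; generator
minimizes −mean f(fake). Five critic updates per generator update, each
on a freshly matched tensor; Adam (lr 0.001, β₁ 0.5, β₂ 0.9, ε 1e-7)
for the generator, RMSprop (lr 0.0005) for the critic. Some
hyperparameter corners collapse to NaN losses; the `nan_policy` either
aborts with a diagnostic (default) or re-seeds and retries up to three
times. A grid-search helper (`omicbridge sweep`) iterates filter counts
{8, 32, 64, 128, 256, 512} and embedding widths {5, 10, 15} and reports
NaN collapses per configuration.

The networks run on the package's own reverse-mode automatic
differentiation engine over numpy (`_autodiff`). Every backward rule is
written in terms of the same primitive operations, so gradients built
with `create_graph=True` are themselves differentiable — the
second-order path the gradient penalty term requires. The engine is
verified against central finite differences at first and second order.

Semisupervised training fits one model per batch label on that batch's
cells only (neighbor graphs are rebuilt per subset) and concatenates the
outputs with a model-of-origin label; batches smaller than N are skipped
with a warning. The consistency filter transfers batch identity from
real reference-modality cells to synthetic cells by kNN majority vote
(k = 15) and keeps cells whose transferred batch equals their model
label.

## Bridge transfer and reconstruction

Feature reconstruction is 2-nearest-neighbor regression (unweighted
mean, Euclidean metric in the modality's embedding), fit per modality on
real cells and applied to the synthetic slice; predictions therefore
stay within the convex hull of training feature values.

Label transfer is explicit two-stage kNN majority voting (default
k = 15): each synthetic cell takes the plurality label of its k nearest
real source cells in the source slice; each target cell takes the
plurality label of its k nearest synthetic cells in the target slice.
Ties break to the lexicographically lowest label, making the whole
operation deterministic. The reported per-cell confidence is the stage-2
agreement fraction multiplied by the mean stage-1 agreement of the
voting neighbors. This replaces graph-partition-marginal label transfer
used elsewhere; equivalence is not claimed — the only information used
here is embedding proximity.

## Evaluation stack

- **AMI / homogeneity / completeness / V-measure** wrap scikit-learn
  (permutation-model expectation, arithmetic-mean normalization). A
  zero-entropy labeling scores AMI 0 by convention.
- **LISI**: for each cell, its 3·perplexity nearest neighbors are
  weighted by a Gaussian kernel whose bandwidth is bisected (≤ 50
  iterations, tolerance 1e-5) until the weight entropy matches
  log(perplexity); the index is 1/Σ_b p_b² over label probabilities.
  Values lie in [1, number of labels]; fewer available neighbors than
  requested are used in full with a warning.
- **Marker detection**: per group, two-sided Wilcoxon rank-sum
  (tie-corrected normal approximation, no continuity correction) of each
  feature against all other cells, Benjamini–Hochberg adjustment within
  group, log₂ fold change of group mean over rest mean with pseudocount
  1e-9. Marker sets keep the top-k features (100 for expression-like,
  500 for region-like modalities) with adjusted p < 5e-3, sorted by
  decreasing fold change. The train/test split is a seeded 70:30
  partition stratified by cell type (stratification avoids empty groups
  at fixture scale).
- **Preranked GSEA**: classic weighted Kolmogorov–Smirnov running sum
  with weight |metric|¹; ES is the extremum; the null is n_perm = 1000
  seeded random same-size feature sets; NES divides ES by the mean
  |null ES| of matching sign; an empty intersection yields NaN, imputed
  as 0 downstream.
- **Graph clustering**: pipelines without ground-truth labels can derive
  partitions with a generic Leiden modularity clustering of the weighted
  neighbor graph (`leiden_clusters`); this is a pragmatic stand-in for
  heavier block-model inference, not an equivalent of it.
- **NES confusion accuracy**: entry (s, t) is the NES of type s's marker
  set against type t's fold-change ranking; columns are scaled by their
  absolute maxima; positive/negative diagonal mass counts as TP/FN and
  positive/negative off-diagonal mass as FP/TN; weighted accuracy is
  (TP + TN)/(TP + TN + FP + FN), and the unweighted variant takes signs
  before summing. The accuracy is invariant to positive rescaling of any
  column.

## Synthetic studies: what they emulate, and what not

The generator draws K latent Gaussian populations (multinomial mixture,
isotropic within-population noise) in d_latent dimensions and renders
each modality as latent · load_matrix + Gaussian noise; features are
softplus(embedding · nonnegative map) + noise (softplus keeps features
nonnegative, mimicking normalized expression; a raw linear option exists
for exactness tests). Paired studies reuse one latent draw across
modalities; unpaired studies draw independent cells from the same
population. Batch structure adds latent offsets.

Default study: K = 3 populations (proportions 0.5/0.3/0.2),
d_latent = 8, C = 10, M = 2, 3000 cells per modality, within-population
sd 1, embedding noise sd 0.1 — sized so adversarial training completes
in minutes on one core. Population centers are drawn at scale 1.6·sd;
this keeps the k = 15 neighbor graph connected (cross-population edge
fraction ≈ 4%) while populations remain cleanly separable. Connectivity
matters: with fully disconnected populations the Fiedler vector is
degenerate and eigenmap ordering carries no information — real
single-cell graphs at these scales are connected, and the degenerate
regime is exactly what the disconnected-graph error guards.

Default load matrices share one orthonormal latent basis per study, with
a small random rotation (scale 0.2) per modality. This emulates
harmonized embeddings that capture the same latent geometry with
modality-specific distortion, as variance-ordered PCA embeddings of the
same tissue do. It is a favorable regime chosen deliberately: with
arbitrary per-modality rotations the ridge-based matching score is
uninformative, and with it the whole pre-match premise. Passing tests on
these fixtures therefore show that the machinery works *when the
embeddings are comparable*; they do not show how far real PCA spaces of
two assays satisfy that premise. Other idealizations: Gaussian
within-population noise (no count noise, dropout, or depth variation),
linear modality maps, and cluster-shaped geometry rather than
trajectories.

A planted-marker generator (disjoint blocks of features elevated per
cell type over nonnegative noise) backs the marker-recovery accuracy
checks; the degenerate alternative — marker sets covering most of a
short ranking — makes enrichment scores meaningless, so those fixtures
carry several hundred features.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.Generator` seeds; training
  history, generation, simulation and the CLI's per-stage seeds (derived
  from one global seed via `SeedSequence`) are reproducible exactly.
  h5ad artifacts are byte-identical across runs and carry the config
  digest and seed that produced them.
- Score ties in mini-batch selection break to the first candidate; label
  vote ties break lexicographically; the eigenvector sign chain is
  described above.
- Scaled-down training used in the test suite (N = 64, generator filters
  64/32/C, critic 64/256, 1500 generator steps on the 3000-cell study)
  is the package's reference desk-scale configuration; production-scale
  defaults (N = 256, 512/128/C) are the config defaults.
- Known limitations: the pre-match assumes comparable embedding
  orientations (see above); a 1-D spectral ordering can place two of
  K > 2 populations at similar eigenmap levels, weakening matching for
  those populations; the critic/generator are small fixed architectures
  with no spectral or hinge alternatives; LISI at very small n uses all
  neighbors and is then close to a global, not local, index.
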