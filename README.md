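# omicbridge

Synthetic multimodal single-cell bridges from unpaired (or paired)
modality embeddings.

Single-cell assays profile different molecular layers — transcriptome,
chromatin accessibility, histone marks — usually in *different* cells.
Integrating such unpaired ("diagonal") datasets is hard because neither
cells nor features are shared. `omicbridge` learns a joint generative
model over the per-modality embeddings and emits **synthetic multimodal
cells**: each synthetic cell carries one coordinate vector per modality,
jointly. These synthetic cells act as a molecular bridge through which
cell-type labels and feature values can be transferred between real
unimodal datasets.

It is aimed at computational biologists who already have per-modality
embeddings (PCA/SVD scores from any standard pipeline) and want paired
pseudo-cells linking them.

## The model

Each modality *m* contributes an embedding matrix (cells × C, with C at
most the lowest matrix rank across modalities) and a weighted kNN cell
graph. Training tensors of shape (N, M, C) — N cells per mini-batch,
M modalities, C components — are built by **mini-batch pre-matching**:

1. Cells of each modality are ordered by the first nontrivial
   eigenvector of the symmetric-normalized graph Laplacian (the Fiedler
   vector of the affinity graph), which tracks local data structure, so
   a contiguous window of the ordering contains similar cells.
2. A window of N cells is sampled from the reference modality (for
   example RNA); a Bayesian ridge regressor *R* is fit to predict its
   eigenmap values *y* from its embedding *X*.
3. 50 candidate windows are drawn from each other modality; each is
   scored by the coefficient of determination of *R* on its own (X, y),
   and the best-scoring candidate is paired with the source window.

For paired data (shared barcodes) the pre-match is skipped: cells are
sorted lexicographically by barcode and one shared index set samples
every modality.

The tensors train a **Wasserstein GAN with gradient penalty**. The
generator (three 1-D convolutions along the modality axis, kernel 2,
batch normalization after the first two, filters 512/128/C) maps
per-cell Gaussian noise to an (M, C) block. The critic (two
convolutions, filters 128/512, one affine unit, no normalization) is
trained with the Wasserstein objective

    L_critic = E[f(x_fake)] − E[f(x_real)] + λ · E[(‖∇ f(x̂)‖₂ − 1)²],

λ = 10, five critic updates per generator update, Adam (lr 0.001,
β₁ 0.5, β₂ 0.9) for the generator and RMSprop (lr 0.0005) for the
critic. Semisupervised training fits one model per known batch and
concatenates the outputs under a model-of-origin label; a consistency
filter keeps synthetic cells whose kNN-transferred batch identity
matches that label.

Downstream utilities: 2-nearest-neighbor regression to give synthetic
cells feature values; two-stage kNN majority label transfer
(source → synthetic → target); and an evaluation stack with adjusted
mutual information, homogeneity/completeness/V-measure, the local
inverse Simpson's index (LISI, 1 = separated … M = mixed), and a
marker-recovery accuracy built from preranked GSEA normalized
enrichment scores collected into a cell-type confusion matrix.

A `synthetic_data` module generates studies with known ground truth —
K latent Gaussian populations observed through modality-specific linear
maps plus noise, paired or unpaired, with optional batch structure — so
the whole pipeline is testable end to end without downloads.

## Worked example

```python
import numpy as np
import omicbridge as ob
from omicbridge.wgan import TrainConfig, train, generate
from omicbridge.bridge import transfer_labels
from omicbridge.evaluation import adjusted_mutual_information, lisi

study = ob.default_study(seed=0, n_cells=3000)   # K=3 populations, M=2, C=10
config = TrainConfig(N=64, steps=1500, generator_filters=(64, 32, None),
                     critic_filters=(64, 256), seed=0)
model = train(study, config)
synthetic = generate(model, n_syn=3000, rng=1)

rna, atac = study.modalities
res = transfer_labels(rna, synthetic, atac, k=15)
ami = adjusted_mutual_information(res.transferred, atac.cell_labels)
print(f"bridge transfer AMI vs ground truth: {ami:.3f}")

for m, view in enumerate(study.modalities):
    joint = np.vstack([view.embedding, synthetic.modality_embedding(m)])
    origin = ["real"] * view.n_cells + ["synthetic"] * synthetic.n_syn
    _, mean_lisi = lisi(joint, np.array(origin))
    print(f"modality {m} real/synthetic mixing LISI: {mean_lisi:.2f}")
```

Output:

```
bridge transfer AMI vs ground truth: 0.627
modality 0 real/synthetic mixing LISI: 1.63
modality 1 real/synthetic mixing LISI: 1.66
```

The AMI of 0.627 says labels carried from the first modality through the
synthetic bridge recover most of the second modality's true cluster
structure (1 would be perfect, ~0 is chance; a shuffled bridge scores
≈ 0.00). LISI values of ~1.6 (out of a maximum of 2 for two datasets)
say the synthetic cells land inside the real cells' neighborhoods rather
than in a separate blob.

The same workflow is available from the shell:

```sh
omicbridge simulate --out study/ --seed 7
omicbridge train study/modality_0.h5ad study/modality_1.h5ad \
    --out syn/ --steps 1500 --batch-size 64 --seed 7
omicbridge reconstruct study/modality_0.h5ad --synthetic syn/ --out rec/
omicbridge transfer study/modality_0.h5ad study/modality_1.h5ad \
    --synthetic syn/ --out annotated.h5ad
omicbridge evaluate study/modality_0.h5ad --synthetic syn/ --out report.json
```

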