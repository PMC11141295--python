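# stMDA

Multi-modal domain adaptation for spatially resolved transcriptomics (SRT):
spatial-domain detection and gene-expression denoising by integrating
expression, spatial coordinates, and histology features.

## The problem

SRT assays (10x Visium, Slide-seqV2, Stereo-seq, …) measure gene expression
at spatially indexed spots, but the counts are sparse and noisy.  The same
experiment usually carries two more views of the tissue — the spot layout
itself and the stained histology image — and spots belonging to one
anatomical or functional *spatial domain* should agree across all three.
stMDA is for analysts who want domain maps and denoised expression that use
all the modalities at once instead of expression alone.

## The model

Expression `X1 ∈ R^{M×N}` is encoded three ways over the same N spots: a
graph convolutional network over the spatial kNN graph (normalized as
`D̃^{-1/2}(A+I)D̃^{-1/2}`), a variational encoder of expression alone
(latent `μ, σ`), and an MLP over per-spot image features `X2`.  The
per-layer representation distributions of the expression branch are pulled
toward the spatial and image branches with Gaussian-kernel maximum mean
discrepancy, both globally over all spots and locally within each spot's
k-neighborhood:

    L = recon + KL + λ · (Loss_align_global + Loss_align_local)

A shared attention vector fuses the three latents into the joint
representation `H` (per-spot softmax weights), and a decoder reconstructs
expression `X̃1` from `H`.  After training, `H` is Leiden-clustered into
spatial domains and `X̃1` serves as denoised expression.  Training is
full-batch Adam, float64, fully seeded, on a small built-in reverse-mode
autodiff engine — no GPU or deep-learning framework required.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

```python
import numpy as np
from stmda import SyntheticSpec, generate, STMDA, ari, morans_i

spec = SyntheticSpec(grid=(15, 15), n_genes=80, seed=0)   # 3 stripe domains
ds, truth = generate(spec)

model = STMDA(epochs=150, random_state=0)
labels = model.fit_predict(ds, target_domains=3)

print(f"ARI vs truth: {ari(labels, truth):.3f}")
hist = model.loss_history_
print(f"loss: {hist[0]['total']:.1f} -> {hist[-1]['total']:.1f}")
gene = 0  # marker gene of domain 0
raw = morans_i(np.log1p(ds.expression[gene]), ds.coords, k=6)
den = morans_i(model.denoised_[gene], ds.coords, k=6)
print(f"Moran's I gene_0: raw {raw:.3f} -> denoised {den:.3f}")
```

prints

```
ARI vs truth: 0.884
loss: 558.7 -> 250.2
Moran's I gene_0: raw 0.269 -> denoised 0.677
```

The clustering recovers the three planted stripe domains almost exactly
(ARI 0.88; 1.0 is perfect, 0 is chance).  The total loss falls as the
reconstruction, KL, and alignment terms are optimized.  Moran's I — spatial
autocorrelation of a gene's expression — rises from 0.27 to 0.68 after
denoising: the reconstruction smooths the marker gene's spatial pattern, as
expected for a gene expressed in one contiguous domain.

The same pipeline runs from the shell:

```sh
stmda simulate --layout stripes --domains 3 --grid 30x30 --seed 0 --out sim/
stmda fit --expr sim/expression.csv --coords sim/coords.csv \
          --image-features sim/image_features.csv \
          --lambda 1.0 --knn-k 6 --epochs 300 --domains 3 --seed 0 --out out/
```

Real data loads through `stmda.read_visium(dir)` (MTX triplet +
tissue-positions CSV) or `stmda.read_csv_bundle(expr, coords, features)`.

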