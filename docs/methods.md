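# Methods

## Model

stMDA treats a spatially resolved transcriptomics (SRT) experiment as a
multi-modal integration problem.  Gene expression `X1 ∈ R^{M×N}` (M genes,
N spots) is the *source* view; spatial coordinates and histology-derived
per-spot features `X2 ∈ R^{F×N}` are *target* views.  Three encoders produce
layer-wise representations of the same N spots:

- **Spatial branch** — a graph convolutional network over a spatial kNN
  graph.  Each layer computes
  `H1^(l) = φ_l(W^(l) H1^(l−1) D̃^{−1/2} Ã D̃^{−1/2} + b^(l))`
  with `Ã = A + I` and `D̃` its row-sum degree matrix, so features are
  smoothed over spatial neighborhoods.  `H1^(0) = X1`.
- **Expression branch** — a variational encoder of `X1` alone.  Hidden
  layers are plain affine+activation; the last layer has two linear heads
  producing `μ` and `log σ²`.  During training the latent is sampled by the
  reparameterization `μ + σ·ε`; in eval mode it is `μ`.
- **Image branch** — a plain MLP on the per-spot image features `X2`
  (z-scored per feature before entering the network; CNN-style features
  arrive on arbitrary scales and unstandardized inputs destabilize the
  kernel losses).

All branches share layer widths (default input → 128 → 10) but own their
parameters: the inputs have different dimensions, so literal weight sharing
is impossible at the first layer.

A shared attention vector scores the three final-layer latents per spot
(`softmax` of `W_attᵀ tanh(W h + b)` over modalities), and the weighted sum
is the joint representation `H`.  A mirror-image decoder (10 → 128 → M,
final layer linear) maps `H` back to expression space, giving the
reconstruction `X̃1` used for denoising.

## Spatial graph

Edges are the k nearest spots by Euclidean distance on the array
coordinates (default k = 6, the hexagonal Visium neighborhood).  Distance
ties break to the lower spot index, so construction is fully deterministic.
Edge weights are transcriptional: with `U` the 15-PC embedding of log
expression, the weight of edge (i, j) before normalization is
`exp(2 − d(U_i, U_j))`, then columns are normalized to sum to 1 over their
support.  Two conventions are implemented for `d`:

- `cosine_distance` (default): `d = 1 − cos(U_i, U_j) ∈ [0, 2]`, so
  identical neighbors get weight e² and opposite ones e⁰ — monotone in
  similarity, which is the evident intent of weighting similar neighbors
  more strongly;
- `as_printed`: `d = cos(U_i, U_j)`, the formula exactly as usually
  typeset.  This grows with *dis*similarity and is kept only as a flag for
  comparison, never as the default.

The kNN relation is asymmetric; we symmetrize by averaging with the
transpose before adding self-loops, since the symmetric normalization
presupposes a symmetric adjacency.  Spots with zero total counts are
dropped at load time — the column normalization divides by neighbor weight
sums and degenerate spots would propagate NaN.

## Alignment losses

The model's core is distribution alignment between the expression branch
and each target branch, measured by squared maximum mean discrepancy (MMD)
with a Gaussian kernel `K(x, y) = exp(−‖x−y‖²/2)` (bandwidth 1; a list of
bandwidths may be averaged).

Two estimators are implemented.  The default `standard_biased` V-statistic

    MMD²(X, Y) = (1/n²) ΣΣ K(x,x′) − (2/nm) ΣΣ K(x,y) + (1/m²) ΣΣ K(y,y′)

is non-negative and zero iff the two empirical samples coincide — the
property a "distribution difference" requires.  The `as_printed` variant
(coefficient 1 on the cross term, both sums over n) is retained as a
diagnostic; it is nonzero even for X = Y and is never used in training by
default.

The **global** loss sums `MMD²(H2^(l), H1^(l)) + MMD²(H2^(l), H3^(l))`
over encoder layers l = 1..K, treating spots as sample points.  Layer 0 is
excluded: the raw inputs have different dimensions.  The **local** loss
applies the same discrepancy per spot, restricted to the columns of each
spot's k spatial neighbors, summed over spots and layers.  Both source and
target representations receive gradients (no stop-gradient).

Cost: the local loss shares its N×N kernel Gram matrices with the global
loss, so one training step costs O(K · N² · width) regardless of k.  For
N > 2000 the local sum is estimated on 512 seeded spots per step and
rescaled by N (unbiased); below that it is exact.

## Objective and optimization

    L = recon + KL + λ (global + local)

with `recon` the squared reconstruction error summed over genes and
averaged over spots (a unit-variance Gaussian likelihood on log1p data),
and `KL` the closed-form divergence of the variational posterior from the
standard-normal prior, averaged over spots.  λ defaults to 1 and 0 disables
alignment entirely; `select_lambda` grid-searches λ by clustering agreement
(ARI or purity) with reference labels, ties to the smaller value.

Optimization is full-batch Adam with the usual defaults (lr 1e-3, betas
0.9/0.999, eps 1e-8), 500 epochs by default, float64 throughout, entirely
seeded: a fit reproduces its loss trajectory exactly.  The networks and
losses run on a small in-package reverse-mode autodiff engine over numpy;
the kernel Gram is a single fused op with a hand-derived backward pass
(verified against central finite differences).  Parameters initialize
Glorot-uniform from the seed; a NaN in any loss component aborts with the
epoch and component named.

Ablation switches mirror the model's components: `use_image` drops the
image branch and its MMD terms; `use_spatial` replaces the GCN with an MLP
on `X1` and drops the local loss (which needs neighbors);
`use_deep_alignment=False` aligns only the final layer;
`use_any_alignment=False` is exactly the λ = 0 run (identical trajectory,
asserted in tests).

## Preprocessing

Top-3000 highly variable genes on raw counts, then log1p, then 15-PC PCA
of the HVG-restricted log matrix (one canonical `X1` feeds the encoders
and the graph similarity).  HVGs are ranked by the Seurat-style dispersion
statistic computed on log data.  We rank by the *raw* dispersion rather
than the mean-binned z-normalization: with few genes per mean bin (always
the case on small inputs, and common when marker genes dominate a bin) the
within-bin z-score normalizes markers only against each other and inverts
the intended ranking.  Exact top-n selection with input order as the tie
break keeps the gene set deterministic.  PCA signs are fixed by forcing
each component's largest-magnitude loading positive.  No library-size
normalization is applied by default; `normalize_total` enables a
median-count scaling for users who want it.

## Image features

Tiles of side 32 px (configurable) are cropped around each spot's pixel
position, zero-padded at borders, and embedded by a pluggable `Embedder`.
The built-in embedder computes per-channel means and SDs plus a 10-bin
intensity histogram (16 dims) — deterministic, training-free, and
sufficient to separate stain-level differences.  Any callable with an
`output_dim` attribute can be plugged in (e.g. a pretrained CNN); a
precomputed feature CSV can bypass tiles entirely.  Feature extraction is
pure: `X2` is fixed before optimization.

## Domain calling and evaluation

The joint embedding `H` is clustered by Leiden on a 15-NN graph (scanpy).
When a target domain count is requested, the resolution is bisected in
[0.01, 5] for at most 40 iterations; if the exact count is unreachable the
closest labeling is returned with a warning flag rather than an exception.

Metrics: ARI (chance-corrected partition agreement) and purity against
references; silhouette and Davies–Bouldin computed on *spatial
coordinates* (spatial coherence of the called domains, not embedding
compactness); Moran's I with binary spatial-kNN weights (the same
neighborhood as the model graph) for per-gene spatial autocorrelation; and
per-domain log2 fold change (ε = 1e-9) with a >1 threshold for DEG
calling.

## Synthetic data

The generator emulates the study conditions end to end: a rows×cols
lattice of spots carved into contiguous domains (vertical stripes,
quantile rings, or Voronoi blobs); Poisson (optionally gamma-mixed
negative binomial) counts with per-domain marker genes whose log-mean is
shifted by `marker_log_effect` (default 1.5, i.e. ×4.5); independent
multiplicative dropout (default 0.3); and image features drawn as
per-domain standard-normal mean vectors plus Gaussian noise with SD
`1/image_signal` (default 0.5).  The default benchmark is a 30×30 lattice
(900 spots), 100 genes, 10 markers per domain, base mean 1.0 — a
realistic per-HVG count scale for spot-level SRT.  Everything is seeded.

What it does *not* emulate: platform-specific library-size profiles,
spatial covariance within domains beyond the hard domain boundaries,
segmentation noise in histology, or batch effects.  Passing the recovery
tests therefore shows the pipeline recovers planted, cleanly bounded
spatial structure under dropout — not performance on tissue.

One empirical caveat the tests surface deliberately: on this benchmark the
no-alignment (λ = 0) ablation is already near-perfect, because the
synthetic image features alone separate the domains linearly and still
reach the clustering through the attention fusion.  The benefit of
alignment that motivates the model appears on noisy, weakly separable
data; a fixture in that regime cannot simultaneously guarantee the ≥0.8
recovery bound.  The ablation-comparison test documents this honestly
rather than tuning the generator until both hold.

## Numerical choices and limitations

- float64 everywhere; MMD values within −1e-12 of zero are clamped to 0.
- kNN ties break to the lower index; HVG ties to input gene order; λ grid
  ties to the smaller λ.
- Zero-norm PC vectors get similarity 0 (logged), zero-variance image
  features map to 0 after standardization, constant genes are rejected by
  Moran's I.
- Single fits are full-batch; memory is O(N²) for the kernel Grams, which
  bounds practical N at a few thousand spots per fit on desk hardware.
  Problem sizes in the test suite (100–900 spots, 40–100 genes,
  20–300 epochs) were chosen to exercise every code path at desk scale.
- No multi-slice integration, no negative-binomial reconstruction head
  (Gaussian on log1p only), no GPU path.
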