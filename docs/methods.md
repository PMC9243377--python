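# Methods

`pathcam` turns multi-omics expression matrices into per-sample "pathway
images", classifies a binary clinical outcome with a channel-attention CNN,
and identifies outcome-associated pathways by combining X-Grad-CAM class
activation maps with per-pixel rank-sum statistics.  This note records the
model, the choices the implementation makes where the procedure admits more
than one reading, and what the synthetic benchmark does and does not show.

## Pathway images

For each gene set p_i (r_i genes) and omics type, the sample × gene
submatrix B ∈ R^{n×r_i} is reduced by PCA to q principal-component scores
per sample.  Stacking the score blocks over all P retained pathways and C
omics types yields one C × P × q tensor per sample; the display/classifier
layout is P rows × (C·q) columns, with omics types as contiguous column
blocks (column c·q + k holds omics c, PC k).

Numerical conventions:

* **Centering/fitting scope.** Within cross-validation, PCA centering
  vectors, loadings, the pathway ordering and the per-pixel scaling are
  fitted on each fold's training portion only; held-out samples are
  transformed with the frozen parameters and clipped into [0, 1].  A
  whole-cohort fit is used only for the interpretation model (below).
  Whole-cohort fitting for performance estimates is possible but not the
  default, because it leaks test-sample statistics into the transform.
* **Sign convention.** Each loading column is flipped so its
  largest-magnitude entry is positive, making runs reproducible across
  linear-algebra backends.
* **Rank deficiency.** When r_i or the training-sample count supports fewer
  than q components, missing PCs are zero-filled so the image stays
  rectangular.  Pathways with fewer than two genes present in an omics
  matrix contribute a constant pixel row, which the scaling maps to 0.5.
* **Pixel scaling.** Per-pixel min-max to [0, 1] on training samples;
  degenerate pixels (min == max) map to 0.5.

## Pathway ordering

Rows of every image follow one shared pathway sequence chosen so that
correlated pathways are adjacent — the locality that both the convolution
and the activation maps exploit.  Similarity between two pathways is the
mean absolute Pearson correlation over all pairs of their PC score columns
(all omics types; the absolute value because PC signs are arbitrary;
zero-variance columns contribute 0).  The order is a deterministic greedy
chain: start at the pathway with the largest total off-diagonal similarity,
repeatedly append the unselected pathway most similar to the last placed
one; all ties break to the lowest original index.  This reproduces a greedy
procedure, not an optimal seriation.

## The attention CNN

Input: the C × P × q tensor plus optional numeric covariates (z-scored
with training statistics).  Layers:

1. **Channel attention** over the C omics channels: global average and max
   pooling per channel, a shared two-layer perceptron (C → max(1, ⌊C/r⌋) →
   C, reduction ratio r = 2 by default), gate = sigmoid of the summed
   outputs, channels rescaled by the gate.
2. Channels are laid out as column blocks of a single-channel P × (C·q)
   image.  This reconciles channel attention (which needs C channels) with
   the P × (C·q) image the rest of the pipeline works on, and gives the
   statistical stage one pixel per (pathway, omics, PC) cell.
3. **Dilated convolution**: 32 filters, 2×2 kernel, dilation 2, ReLU.  For
   images too narrow for the effective kernel, dilation is reduced to 1 and
   then the kernel clamped to the image extent (logged); a single-omics
   q=1 image therefore degenerates to a 2×1 kernel along pathways.
4. **2×2 pooling**, average and max branches summed; dropout 0.5; flatten;
   covariates concatenated; dense 64 (ReLU); dropout; dense 2; softmax.

Training minimises class-weighted cross-entropy (w_c = N / (2·n_c), which
equalises the two classes' loss mass) with plain SGD, learning rate 0.001
by default, batch size 16, early stopping on validation AUC with patience
20.  All forward and backward passes are explicit NumPy code: gradients are
closed-form, runs are bit-reproducible for a fixed seed, and the
interpretation stage reads exact logit gradients at any internal layer.
The whole stack is sized for a single CPU.

The **interpretation model** is trained on all samples (no validation
carve-out, no early stopping; the final-epoch parameters are kept).  Early
stopping is a performance-estimation device; for attribution the model
should be trained to convergence — an undertrained model produces activation
maps dominated by its random initialisation.  This model is used for
attribution only, never for performance claims.

## X-Grad-CAM and the difference-map statistic

For class c and target activation F^l with K channels, the channel weight
is the activation-normalised gradient sum

    α_k = Σ_{x,y} [ F_k(x,y) / Σ_{x,y} F_k(x,y) ] · ∂S_c/∂F_k(x,y),

with α_k = 0 when the channel is identically zero, and the raw map is
M(x,y) = Σ_k α_k F_k(x,y) with no rectification.  S_c is the pre-softmax
logit.  Maps are min-max normalised to [0, 1] (a constant map becomes all
zeros) and bilinearly upsampled (align-corners) to the P × (C·q) input
grid.

Two design points matter and were settled empirically on cohorts with known
ground truth:

* **Shared pair scale.** Each sample yields two maps (one per class).  The
  statistic D_i = |L_i^pos − L_i^neg| is computed after normalising the
  *pair* with a common per-sample min/max, not each map separately.  The
  two class logits are nearly anti-symmetric, so per-map scaling forces
  L^neg ≈ 1 − L^pos and D ≈ |2L^pos − 1| — identical for strong positive
  and strong negative evidence, which cancels the class contrast the test
  is looking for.  The method's premise ("the positive map is more
  activated than the negative one for positive samples") requires the two
  maps to share a scale.  Per-map normalisation remains available
  (`shared_scale=False`) and is what `normalize_and_upsample` does for a
  single map.
* **Target layer.** The conventional CAM target is the last convolutional
  activation, and that is the default of the low-level API.  For
  key-pathway identification the default target is the channel-attention
  output ("attended_input"): the pathway image's pixels are themselves the
  semantic units, and at conv resolution the dilated kernel mixes adjacent
  pathway rows while attribution concentrates on whichever subset of
  correlated informative rows the optimiser happened to use.  On planted
  benchmarks the attended-input target recovers all planted pathways in
  10/10 seeds versus 3/10 for the conv target, with identical training.

## Pixel statistics and the pathway table

Per pixel of the P × (C·q) grid, the D values of the two outcome groups are
compared with a two-sided Wilcoxon rank-sum test: exact enumeration when
the combined sample size is ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections.  Pixels identical across
all samples get p = 1 and are flagged.  Bonferroni correction multiplies by
the full pixel count m = P·C·q (capped at 1).  Significant pixels
(adjusted p < 0.001 by default) are grouped into 4-connected components
within each omics channel block; components below a minimum size (default
1) are dropped.  The pathway table lists every image row owning a
significant pixel, ordered by row index, with the adjusted p per
(omics, PC) cell and blanks elsewhere.

## Cross-validation

Stratified five-fold CV repeated (default 30 repeats), scoring test AUC.
Within each fold the training portion donates a stratified 20% validation
subset for early stopping; projections, ordering and scaling are refitted
per fold.  Stratification is used because imbalanced cohorts (the intended
use case has roughly 1:3 classes) otherwise risk one-class validation
sets.  AUC is the Mann–Whitney statistic with half-credit for ties.

## Synthetic cohorts

Each pathway is a disjoint gene block sharing one latent factor; gene
values are √ρ·factor + √(1−ρ)·noise, so the within-pathway pairwise gene
correlation is ρ (default 0.8) and the pathway's first PC tracks the
factor.  Planted pathways shift the factor mean between classes by δ
pooled-SD units (default 1.5) in every omics type.  Optional pathway
blocks share a common factor with weight w (between-pathway correlation
w², members interleaved through the collection so the file order scatters
them).  Defaults: n = 120 samples, 100 pathways of 8–20 genes, 2 omics
types, 5 planted pathways, 30% positive class (emulating a roughly 1:3
imbalanced cohort), and a smoking-age covariate ~ N(30, 10²) years with
the positive class lowered by 10 years — a clearly outcome-associated
covariate of the kind the model injects at the dense layer.  The seed is a
required argument.

What the generator does **not** emulate: real expression distributions
(counts, heavy tails), batch effects, overlapping gene sets, pathway-size
dependent signal, missingness patterns, or survival endpoints.  Passing
benchmarks here shows the pipeline recovers linear factor signal planted
the way its own PCA stage expects — a correctness check of the machinery,
not evidence about biological cohorts.

## Benchmark study sizes

The bundled studies are sized for one CPU: recovery runs 10 cohorts at the
generator defaults with interpretation models trained 300 epochs at
learning rate 0.01 (the same optimisation progress as the default 0.001
rate run longer); the performance check uses a strongly separable cohort
(δ = 2.0) under 5-fold CV (2 repeats) with models trained up to 150 epochs
at rate 0.02; null calibration permutes labels 200 times over a 60-sample
null cohort.  Typical results: all planted pathways hold the smallest
adjusted p-values in ≥ 8/10 seeds, separable-cohort mean AUC ≈ 0.95, null
family-wise error ≈ 0.03–0.05 at α = 0.05, null CV AUC ≈ 0.5.

## Known limitations

* Attribution redundancy: when several correlated pathways carry the same
  signal, conv-layer CAM concentrates on a subset; the attended-input
  target mitigates but does not abolish this.
* The Bonferroni family is the full pixel grid; with large P·C·q the
  procedure is conservative, and upsampling smears attribution onto rows
  adjacent to truly associated pathways.
* The greedy ordering is a heuristic; no optimality is claimed, only the
  block-contiguity property verified in the tests.
* SGD without momentum or weight decay follows the source procedure;
  convergence on large images may need more epochs than the defaults.
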