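# pathcam

Interpretable deep learning on multi-omics data via **pathway images**:
per-pathway PCA turns sample × gene matrices into per-sample 2-D images
(rows = gene sets, columns = principal-component scores, channels = omics
types), a **channel-attention CNN** classifies a binary clinical outcome
from those images, and **X-Grad-CAM** class-activation maps combined with
per-pixel Wilcoxon/Bonferroni statistics pinpoint the pathways that drive
the classification.

The intended users are computational biologists who have expression-like
matrices for one cohort (e.g., lung adenocarcinoma patients with and
without a primary tumor symptom), a gene-set collection in GMT format, and
a binary label — and who want both a cross-validated classifier and a
ranked table of outcome-associated pathways.

## Method in brief

For pathway p_i with r_i genes, the submatrix B ∈ R^{n×r_i} is reduced by
PCA to scores G_{p_i} ∈ R^{n×q}; over P pathways and C omics types this
gives each sample an image of P rows × (C·q) columns, min-max scaled per
pixel, with rows ordered so correlated pathways are adjacent (greedy
mean-|Pearson| chain).  The classifier applies channel attention
M_c = σ(MLP(avgpool F) + MLP(maxpool F)) over omics channels, then a
dilated 2×2 convolution (32 filters), summed 2×2 average/max pooling,
dropout 0.5, a 64-unit dense layer with injected covariates, and softmax;
training uses SGD with class weights w_c = N/(2·n_c).  For interpretation,
X-Grad-CAM weights each feature channel by

&nbsp;&nbsp;α_k^c = Σ_{x,y} [ F_k(x,y) / Σ_{x,y} F_k(x,y) ] · ∂S_c/∂F_k(x,y),

forms M_c(x,y) = Σ_k α_k^c F_k(x,y), normalizes and upsamples it to the
image grid; per sample the two class maps give D_i = |L_i^pos − L_i^neg|,
and per pixel a two-sided Wilcoxon rank-sum test compares D across outcome
groups, Bonferroni-corrected over all P·C·q pixels.  Significant pixels
form 4-connected hotspots and a ranked pathway table.  Performance is
estimated by repeated stratified five-fold cross-validation (AUC), with
all transforms refitted per fold.  `docs/methods.md` has the full account,
including the normalization and target-layer choices.

Everything — including the CNN's forward/backward passes — is plain
NumPy/SciPy, deterministic for a fixed seed, and sized for one CPU.

## Worked example

`examples/03_identify_key_pathways.py` generates a synthetic two-omics
cohort (120 samples, 100 pathways, 5 of them carrying a 1.5-SD
class-dependent latent factor shift), trains the interpretation model on
all samples, and runs the full attribution stage:

```
200 pixels tested; 10 significant at Bonferroni-adjusted p < 0.001
hotspots: [(0, 5), (1, 5)] (omics channel, pixel count)

ranked pathway table (blank cells = not significant):
 row      pathway   omics1_PC1   omics2_PC1
   1 PATHWAY_0092 1.126628e-11 1.126628e-11
   2 PATHWAY_0045 1.267078e-12 1.267078e-12
   3 PATHWAY_0001 3.357691e-13 3.357691e-13
   4 PATHWAY_0057 7.586542e-12 7.586542e-12
   5 PATHWAY_0083 1.167332e-10 1.167332e-10

ground truth planted pathway indices: [1, 45, 57, 83, 92]
```

All five planted pathways — and only those — reach significance, in both
omics channels; note the ordering stage has placed them on adjacent image
rows 1–5.  The other examples build images (`01`), cross-validate
(`02`, printing a mean test AUC around 0.95–0.97 on a strongly separable
cohort), and demonstrate the pathway ordering on block-correlated cohorts
(`04`).

## Command line

Each stage is also a subcommand of `pathcam`:

```bash
pathcam simulate --config cohort.yaml --out data/
pathcam build-images --expr data/expr_omics1.tsv:rna --expr data/expr_omics2.tsv:cnv \
        --gmt data/pathways.gmt --annotations data/annotations.tsv --q 1 --out images/
pathcam cv --expr data/expr_omics1.tsv:rna --gmt data/pathways.gmt \
        --annotations data/annotations.tsv --repeats 30 --seed 7 --out cv.tsv
pathcam train --images images/ --annotations data/annotations.tsv --out model/
pathcam explain --model model/ --images images/ --annotations data/annotations.tsv --out maps/
pathcam identify-pathways --model model/ --images images/ \
        --annotations data/annotations.tsv --alpha 0.001 --out table.tsv
pathcam run-all --config run.yaml
```

Inputs are plain TSV/CSV matrices (IDs in the first row and column),
standard GMT gene sets, and a sample table with a binary class column and
optional numeric covariates.

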