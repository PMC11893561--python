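# Methods

## Problem setting

Whole-slide images (WSIs) are gigapixel scans labeled only at the slide
level.  The standard computational treatment is multiple-instance learning
(MIL): a slide is a *bag* of cropped patches (*instances*), the bag is
positive iff at least one instance is positive, and instance labels are
unobserved.  This package operates entirely downstream of feature
extraction: a bag is a set of row-aligned embedding matrices per patch —
patch features `F_p` (m x 512), cell features `F_c` (m x 1280) and text
features `F_t` (m x 512) — of the kind produced by pathology foundation
models (a vision-language patch encoder, a nuclei-segmentation encoder, and
caption embeddings).  Producing those embeddings from pixels is out of
scope; the package consumes them.

The pipeline has three stages:

1. **Anomaly detection.**  A variational autoencoder with either a standard
   normal prior (`mode="vae"`) or a learnable K-component Gaussian-mixture
   prior (`mode="gmvae"`) is trained **only on instances from normal
   bags**.  Posterior: `q(z|x) = N(mu(x), sigma^2(x) I)`; likelihood
   `N(x; x_hat, I)`, so the negative ELBO is a mean-squared reconstruction
   error plus a KL term.  The Gaussian KL is closed-form; the mixture KL is
   estimated by Monte Carlo as `E_q[log q(z|x) − log p(z)]`, with the
   mixture density evaluated by log-sum-exp.  After training the model is
   frozen; each instance gets a reconstruction embedding
   `f_r = Dec(Enc(f_p))` (deterministically, through the posterior mean)
   and an anomaly score `e_i = ||f_p,i − f_r,i||^2`.
2. **Top-k selection.**  With a fraction `k` in (0, 1], a bag keeps
   `ceil(k*m)` instances: either the largest-error instances (*max*), or a
   ceil/floor split between largest- and smallest-error instances
   (*minmax*), or everything (*none*, the no-selection ablation).  Ties are
   broken by original index (stable sort), so selection is deterministic.
3. **Fusion and classification.**  Single-head cross-attention blocks
   (`softmax(QK^T/sqrt(d_k)) V`) are cascaded: text queries attend over
   cell features, the result queries patch features, and reconstruction
   features query the result.  Rows (instances) are preserved through the
   cascade; the bag representation is the row mean of the last block,
   classified by a linear head.  Class imbalance is handled by weighted
   cross-entropy with `w_c = N_total / (C * N_c)` (so
   `sum_c N_c w_c = N_total`).  In unimodal mode (`F_p` + `F_r` only) a
   fixed-size learnable latent array attends to the representation
   (Perceiver-IO style), making the readout cost independent of bag size.

## Synthetic data model

Real slide archives and foundation-model inference are far beyond desk
scale, so the package ships a generator that emulates the statistical
structure the method assumes, in embedding space only:

* Normal instances: latent `z` from a K-component Gaussian mixture
  (default K=3, latent dim 16, component means `3*e_k`, unit scales,
  uniform weights); each modality is a fixed linear map of the same latent
  (entries `N(0, 1/sqrt(16))`, keyed by `map_seed`) plus isotropic Gaussian
  noise (sd 0.25 per coordinate).  Sharing one latent across modalities
  mimics patch/cell/text views of one tissue region.
* Abnormal instances: the same mixture **shifted** by
  `abnormal_shift * v`, where `v` is one fixed random unit direction per
  dataset (drawn from `map_seed`, like the maps).  Tumor instances thus
  form a coherent off-manifold cluster, the way a distinct morphology
  does; a per-instance random direction would instead make class means
  identical by symmetry and no convex-combination aggregator could
  separate bags.  `abnormal_shift` (default 4.0) is the single effect-size
  knob, and reconstruction error is monotone in it.
* Bags: size uniform in [30, 80]; negative bags are all-normal; positive
  bags contain `ceil(0.1 * m)` abnormal instances at random positions
  (ceiling guarantees at least one).  Hidden instance labels are kept as
  synthetic ground truth for instance-level evaluation only.
* Reproducibility: bag `i` draws from `SeedSequence(seed, spawn_key=(i,))`,
  so datasets are bitwise reproducible and parallelizable.

### How separable are instances, at best?

A detector trained only on normal bags cannot know the abnormal shift
direction `v`, so by rotational symmetry the best direction-blind
instance score is radial: the squared latent distance to the nearest
component mean, `chi^2(16)` for normal instances versus noncentral
`chi^2(16, 16)` for abnormal ones at shift 4 and unit component scales.
A normal approximation puts that oracle's instance AUC at about
`Phi(16 / sqrt(32 + 96)) ~= 0.92`.  Reconstruction-error scoring is one
realization of a radial score, so the instance-level AUC the pipeline
reports should be read against this ceiling rather than against 1.0;
pushing the effect-size knob (`abnormal_shift`) up or the component scales
down is how a user makes the instance problem easier.  Bag-level classification is
much easier than instance scoring because the fusion model aggregates
many instances and sees the (consistent) shifted cluster directly.

What the generator does **not** emulate: real foundation-model embedding
geometry (effect sizes are not calibrated to any particular encoder),
spatial correlation between neighboring patches, staining/batch effects,
or heavy-tailed noise.  Passing tests on this generator shows the pipeline
recovers planted structure under its own assumptions, not clinical
performance.

## Default parameters and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| AD encoder/decoder | MLP 512-256-128, twin linear heads, mirrored decoder | enough capacity to fit normal variation at these dims |
| AD activation | tanh | saturating units extrapolate poorly off the training support, which is what reconstruction-error scoring needs; relu nets reconstructed abnormal inputs too well (instance AUC 0.83 vs 0.92 on matched data) |
| AD latent dim / KL weight (pipeline) | 8 / 100 | beta-VAE-style bottleneck: with the plain ELBO (weight 1, latent 16) the autoencoder nearly inverts the generator's linear map and reconstructs ~90% of the abnormal displacement; a narrow, heavily regularized latent contracts encodings toward the normal manifold.  `ADTrainConfig` itself defaults to kl_weight 1.0 (the faithful ELBO); the pipeline-level default overrides it for scoring |
| AD optimizer | Adam, lr 1e-3, batch 128, 120 epochs (pipeline) | the bottlenecked objective converges slowly; detection quality saturates near 120 epochs |
| Mixture components K | 5 | a few more modes than the generator truly has; weights/means/variances are learned jointly by gradient (logits / log-variances keep them unconstrained) |
| Mixture KL samples `n_mc` | 1 per step | standard single-sample estimator; large `n_mc` only in verification |
| Scoring | `z = mu(x)`, no sampling | selection must be reproducible run to run |
| Selection | max, k = 0.3 | the reference operating point for the multimodal cascade |
| Fusion `d_model` | 512 | native patch/text dim; per-block learned Q/K/V projections reconcile the 1280-dim cell features |
| Fusion optimizer | Adam, lr 3e-5, weight decay 1e-3 (decoupled), one bag per step, 20 epochs | per-bag steps handle variable bag size; at lr 1e-4 the single-bag noise destabilizes training at reference scale (oscillating loss); at 3e-5 the loss converges below 1e-3 within ~15 epochs.  The cascade has ~4M parameters against a few hundred bags, so it memorizes the training set — decoupled weight decay suppresses the resulting confidently-wrong held-out predictions, and stopping at 20 epochs avoids training far past convergence |
| Class weights | `N_total/(C*N_c)` from training labels | conserves `sum N_c w_c = N_total` |

## Numerical choices

* Mixture log-densities and softmaxes use max-shifted log-sum-exp; the
  shift is treated as a constant in differentiation.
* Training runs in float32 (scalar constants adopt the graph dtype so
  nothing silently upcasts); the closed-form math functions keep the dtype
  of their inputs, so float64 verification is exact.
* Selection sorts with a stable descending order; equal errors keep the
  lower original index first.  For minmax with an odd budget the extra
  instance goes to the max side (`h_max = ceil(n_sel/2)`), since max
  selection is the stronger single strategy.
* AUC is the Mann-Whitney rank statistic with midrank tie handling; a
  threshold-sweep trapezoidal ROC integral is kept as an independent
  cross-check.
* Degenerate guards: empty bags, empty selections, single-class AUC input,
  and non-normal bags reaching the anomaly detector all raise.

## Training protocol

The experiment harness holds out a stratified test set once per dataset
(default 20%), then runs stratified k-fold cross-validation (default 5) on
the rest.  Within each fold the anomaly detector is trained only on the
label-0 bags of that fold's training split — positive bags never touch it
— then the fold's bags are scored, selected and used to train the fusion
classifier.  Fold models are evaluated on fold-validation bags and the
fixed test set; metrics are reported as mean ± sd over folds.  Every stage
derives its seed from the run seed, and reruns produce byte-identical
metrics files.

Reference problem sizes: the shipped study configuration uses 200 bags
(100 normal / 100 tumor) with 30-80 instances per bag, a single 80:20
split for the headline numbers, and the cross-validated harness for grids.
These sizes are the package's reference conditions for the synthetic
study; all stages scale linearly in bags and instances.

## Known limitations

* The autodiff engine is minimal by design (dense 2-D matmul, broadcast
  arithmetic, reductions); there is no GPU path and no batched attention
  across bags.
* The fusion cascade follows a fixed modality order (text -> cell ->
  patch -> reconstruction), skipping absent modalities; other orderings
  are not explored.
* Multi-head attention, residual connections and layer normalization are
  deliberately absent: the fusion blocks are single-head scaled
  dot-product attention plus linear projections.
* Recall for more than two classes is macro-averaged one-vs-rest; the
  shipped tasks are binary.
* Instance-level evaluation requires the generator's hidden labels and is
  therefore synthetic-only.
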