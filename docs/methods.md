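# Methods

## Problem setting

The package targets semi-supervised image classification in regimes
typified by endoscopic grading of inflammatory bowel disease: classes that
look alike (ulcerative colitis vs. Crohn's disease vs. normal mucosa),
strong heterogeneity *within* each class (one disease presents as several
visually distinct modes), and labels that are expensive while unlabeled
images are plentiful. A dataset is a manifest of images with integer class
labels (−1 for unlabeled), a patient id per image, and a split column;
splits are always patient-level so no patient contributes to both training
and testing, nor to both the labeled and unlabeled pools.

## Model and objective

Three networks share an encoder g_θ: a prediction head h_θ giving class
probabilities p(y|x) and a projection head h_φ giving an ℓ2-normalized
embedding z ∈ R^D. Each iteration samples B_l labeled and B_u unlabeled
images, weak-augments everything and strong-augments the unlabeled images
twice. The objective is

L_total = L_s + λ1·L_u + λ2·L_sac

* **L_s** — mean cross-entropy (natural log) of labels against predictions
  on weakly augmented labeled images.
* **L_u** — confidence-thresholded pseudo-labeling: the soft pseudo-label
  q_m is the prediction on the weak view of unlabeled image m; when
  max q_m strictly exceeds T the hard label q̂_m = argmax q_m supervises
  the *first* strong view. The sum is divided by B_u, not by the number of
  retained samples.
* **L_sac** — the subclass-aware contrastive term, (L_conf + L_unc)/(2B_u),
  computed on the multi-view batch of 2B_u strong views whose soft
  pseudo-labels are shared between the two views of one image.

Within the multi-view batch, views with max q̃ > T_conf form the confident
set, the rest the uncertain set (the partition is strict at the threshold
and pairs always co-partition). Uncertain anchors get the instance-level
loss: positive = the partner view, denominator = all other 2B_u−1 views,
temperature τ. Confident anchors are grouped by predicted class; each
group is assigned to that class's K unit-norm prototypes by entropic
optimal transport maximizing ⟨M, PᵀZ⟩ + κH(M) under per-sample mass 1 and
per-prototype mass N_c/K (the equipartition that prevents collapse onto
one prototype), solved by Sinkhorn–Knopp in the log domain. The argmax of
a sample's transport column is its subclass; the two views of an image are
assigned independently. A confident anchor's loss adds its partner term
plus, for every other confident view with the same class and prototype, a
log-ratio weighted by the product of the two max pseudo-probabilities, all
divided by 1 + |Pos(i)|. After the optimizer step each prototype moves by
momentum α toward the normalized center of its assigned embeddings and is
renormalized to unit length (the convex combination alone would leave the
sphere, and the transport similarities presume unit prototypes).

Pseudo-labels, transport plans and prototype updates are all computed
outside the differentiated graph; gradient flows only through the
cross-entropy and contrastive log-ratios.

The printed transport constraints one sometimes sees for this construction
(row sums 1_K together with column sums (N_c/K)1_{N_c}) are mutually
inconsistent for N_c ≠ K; the implementation enforces the standard
interpretation — each sample carries unit mass, each prototype receives
N_c/K — which is the only reading compatible with "assign each sample to a
prototype" and with the equipartition rationale.

## Default hyperparameters

| parameter | default | meaning |
|---|---|---|
| T | 0.8 | pseudo-label retention threshold (strict) |
| T_conf | 0.9 | confident/uncertain partition threshold (strict) |
| τ | 0.1 | contrastive temperature (standard default; configurable) |
| κ | 0.05 | entropic smoothness of the transport plan |
| K | 3 | prototypes (subclasses) per class |
| D | 128 | embedding dimension |
| α | 0.99 | prototype EMA momentum |
| λ1, λ2 | 1, 2 | weights of L_u and L_sac |
| B_l, B_u | 40, 80 | labeled / unlabeled batch sizes |
| epochs | 150 | linear LR decay 1e-3 → 1e-6, AdamW weight decay 5e-4 |

Sinkhorn runs 3 alternating scalings by default (early stop at marginal
residual 1e-6), always ending on the per-sample normalization so each
column sums to exactly 1 on exit. All argmax tie-breaks take the lowest
index. Contrastive ratios are computed via log-sum-exp with the self-pair
masked by a large negative additive constant; losses remain finite for any
dot products in [−1, 1] and τ ≥ 0.01.

`TrainConfig.desk()` is the CPU-scale preset used by the package's own
experiments: B_l=8, B_u=16, 30 epochs, D=64, the 4-block conv encoder, and
a λ2 warm-up (below). These sizes were chosen so that a full paired
comparison over five seeds completes in a few minutes on a single core;
they are the package's desk-scale operating point, not tuned quantities.

## Training machinery

No GPU framework is used: the package carries a compact reverse-mode
automatic differentiation core on numpy arrays (`sacssl.tensor`), with
exactly the primitives the objective needs (conv2d via im2col, matmul,
reductions, gather, stable log-sum-exp composites), plus AdamW with
decoupled weight decay. Gradients of every layer type are verified against
central finite differences in the test suite. Two encoder presets are
provided — a 4-block stride-2 conv net and a tiny two-block single-head
vision transformer — behind a pluggable contract; full-scale backbones are
out of scope but the contract admits them. Epochs follow the data-chunk
scheme: both pools are shuffled independently and the labeled loader
cycles (reshuffling on exhaustion) while one pass over the unlabeled pool
defines the epoch.

### λ2 warm-up

With a pretrained encoder, confident samples appear early and the
instance-level loss touches only a shrinking uncertain set. From a cold
start, however, *every* view is uncertain, and full-strength instance
repulsion from the first step holds the classifier's confidence down — a
feedback loop in which the pseudo-label threshold is never crossed, the
uncertain set never shrinks, and the semi-supervised branch never engages
(measured on the synthetic task: pseudo-label coverage stays at 0 for the
whole run, while the pseudo-labeling-only configuration reaches coverage
above 0.8). `lambda2_warmup_epochs` therefore ramps λ2 linearly from 0
over the opening epochs, letting the pseudo-labeling branch bootstrap
before the contrastive module engages — a stand-in for the pretrained
initialization a full-scale run starts from. The default is 0 (the printed
objective); the desk preset uses 10 of 30 epochs. The per-iteration log
records the effective λ2 so the objective decomposition remains checkable.

## Synthetic data

The generator emulates the geometry of the motivating task rather than its
appearance: subtle between-class differences and large, *structured*
within-class variability. Every class shares one mucosa-like color tint —
classes are deliberately not separable by color — and is defined by a
texture family (oriented gratings, soft blob lattices, checkerboards, with
frequency variants beyond three classes); each of its k_true subclasses is
a deterministic geometric variant (orientation, blob count, cell scale).
Individual images add phase/position jitter, a per-image illumination
factor, and Gaussian pixel noise (noise_sd, default 0.08 on the [0,1]
scale), then clip to [0,1]. Images therefore cluster around per-subclass
pixel centroids that are tighter than class centroids — the structure the
prototype machinery is meant to discover. Patients belong to one class and
receive a uniform number of images (no per-patient count distribution is
imposed); class imbalance is off by default, with `class_proportions`
available as a preset for imbalanced regimes.

What the generator does **not** model: photorealistic mucosa, endoscope
optics, specular highlights, label noise, inter-patient appearance shifts,
or domain shift between centers. Passing tests on this data demonstrate
that the optimization machinery behaves as designed — that the losses are
computed correctly, that transport assignment recovers latent modes, and
that unlabeled data improves accuracy when labels are scarce — not that
the method reaches any particular accuracy on clinical images.

A separate fixture generator samples unit vectors around C·k_true
well-separated directions on the sphere (sample ≈ normalize(κ·μ + ε)),
giving ground-truth subclass structure directly in embedding space for
testing the assignment machinery in isolation.

## Evaluation

Accuracy is the proportion of correctly classified test images
(trace/total). Sensitivity, specificity and F1 are one-vs-rest per class
and macro-averaged. The per-class one-vs-rest accuracy average
Σ(TP_c+TN_c)/Σ(TP_c+TN_c+FP_c+FN_c) is reported alongside as
`per_class_avg_accuracy`; for C>2 it differs from trace/total (each
correct sample appears in C one-vs-rest tallies, each error in C−2) and is
included only for transparency. Per-class terms with zero denominators
contribute 0 and raise a warning rather than poisoning the macro average
on small test sets.

Model comparison uses a percentile bootstrap (not BCa) of the paired
macro-F1 difference under image-level resampling, 10,000 replicates by
default; both resampling unit and replicate count are configurable, and a
fixed seed reproduces the interval bit-for-bit. Subclass recovery is
scored by the adjusted Rand index between discovered prototype assignments
and ground-truth subclasses, computed within each true class and pooled by
sample-weighted mean; degenerate single-cluster partitions score 0.

## Design choices that were genuinely open

* The unsupervised loss uses the first strong view; the second exists for
  the contrastive module.
* Thresholds are strict inequalities at T and T_conf.
* Cutout is applied after the sampled strong operations (the conventional
  recipe), with reflection padding for geometric ops so outputs stay in
  range.
* The two views of an image may land on different prototypes; forcing
  agreement was considered and rejected in favor of the per-view
  definition.
* Contrastive denominators include the partner view (index j ≠ i only).
* Labeled images do not enter the contrastive batch.
* Prototypes are non-learnable state (no gradient), initialized uniformly
  on the sphere.
* The iteration order is forward → losses → optimizer step → prototype
  EMA update, so assignments reflect the embeddings the losses saw.
* Classes with no confident samples in a batch are skipped; N_c < K is
  allowed (per-prototype mass below 1).

## Known limitations

* Pure-numpy training limits practical scale to small images and encoders;
  the desk experiments use 32×32 images and a ~50k-parameter conv net.
* Entropic transport converges slowly on near-degenerate instances at
  small κ; the feasibility-critical column normalization is exact by
  construction, but tight row-marginal tolerances can require many
  iterations (tests use generous iteration caps on tiny matrices).
* The λ2 warm-up is a documented departure from the fixed-weight
  objective, needed only for cold-started encoders.
* The bootstrap treats images as exchangeable; patient-level resampling is
  available but not the default, and no calibration or ROC analysis is
  provided.
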