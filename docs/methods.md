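# Methods

This note records the models, parameter choices and numerical conventions
behind `morphoprof`, and what the synthetic testbed does and does not show
about real screens.

## The causal picture

A perturbation experiment has four variables: treatments (chosen by the
experimenter), phenotypes (latent outcomes), technical confounders (latent
batch/plate/well effects) and images (observed, influenced by both latent
variables). A classifier trained to predict treatments from images can
reach its target through *either* latent path — phenotype or confounder —
because non-randomized plate maps tie treatments to positions and plates.
The workflow therefore (a) learns a rich representation with the weak
treatment-classification pretext task, and (b) uses control wells to model
unwanted variation and remove it linearly (sphering) before any biological
comparison.

## Synthetic experiment generator

Cells are parametric blobs: a smooth nucleus disc (channel 1) of base
radius 5 px and a cytoplasm annulus (channels 2–5) of base radius 11 px,
with per-cell radius/intensity jitter, additive Gaussian camera noise
(σ = 0.01 intensity units) over a background of 0.04, scaled by 20,000
counts/unit into 16-bit range. Realism is deliberately sacrificed for
statistical controllability — downstream stages only need structure whose
ground truth is known.

**Phenotypes.** Each MoA class draws a random unit *signature* over 7
response knobs: 5 per-channel intensity multipliers and the nucleus/cell
radii. A treatment's signature is its class signature plus 25% jitter,
renormalized; same-class treatments therefore share a phenotype direction,
which is what makes MoA retrieval meaningful. A treatment with effect size
`e` and signature `s` multiplies channel `c` intensity by `exp(0.4·e·s_c)`
and the radii by `exp(0.2·e·s_{5,6})` — monotone in `e` by construction.

**Confounders**, two hierarchical levels:

* *plate*: a multiplicative illumination ramp (random orientation,
  amplitude = `plate_effect`), a brightness factor, and — because real
  plates also differ in growth and acquisition conditions — a plate-wide
  cell-size factor and camera-noise scale;
* *well position*: an additive background offset whose systematic component
  depends on the well's (row, column) — this is what makes the fixed plate
  map a genuine confounder — plus a random per-(plate, well) component,
  noise-scale and cell-size drift.

The non-affine components (noise level, cell size) matter: purely affine
brightness shifts are invisible to a model trained with per-channel
brightness augmentation, whereas real technical variation leaves texture
and morphology traces. They are what lets a leave-cells-out model exploit
well signatures, reproducing the characteristic validation gap between the
two split schemes.

**Defaults** (the package's desk-scale study conditions): 3 plates × 32
wells (20 treatments at fixed positions + 12 controls) × 2 sites, 15
cells/site (Poisson), 256×256 px, effect sizes graded linearly from 0 (no
phenotype — as in real screens) to 3, `plate_effect` 0.3, `well_effect`
0.15. Per-site RNG streams are derived by hashing (seed, plate, well,
site), so rendering is order-independent and any subset is reproducible.

**Not emulated**: photorealistic morphology, segmentation errors (nucleus
centers are exact), cell crowding/contact biology, day/batch structure
above plates, and dose–response (a single concentration per treatment).
Passing tests on this generator show the *pipeline machinery* recovers
injected structure under controlled confounding; they do not certify
performance on real Cell Painting data.

## Preprocessing

Illumination surfaces are the per-pixel mean over a plate-channel,
downscaled to 25% of height/width, median-filtered (window = ¼ of the
downscaled dimension, rounded odd) then Gaussian-smoothed (σ = window/4),
and normalized so the robust (1st percentile) minimum is 1 — correction
only brightens relatively dark regions, and a flat field is a no-op.
The smoothing recipe is this package's choice of a standard retrospective
correction; the window is configurable.

Percentile stretch uses the linear-interpolation empirical percentile on
each image alone (0.05 / 99.95), clips, maps affinely to [0, 255] and
rounds half-to-even (bit-reproducible); constant images map to 0. The
16→8-bit step is an exact 2× buffer reduction; PNG adds a content-dependent
factor on top.

## Training

Crops are 128×128×5 by default (32×32 in the desk-scale configs), centered
on the nucleus with zero-padding at borders, never resized and never
masked — context is preserved deliberately. The crop window is the
half-open square `[c − s/2, c + s/2)` in 0-based pixel coordinates
(x = column).

Each epoch draws exactly the median class size from every treatment
(larger classes subsampled without replacement, smaller oversampled with
replacement) and re-draws every epoch. Augmentation: random crop-and-resize
(p = 0.5, scale 0.8–1.0), horizontal flip and k·90° rotation, then
per-channel affine brightness/contrast jitter (Δ ~ U(−0.15, 0.15), factor
~ U(0.8, 1.2)) in which all pixels of a channel move together, followed by
re-clipping to the valid range. The re-clip (rather than a per-channel
min-max) is deliberate: a min-max renormalization is invariant to affine
maps and would exactly undo the jitter it follows, besides shifting the
training distribution away from the unaugmented crops seen at inference;
the min-max variant remains available as an option.

The optimizer is plain SGD (momentum 0, constant learning rate), batch 32,
categorical cross-entropy with label smoothing 0.1; the screen-scale recipe
(30 epochs, lr 0.005) is the default `TrainingConfig`. The desk-scale demo
uses 20 epochs at lr 0.1 with a 4-block CNN — small-input NumPy training
needs the larger step — and standardizes inputs with a global mean/std
fitted on the training crops (stored in the checkpoint and applied at
inference and feature extraction).

Online Label Smoothing updates each training cell's target at epoch end as
`L ← αL + (1−α)P` with α = 0.03, where `P` is the model's predicted
distribution; the initial `L` is the (smoothed) ground truth.

Two backbones sit behind one interface. The **toy CNN** (conv3×3 → ReLU →
maxpool blocks, global average pooling, softmax head) trains end-to-end
with full NumPy backprop; its feature layer is the pooled penultimate
activation. **EfficientNet-B0** is implemented forward-only in NumPy
(MBConv blocks with squeeze-and-excitation, TF-style same padding,
batch-norm with identity statistics, deterministic He initialization from a
seed); when selected for training, a linear probe (softmax head) is fitted
on its frozen pooled features — full backprop through MBConv blocks is out
of proportion for a desk-scale CPU tool. All dimensionality contracts
(672-dim `block6a_expand_activation`; 5 × 672 = 3,360 pseudo-RGB
concatenation) are architecture properties and independent of the weights.
With non-3-channel input the stem is inflated by channel-mean replication,
rescaled by 3/n.

The gated-attention MIL head (bags of 16 cells; control bags all-control;
treated bags 4–12 treated members topped up with controls; equal bag counts
per class; 50 epochs) is implemented and tested but excluded from the
default pipeline, since the classification-loss route is the primary path.

## Feature extraction and profiling

Features are the spatially averaged activation of the declared layer
(max-pool available), one forward pass per cell for the native 5-channel
model; the pseudo-RGB route resizes each channel to 224×224 (bilinear),
min-max rescales to [−1, 1] — resize first, so the output attains exactly
±1 — replicates it to 3 channels and runs five passes per cell. Per-site
archives (`<plate>/<well>_<site>.npz` + index CSV) preserve the locations
order.

Aggregation is median (cell→site, robust to segmentation/feature outliers),
then mean (site→well), then mean (well→treatment); well rows with any NA
feature are dropped first; permutation-invariant by construction.

**Sphering.** Fitted on negative-control well profiles only. The control
mean is subtracted before `Σ = XᵀX/n` (the uncentered literal form is
available via `center=False`); eigenvalues are clipped at 0, and
`Q = U(Δ+λ)^(−1/2)Uᵀ` adds λ to the eigenvalues *before* the inverse square
root — regularization is not eigenvalue flooring. λ = 0 with a singular
control covariance (always when n ≤ d) is an error directing the user to
λ > 0. One global transform is fitted per dataset (controls pooled across
plates). Defaults: λ = 1e−3 for correction, λ = 1e−2 inside the
treatment-effect procedure. Corrected controls have covariance eigenvalues
`δᵢ/(δᵢ+λ)`, each in (0, 1), monotone in λ, and the λ→∞ limit is uniform
shrinkage λ^(−1/2)·I — all verified in tests.

**Treatment effect.** Per plate: median control profile, Euclidean
distances of every well to it, control-distance mean and (population) SD,
Z-scores for treated wells, and the treatment score is the mean Z over its
replicate wells. Plates with < 2 controls are skipped with a warning; zero
control SD is an error. Effect estimation uses a *non-trainable*
descriptor — the concatenated pooled features of three fixed-seed untrained
CNNs — rather than the trained model: features fitted to treatment labels
preferentially encode well signatures and bias the distance, while a fixed
random projection is neutral to the label structure (the same reason
screen-scale studies use classical engineered features here). Bands:
treatments sorted ascending by score (ties by id), k = round(0.2·N), weak =
first k, strong = last k, median = k centered at `⌊(N−k)/2⌋`.

## Evaluation

A query is any annotated treatment sharing ≥ 1 annotation with another
treatment; its library is all other annotated treatments ranked by cosine
similarity (stable tie-break by treatment id); a hit shares ≥ 1 annotation.

*Interpolated mAP*: precision/recall are computed down each ranked list;
the precision envelope `p_inter(r) = max_{r'≥r} p(r')` is evaluated on the
shared grid `{j/K_max}` where `K_max` is the maximum positive count over
queries — the densest grid the dataset supports, making per-query APs
averageable at identical recall points. This grid choice is the single
biggest metric-definition decision and is pinned by exhaustive brute-force
oracles in the tests.

*Folds of enrichment*: per query, the ranked list is cut at
k = max(1, ⌈0.01·L⌉) (per-query, so small libraries keep a nonempty top
set); the 2×2 table of positives/negatives above/below the cut gives the
cross-product odds ratio, Haldane-corrected (+0.5 to every cell when any
cell is zero), averaged over queries; one-sided Fisher p-values ride along
for audit. A ranking-independent "row-sum ratio" reading of the odds ratio
exists in the literature of this metric; it cannot measure ranking quality,
so the cross-product form is the default and the literal form is behind a
flag. Note the Haldane-corrected odds ratio is biased upward under the null
for small cut sizes k (Jensen); the permutation-null test therefore uses a
large balanced library (4,000 items, k = 40), where the exact null
expectation is 1.05.

The regularization scan re-fits sphering per λ, with the uncorrected
baseline as the leftmost point. Batch structure is quantified as the
silhouette score of well profiles under plate labels.

## Desk-scale problem sizes

The bundled demo and the heavier tests use: 3 plates × 20 wells × 2 sites,
96×96 px images, 10 treatments in 5 MoA classes, 32×32 crops, a
(16, 32, 64)-channel CNN, 20–25 epochs — chosen so the full workflow and
its phenomenology (split-scheme validation gap, mAP gain from sphering,
plate-silhouette collapse, effect-size recovery) reproduce in a few minutes
of CPU time. The parameter-recovery check runs at the generator defaults
(20 treatments, 48×48 crops).

## Known limitations

* The B0 path uses deterministic random initialization; pretrained ImageNet
  weights are not bundled, so pseudo-RGB features are structurally faithful
  (dimensions, block layout) but not transfer-learned.
* Sphering is fitted once globally; per-batch variants are out of scope.
* The generator's confounder spatial model (a linear ramp within images) is
  one admissible choice; real illumination patterns are more complex.
* Leave-cells-out stratifies exactly per well (rounded per-well counts);
  a global-fraction variant would differ negligibly at screen scale.
* Harmony-style nonlinear correction, gradient-reversal branches and
  CellProfiler feature computation are intentionally absent; external
  feature tables can be fed to the profiling layer directly.
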