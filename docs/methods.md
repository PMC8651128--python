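# Methods

## Problem and model

`stdgnn` forecasts the follow-up dynamic contrast-enhanced MRI (DCE-MRI)
of a hepatocellular carcinoma (HCC) treated with transarterial
chemoembolization (TACE), from the pre-treatment sequence and its tumor
annotation alone.  The forward model has five parts:

1. **Convolutional trunk.** Each 3-D phase volume, stacked with the
   baseline tumor mask as a second channel, is mapped to a feature map by
   a small configurable CNN (3 convolutions, 2 max-pools; an optional
   fixed input pool halves the grid first).  The original architecture
   is a ResNet-scale trunk on GPU hardware; all sizes here are
   configuration fields so the trunk can be shrunk to a single-CPU
   profile.
2. **Discriminant graphs.** Feature maps are partitioned into a grid of
   3-D patches and average-pooled; the N = T x P patch vectors form graph
   nodes.  Over labeled node sets, two binary adjacencies are built with
   a symmetric-OR k-nearest-neighbour rule on Euclidean feature
   distances: W_w links nearest *same-class* nodes, W_b nearest
   *other-class* nodes.  The "hypersphere neighbourhood" of the original
   description is operationalized as a k-NN count (defaults k_w = 5,
   k_b = 3); distance ties break toward the lower node index so
   construction is deterministic.  Adjacencies are normalized as
   D^(-1/2)(W + I)D^(-1/2) (self-loops keep isolated nodes well-defined
   and bound the spectral radius by 1); the Laplacian is L = Diag - W.
3. **Graph-convolution branches.** The temporal branch runs K = 3 layers
   of `X_k = W_b_hat X B_k - W_w_hat X B_k` (shared weights B_k between
   the two propagation terms, exactly as the update is written) over all
   N patches of a sequence, with batch-norm, leaky rectifier, and
   residual shortcuts from layer 2 on, then max-pools over nodes into
   f_t.  The structural branch runs M = 2 layers per volume over its P
   patches, halving the feature width per layer down to d_m, max-pools
   per volume and concatenates across volumes into f_s.  Within one
   sequence every patch shares the (possibly unknown) sequence class, so
   the per-sequence within-graph degenerates to a plain k-NN graph and
   the between-graph is empty — branch forward passes therefore need no
   label at test time.  Labeled cross-sequence graphs appear in the
   training losses (soft-weighted, below).
4. **Global / domain-translation branch.** The spatially pooled trunk
   features, concatenated with the lesion's own enhancement curve (mean
   normalized intensity inside the annotated tumor per sampled phase),
   pass through a two-layer perceptron into f_global.  The explicit ROI
   curve matters at desk scale: after 8x trunk downsampling a 10–15 mm
   lesion occupies roughly one grid cell, so the pooled maps alone carry
   little of the class-discriminative enhancement kinetics that the
   annotation makes directly accessible.
5. **Decoder and discriminator.** The fused vector [f_global, f_t, f_s]
   yields the 3-class viability softmax, and modulates (scale/shift per
   channel) the time-averaged trunk map entering the decoder: 4
   convolutional layers over 3 upsampling stages emit the predicted
   follow-up phase volumes and a 2-class voxel softmax tumor mask.
   During training both live on a half-resolution grid (half in each
   axis); inference restores the input grid by nearest upsampling, which
   commutes with the softmax.  A small convolutional critic scores
   (phases + mask) stacks of real vs generated follow-ups.

## Losses

The training objective is reported in the decomposition

    E_triplet_global = E_tumor + lambda_w * E_weight + lambda_a * E_adv
    E_overall = E_triplet_global + E_triplet_t + E_triplet_s + E_softmax

with the published operating point lambda_w = 0.2, lambda_a = 0.5,
phi = 30, xi = 0.35.

* **E_tumor** — voxelwise 2-class cross-entropy of the predicted
  follow-up mask against the registered follow-up annotation, summed over
  batch samples.  Voxels are re-weighted so foreground (about 2 % of the
  volume) and background contribute equally; without this the mask head
  receives almost no gradient.  Probabilities are clamped at 1e-12.
* **E_adv** — the adversarial objective
  `-E[log D(real)] - E[(phi*c + xi) log(1 - D(fake))]`, where the
  optimal-transport cost c is the mean pairwise sliced-Wasserstein
  distance between the class-conditional distributions of predicted
  class probabilities in the batch (bounded on the simplex; with
  phi = 0, xi = 1 the term reduces to the plain adversarial loss).  As
  written this is the *discriminator's* cross-entropy; the discriminator
  minimizes it, while the generator minimizes the non-saturating
  reversed form `-(phi*c + xi) E[log D(fake)]` carrying the same
  transport weight — the standard resolution of the minimax sign, which
  in practice is also what keeps the shared trunk stable.  The reported
  E_adv and the E_overall decomposition always use the printed form.
* **E_weight** — cosine similarity of the flattened between- and
  within-class adjacencies.  For strictly binary graphs the edge sets
  are disjoint by construction and the term is identically zero, so it
  acts on a soft variant: the k-NN edge structure is fixed from detached
  batch embeddings and edge weights are differentiable heat-kernel
  values exp(-d^2/sigma^2) with sigma^2 the median squared pairwise
  distance.
* **E_triplet_t / E_triplet_s** — batch-hard triplet losses (margin 0.3,
  squared Euclidean distances) on f_t and f_s: per anchor, the most
  distant same-class sample and the closest other-class sample.
* **E_softmax** — cross-entropy of the 3-class logits from the fused
  vector.

## Training procedure

Adam (lr 1e-3 in the desk profile, weight decay 5e-4); one discriminator
update per generator update, the critic at half the generator's learning
rate to keep the game from saturating early.  The generator's adversarial
gradient is enabled after a 15-epoch warm-up — mask and class supervision
first, the usual adversarial warm-up; the discriminator trains and E_adv
is reported from the first step.  Gradients are clipped to a global norm
of 50.  Batches of 6 are stratified so every class is
represented (the triplet and transport terms need at least two classes).
T = 4 of the 5 phases are drawn at random per sample, time order
preserved; augmentation warps a study (all phases and both masks
consistently) with a smooth random displacement field capped at 3 voxels,
with probability 0.3.  Every randomized component draws from a named
child seed of the run seed, so fixed-seed runs are bit-identical and a
checkpoint (weights, optimizer moments, batch-norm statistics, epoch
counter) resumes the exact loss trajectory.  Validation (20 % stratified
split) runs every 5 epochs; the best weights by validation Dice are kept.

The published schedule (lr 5e-5, 600 epochs, momentum 0.09) is retained
as the default `RunConfig`; the printed momentum together with "Adam" is
internally inconsistent, so Adam's beta1 defaults to 0.9 with the
printed value available behind `use_paper_momentum`.  The desk profile
(100 epochs, 48x48x16 phantoms, small trunk) rescales the learning rate
for the far smaller model and image grid.  The network computes in
single precision; the autodiff engine keeps float64 as its default dtype
so that algebraic-identity tests run in double precision.

## Phantom generator

The generator emulates the structure of a pre/post TACE study pair so
that every downstream stage has exact ground truth: a liver-like
background with smooth multiplicative texture (Gaussian-filtered noise,
4 % amplitude), a spherical tumor (default 12 mm radius, jittered per
sample) whose voxel time-courses follow the dual-input single-compartment
model, two small vessel regions carrying the arterial and portal input
functions (gamma-variate bolus; the portal curve delayed and dispersed),
and additive Gaussian noise (sigma 2 on a baseline of 100; a Rician flag
exists).  Acquisition times are the clinical 5-phase protocol (10, 60,
100, 145, 320 s).  Class kinetics are (Ka, Kp, K2) in 1/s:
viable (0.020, 0.003, 0.012) — arterial hyperenhancement with washout;
equivocal (0.005, 0.009, 0.007) — slow portal-dominant accumulation;
non-viable (0.0015, 0.003, 0.010) — devascularized.  These sit in the
1e-3–1e-2 1/s range typical of liver perfusion studies and differ in both
timing and amplitude, which makes the classes separable by construction
(a linear probe on mean tumor curves must exceed 90 % accuracy — a
generator contract, tested).  The follow-up applies a class effect in
the pre-treatment frame (registration is out of scope): non-viable
shrinks the radius x0.6 and suppresses enhancement x0.2; equivocal x0.85
and x0.6; viable grows x1.15 with preserved enhancement — so post-peak
enhancement orders NV < E < V.  Cohort jitter: center +-3 voxels
in-plane, radius +-2 mm, each transfer constant x U(0.85, 1.15).

What the phantom does *not* emulate: liver anatomy, respiratory motion
and registration error, field inhomogeneity, partial-volume effects at
real scanner resolution, multi-lesion interactions, or the biological
overlap between viability grades.  Passing the end-to-end criteria on
phantoms therefore demonstrates that the architecture and losses can
learn class-conditional pre-to-post mappings when they exist — not
clinical performance.

## Perfusion analysis

The kinetic model is dC/dt = Ka*AIF(t) + Kp*PIF(t) - K2*C(t), C(0) = 0
(the cited dual-input single-compartment form, with input delays fixed
to 0).  Simulation uses the exact exponential update for a
piecewise-linear forcing, so the solution on any sampling grid is exact
for linearly interpolated inputs; an explicit-Euler oracle at 1000x
finer step verifies it to 0.1 %.  Fitting is bounded nonlinear least
squares (trf) with a 3-point-per-decade geometric multi-start grid over
(Ka, Kp, K2) in [1e-3, 3e-2]; ties break by lower residual then lower
K2.  Derived quantities: DV = 100*(Ka+Kp)/K2 (%), ART = Ka/(Ka+Kp).
When AIF and PIF are numerically collinear (cosine > 0.999) Ka and Kp
are individually unidentifiable; the result is flagged and only their
sum is meaningful.  Non-parametric descriptors use S0 = first sample,
arrival T0 = first time above S0 + 3*sigma_baseline (sigma from the
first two samples), TTP = argmax time, dS = S_max - S0, PER = dS/S0,
nMITR = PER/TTP, wash-in = PER/(TTP - T0), and the wash-out slope
normalized by S0, ((S_max - S_end)/S0)/(t_end - TTP), zero and flagged
when the peak is the last sample.  Whether the original wash-out slope
is S0-normalized is not stated; the normalized form is used so that the
slope is invariant to intensity rescaling, like the other ratios.  Flat
curves return zeros with a flag rather than an error.

## Numerical and design choices

* Graph construction, frame sampling and nearest-neighbour ties are all
  deterministic under the run seed; sliced-Wasserstein projections are
  seeded (64 by default).
* The sliced 2-Wasserstein distance is sqrt(mean over projections of the
  squared exact 1-D W2 between sorted projections); unequal sample sizes
  compare interpolated empirical quantile functions.
* Convolutions are stride-1 "same" with odd kernels (gradients w.r.t.
  input are themselves convolutions with the flipped kernel); resolution
  changes use explicit pooling/upsampling.  The printed discriminator
  (5 layers of 4x4, stride 2) is realized at desk scale as 3x3 kernels
  with pooling, channel ladder configurable.
* Empty ROIs, masks without foreground, non-monotone acquisition times,
  geometry mismatches and unmineable triplet batches raise structured
  errors or warnings rather than propagating silently.
* The manifold-dimension regularizer of the original formulation has no
  computable definition; only its practical surrogate — the softmax
  cross-entropy on the fused features — is implemented.

## Problem sizes

The tested desk-scale profile uses 48x48x16 phantoms at (1.9, 1.9,
2.5) mm spacing, 30 study pairs per class for training, 100 epochs, and
a trunk of 8/12/12 channels — chosen so a full training run completes in
roughly a quarter hour on one CPU core.  Parameter-recovery checks use
50 curves sampled from the phantom prior on a 5-s grid to 320 s.

## Known limitations

* The adversarial image term shapes global appearance only weakly at
  this scale; generated intensity volumes are plausible but not
  voxel-faithful, and no intensity-reconstruction loss is used (the
  decomposition above is the complete objective).
* Voxelwise parametric perfusion maps are available only through
  ROI-level calls; no deconvolution methods.
* The discriminant graphs use Euclidean distances in feature space; no
  learned or attention-based adjacency.
* Patient data, DICOM ingestion, registration and anonymization are out
  of scope.
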