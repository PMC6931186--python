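# Methods

## The model

`multipath25d` segments stroke lesions in skull-stripped, atlas-aligned
T1-weighted brain MRI (optionally paired with FLAIR) with a *2.5D* design:
nine independent 2D convolutional paths whose outputs are merged by a small
3D convolutional post-processor.

**Views.** A volume on the canonical grid (full scale 192 × 224 × 192, 1 mm
MNI-conformed) is sliced along each anatomical plane (axial, coronal,
sagittal) and standardized in one of three ways: z-scoring each slice over
its foreground (`in_plane`), z-scoring each through-plane intensity profile
(`across_third`), or both in sequence (`both`).  The 3 × 3 product gives
nine distinct path inputs.  Foreground means "not exactly zero": after skull
stripping the background is exact zero and must neither dilute the moments
nor be moved off zero.  Profiles or slices with near-zero variance
(sd < 1e-8) map to zero rather than dividing by noise.

**Path network.** Each path is a dual-encoder U-Net operating on 2D slices.
The two encoders see the two modality views — T1 and FLAIR when available,
otherwise the T1 and its left–right mirror, which supplies a homologous
healthy-hemisphere reference.  Encoders have five convolutional blocks
(3 × 3, stride 1, padding 1; two ReLUs per block; constant channel width,
32 at full scale) with 2 × 2 average pooling after blocks 1–4, so the
pyramid spans scales 1 … 1/16 and in-plane dims must divide 16.  At each
scale the two 32-channel maps are stacked and merged by a 2 × 1 × 1 3D
fusion kernel.  The decoder applies four 2 × 2-stride-2 transposed
convolutions; the fused skip feature is *added* to the upsampled map before
the ReLU (multiplicative gating would shrink already-small values and kill
gradients), followed by a convolutional block.  A 1 × 1 projection yields
two channels — lesion and complement — paired by a per-pixel softmax.

**Fusion.** Per-path soft volumes are binarized at 0.5 (ties to lesion) and
each is stacked with the unnormalized input volume, giving an 18-channel 3D
tensor.  Three fusion strategies are implemented: voxelwise union, majority
vote (≥ 5 of 9), and the learned post-processor — 3 × 3 × 3 convolutions
with channel plan 18 → 36 → 9 → 9 → 2, padding 1 and interleaved ReLUs,
ending in a per-voxel softmax.  The hard mask applies the same ≥ 0.5 rule.

**Loss.** Two-channel soft Dice: with softmax channels (p, q) and binary
target r,

    D(p) = 2 Σ p_i r_i / (Σ p_i² + Σ r_i² + ε),    L = 2 − D(p; r) − D(q; 1−r),

with ε = 1e-7 guarding empty-target sums.  L ∈ [0, 2] and vanishes only at
the exact target.  The same loss trains paths and fuser; gradients are
derived analytically through the softmax pairing.

## Optimization

SGD with Nesterov momentum 0.9, weight decay 1e-4, batch of 32 slices,
initial learning rate 0.01 multiplied by 0.97 after each epoch, 50 epochs —
the full-scale recipe.  Paths are trained independently and then frozen;
the fuser is trained on their stacked outputs (random 3D patches, half of
them centered on lesion voxels).  All randomness flows from a single seed
through `numpy.random.SeedSequence`.

Two numerical choices matter and were made deliberately:

- **Initialization** is Kaiming-style uniform, U(±√(6/fan_in)).  The system
  has no normalization layers, so smaller-variance schemes let activations
  decay through the ten-convolution encoder stack and nothing trains.
- **Class-balanced slice sampling.**  Half of every path batch is drawn from
  lesion-bearing slices, half uniformly from all slices.  The soft-Dice /
  softmax pairing has an all-background fixed point: once p ≈ 0 everywhere
  the gradient scales with p and training stalls.  With purely uniform
  sampling several paths reproducibly fell into it; balanced batches keep
  the lesion term strong while empty slices still contribute through the
  complement channel.  Even so, an occasional path can stall on an
  unlucky initialization — the ensemble tolerates a weak member, which is
  the premise of the nine-path design.

## Synthetic phantoms

The generator emulates what the real pipeline consumes: an ellipsoidal
brain support holding a smooth low-frequency intensity field (base level
1.0 plus four broad Gaussian bumps, amplitude ≤ 0.25 — enough structure
that the three normalization schemes genuinely differ), exact-zero
background, a single ellipsoidal lesion per case confined to the left
hemisphere, additive Gaussian noise (sd 0.05), and two modalities with
opposite lesion contrast (−0.35 on the T1-like channel, +0.45 on the
FLAIR-like one, jittered ±20% per case).  Small lesions have all radii in
3–6 mm (bounding box strictly inside 20 × 20 × 25 mm); large ones are
elongated posterior–anteriorly (radius 10.5–13 mm) so at least one extent
crosses its threshold.  The default grid is 48 × 64 × 48 at 1 mm.

What the phantoms do *not* model: MRI physics (bias fields, partial
volume, acquisition noise structure), anatomy (tissue classes, ventricles),
multi-focal or cortically-shaped lesions, and registration error.  Passing
the phantom benchmark therefore demonstrates that the architecture, losses,
optimization and harnesses work as specified — not that the system reaches
any particular accuracy on clinical data.

## Evaluation machinery

- **Dice**: 2TP / (2TP + FP + FN) with voxel counts against the expert (or
  phantom) mask; empty-vs-empty is defined as 1.  On binary inputs the soft
  Dice reduces to this exactly.
- **Size stratification**: lesions whose whole-foreground bounding box (in
  mm) is strictly below 20 × 20 × 25 (x = left–right, y =
  posterior–anterior, z = inferior–superior) are *small*, otherwise
  *large*; boundary cases go to large.
- **Wilcoxon rank-sum** (Mann–Whitney U), two-sided: exact null enumeration
  for combined n ≤ 12 without ties, otherwise the normal approximation with
  tie and continuity corrections (delegated to scipy; an independent
  brute-force enumeration oracle cross-checks it in the tests).
- **Harnesses**: balanced k-fold cross-validation (fold sizes differ by at
  most one; deterministic per seed) and cross-study evaluation that trains
  on one cohort and tests on a disjoint one, refusing any id overlap.

## Desk-scale profile and problem sizes

The headline numbers are computed by `scripts/acceptance.py` on a reduced
profile chosen so a full experiment trains on one CPU in minutes: grid
48 × 64 × 48, path networks 8 filters wide, batches of 8 slices, 60
minibatches × 6 epochs per path, fuser trained on 16³ patches (40 steps × 8
epochs), 30 training and 10 held-out phantom cases.  The
full-scale defaults (32 filters, 192 × 224 × 192, batch 32, 50 epochs)
remain in the config types and CLI defaults.

## Known limitations

- The 2D convolution uses an im2col matmul and the 3D convolution a
  shift-and-accumulate loop — adequate for desk scale, far from GPU speed.
- Registration, resampling and skull stripping are upstream; the package
  validates aligned inputs but never performs them.
- The per-path output head and per-path training loss reuse the two-channel
  soft-Dice design of the final stage; paths are never fine-tuned jointly
  with the fuser.
- Majority vote on near-perfect phantom ensembles leaves the learned fuser
  no headroom, so their ordering on phantoms can be a statistical tie; the
  learned fuser's advantage shows against union and against systematically
  biased ensembles (covered by a dedicated test).
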