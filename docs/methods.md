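# Methods

This note records the model, the synthetic data, the numerical choices and
the limits of what the test suite demonstrates. It is the package's own
account of its science; all numbers quoted here are computed by the tests
or by `scripts/acceptance.py`, never transcribed from elsewhere.

## The segmentation model

The network is a 3D fully-convolutional encoder–decoder aimed at
structures that are small relative to the voxel grid: heart walls a few
voxels thick, vessels about a voxel in diameter. The difficulty with a
conventional U-Net encoder is receptive-field growth: after `i`
downsampling stages a 3×3×3 convolution covers `2^i × 3` input voxels per
axis, so deep layers integrate context over regions far larger than the
structures of interest and thin detail is lost before the decoder can
recover it.

The encoder therefore runs two branches of four layers each:

- **Downsampling branch** (`F_i^D`): 2×2×2 stride-2 convolution halves the
  resolution per layer while channels double — the semantic-context path.
- **Resampling branch** (`F_i^R`): 3×3×3 stride-1 convolutions keep a
  fixed (configurable) fraction of the input resolution at every layer, so
  the receptive field grows only additively. The analytic calculator in
  `snet3d.model.receptive_field` gives, for the default configuration,
  branch edges 7/13/25/45 voxels at layers 1–4 against 10/28/112/408 for
  the downsampling branch; the gradient-footprint probe
  (`probe_receptive_field`) reproduces these numbers exactly.

Each layer couples the branches with a **multiple cross-aggregation
module** (MCAM):

    F_{i+1}^R = F_i^R + Interp(F_i^D + PReLU(Conv(F_i^D)))
    F_{i+1}^D = F_i^D + Interp(F_i^R + PReLU(Conv(F_i^R)))

with `Conv` a stack of three 3×3×3 convolutions (each followed by a
PReLU) and `Interp` trilinear resampling to the other branch's grid. The
first two encoder layers use unit dilation; layers 3 and 4 use the dilated
schedule {2, 3, 4, 5} (padding equal to dilation), giving single-conv
receptive edges 5/7/9/11. The decoder mirrors the downsampling branch:
2×2×2 stride-2 transposed convolutions, concatenation with the
matching-resolution encoder feature (long skip), convolutions with an
additive short skip, and a 1×1×1-conv + sigmoid head per stage, brought to
input resolution by trilinear upsampling for deep supervision.

### Interpretation choices the architecture description leaves open

- *Dilated-block arrangement.* The four dilated convolutions could sit in
  sequence or in parallel; they are arranged sequentially (dilations 2,3
  in layer 3; 4,5 in layer 4), identically in both branches, which is the
  parameter-economical reading.
- *Printed receptive fields.* The description lists receptive fields
  3³/7³/9³/11³ for the four dilated convolutions, but `d·(k−1)+1` gives 5
  for dilation 2 and 7/9/11 for 3/4/5. The calculator follows the formula;
  the first printed value appears inconsistent with it and is documented
  rather than silently resolved.
- *Receptive field of a branch.* The per-branch receptive-field claim is a
  statement about each branch's own convolution chain. Once MCAM mixes the
  branches, a resampling-branch feature also sees input through the
  downsampling path, so the gradient probe isolates the branch
  (`cross_aggregate=False`) to make the analytic claim testable.
- *Decoder skips.* Encoder features exist at 1/2 … 1/16 resolution, so
  decoder stages at 1/8, 1/4, 1/2 concatenate `F_3^D, F_2^D, F_1^D`; the
  full-resolution stage has no same-resolution encoder feature and uses no
  long skip. Resampling-branch features reach the decoder only through
  MCAM mixing, because concatenation requires matched resolution.
- *Channel widths* are not printed in the source description; the default
  is 16 doubling to 128, config-exposed (`base_width`, `width_growth`).
  The decoder's full-resolution stage uses `base_width/2` channels.
- *Inference head.* The full-resolution head is the inference output;
  auxiliary heads are training-only. Binarization threshold 0.5
  (sigmoid midpoint), config-exposed.
- *Interpolation convention.* All trilinear resampling is corner-aligned,
  project-wide. Any consistent convention satisfies the MCAM equations;
  mixing conventions would break the identity-interpolation property that
  the tests check exactly.

## Loss

Per supervised head, soft confusion counts `TP = ΣG·P`, `FP = Σ(1−G)·P`,
`FN = ΣG·(1−P)` feed the asymmetric overlap index
`TI = TP/(TP + 0.3·FP + 0.7·FN)`; the training loss is `Σ_heads (1 − TI)`.
Two conventions are ours: the printed sum of indices is maximized by good
predictions, so the implementation minimizes `1 − TI` per head; and the
counts are soft (probabilities, not thresholded masks) to keep the loss
differentiable. A smoothing constant of 1e-6 stabilizes the quotient, and
an all-background patch predicted as all-background scores `TI = 1`
(empty-foreground convention). Heads are equally weighted, as the printed
sum carries no per-layer weights.

## Phantoms

Real cardiac CT and rotational angiography are replaced by seeded
phantoms, each a pure function of `(spec, shape, intensity model, seed)`:

- **Shells**: voxels whose normalized ellipsoidal radius ρ satisfies
  `|ρ − 1| ≤ t/(2·r̄)`, r̄ the geometric-mean semi-axis — an analytic,
  orientation-safe band whose measured thickness (twice the maximal
  inscribed radius from the distance transform) stays within one voxel of
  the nominal `t`.
- **Tube trees**: capsules (distance-to-segment ≤ radius) grown
  recursively with per-generation radius decay `r_g = r_0·γ^g`; branching
  stops below the 0.5-voxel resolvable limit. Centerline voxels are always
  rasterized so that sub-voxel radii cannot disconnect the tree (every
  mask is one 26-connected component). An optional sphere at a branch
  node models an aneurysm sac.
- **Intensities**: `bg + (fg−bg)·mask`, plus a smooth bias field (mean of
  three seeded low-frequency cosine products, amplitude 0.2, wavelength
  ≈ 32 voxels) and additive Gaussian noise (σ = 0.1 at unit
  foreground/background contrast). Defaults put the contrast-to-noise
  ratio at 10 — a clean, high-contrast regime.

What the phantoms do **not** emulate: CT physics (beam hardening, streaks,
motion), anatomical texture inside and around the structure, annotation
noise, multi-class context, and anisotropic voxels (the default spacing is
1 mm isotropic, stored in the NIfTI headers so surface metrics are in mm).
Passing the phantom benchmarks therefore shows that the architecture,
loss, training loop and metrics interoperate correctly and that the model
can learn thin structures from intensity + shape; it does not predict
scores on clinical data.

## Metrics

Dice, sensitivity, specificity and relative volume error are computed from
hard voxel counts. Surfaces are foreground voxels with a background
6-neighbour (array boundary counts as background); directed distances come
from exact Euclidean distance transforms with anisotropic spacing. HD95 is
the maximum of the two directed 95th percentiles (linear-interpolation
percentile); ASSD is the symmetric mean. Pooled-percentile HD95 variants
differ slightly; the max-of-directed convention is fixed here. Case tables
aggregate as mean ± Student-t 95% confidence half-width.

## Training profiles and problem sizes

The **published profile** preserves the regimen the architecture was
described with (48×512×512 patches, batch 2, Adam 1e-4, 1000 epochs,
dropout 0.3 after every encoding/decoding layer, full-resolution
resampling branch). It is a named config and is not exercised by the
tests — it assumes data-center GPUs.

The **desk profile** is the package's CPU-scale counterpart and the
default for the benchmarks: base width 8, 32³ patches, one random patch
per volume per epoch, batch 2, 60 epochs, Adam at 2e-3 with cosine decay
(a short schedule needs a larger, decaying step than the 1e-4 of the
1000-epoch regimen), resampling branch at 1/4 resolution (the
configuration's sanctioned response to memory/compute pressure,
`resample_scale`), dropout 0.3. Per-volume z-scoring precedes patching.
Inference tiles volumes with 50% overlap and uniform averaging.

Benchmarks (all seeded end to end):

- *Shell benchmark*: 20 shells of wall thickness 2 at 64³, 75/25
  case split, full model. The held-out mean Dice and HD95 are the
  acceptance quantities; with three training seeds the suite checks
  Dice ≥ 0.85 and HD95 ≤ 3 mm.
- *Tube ablation*: 10 tube trees at 64³ (root radius 2.5–4 voxels, decay
  0.6–0.75 over 3 generations, i.e. terminal radii ≈ 1 voxel), 30 epochs,
  full model vs the single-branch single-supervision backbone, three
  seeds; the check is directional (dual-branch ≥ backbone mean Dice), not
  a value match.

Determinism: phantom generation, initialization, patch sampling and
dropout all derive from one master seed via `SeedSequence` streams;
repeating generate → split → train → evaluate reproduces metric CSVs
bitwise. Checkpoints are self-describing (parameter archive + JSON config
sidecar) and resuming replays the identical stream.

## The tensor engine

No GPU deep-learning framework is used: `snet3d.nn` is a small
reverse-mode autodiff engine on numpy arrays, written for exactly the
operations this model needs. Feature tensors are channels-last; a
convolution is an im2col gather followed by one BLAS matrix product, the
input gradient of a stride-1 convolution is the full correlation of the
output gradient with the flipped kernel, and the non-overlapping stride-2
transitions scatter per kernel tap. Trilinear resampling is a cached
sparse operator (Kronecker product of 1-D corner-aligned matrices), so its
backward pass is its exact transpose. Everything is float32; sigmoid
outputs are clipped to [1e-6, 1−1e-6] so probabilities stay strictly
inside (0,1) under float32 saturation. Correctness is established in the
test suite against scipy correlation, finite differences and dense-matrix
transposes.

## Known limitations

- CPU-only and deliberately small; the published profile is declared, not
  demonstrated.
- Binary foreground/background only; no 2D mode; no augmentation beyond
  random cropping; no multi-GPU.
- The tube ablation at desk scale is under-converged for both variants
  (Dice ≈ 0.6 after 120 gradient steps, against ≈ 0.9 for the shell task
  at 480 steps). Only the Dice ordering is asserted, on the three fixed
  seeds of the test suite, and robustness analysis shows the effect is
  within seed noise at this scale: with other seed triples the ordering
  inverts (the dual-branch model has five times the parameters of the
  backbone and converges more slowly per step, and at a quarter-resolution
  resampling branch the voxel-scale tube branches carry little extra
  signal). The desk-scale ablation therefore demonstrates that the
  four-variant machinery runs end to end, not that the dual-branch
  advantage is detectable at 120 steps on three test cases;
  `scripts/acceptance.py` reports the signed Dice gain for whatever seed
  it is given, and the sign should be expected to vary. A converged
  comparison needs the published-scale regimen.
- Phantom realism limits noted above.
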