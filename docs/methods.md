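# Methods

This note records the modelling conventions, the choices made where the
design was genuinely open, and what the synthetic experiments do and do not
establish.

## Spectral conventions

The forward 2-D DFT is unnormalized and the inverse carries the full
1/(NM) factor (the "backward" convention); transforms act on the last two
axes, per channel, and never mix batch or channel axes. Phase is the
two-argument quadrant-aware angle in (−π, π] — the one-argument arctangent
of im/re would collapse quadrants II/III onto IV/I and break the polar
round trip. After an inverse transform the real part is kept; the discarded
imaginary residue is recorded, and a residue above 1e-4 of the output scale
raises a warning because a conjugate-symmetric spectrum should invert to a
numerically real signal — a larger residue signals upstream corruption.

## MSF3M

Both polar components pass through structurally identical but *unshared*
multi-scale branches: a 5×5 depthwise base convolution, three depthwise
strip pairs (1×7/7×1, 1×11/11×1, 1×21/21×1) applied to the base output in
parallel, aggregation by summation (base + three branches), then a
pointwise 1×1 fusion. All convolutions use "same" zero padding, so the
layer preserves shape for any spatial size. Design points worth noting:

- *Aggregation rule.* Summation followed by 1×1 fusion mirrors the
  multi-scale convolutional-attention design this family of layers derives
  from; with delta kernels and a 1/4-scaled fusion the whole branch is the
  identity, which gives the test suite an exact oracle (the layer then
  computes `x ⊙ x`).
- *Depthwise strips.* Keeps the parameter overhead of the layer small,
  consistent with the lightweight-network goal.
- *No phase re-wrapping.* Branch outputs on the phase path are consumed
  only through cos/sin, which are 2π-periodic, so wrapping back into
  (−π, π] would change nothing numerically while destroying
  differentiability at the wrap points.
- *Linear branches.* No activation is placed between the branch
  convolutions; the layer's nonlinearity comes from the polar
  decomposition and the final residual multiplication.

## MS-DFFM

The channel stage is a squeeze-and-excitation gate: global average pooling,
a 1×1 bottleneck (reduction 16, floored so the reduced width is at least 8
channels but never wider than the input), ReLU, a 1×1 expansion, and a
hard-sigmoid `clamp((t+3)/6, 0, 1)`. Because the gate lies in [0, 1] the
stage can never amplify a channel — a property the tests assert.

The spatial stage feeds the gated features through two paths: a pointwise
1×1 + GELU transform, and a multi-scale attention map (5×5 depthwise base,
four strip pairs 1×3/3×1 … 1×21/21×1, summed, then an exit 1×1). The map
*multiplies* the pointwise path elementwise and the product is added to the
original input. A second reading of this layer family's design sums the
two paths rather than multiplying them; both wirings are
implemented behind `AttentionConfig.combine = "multiply" | "add"` and both
satisfy the residual-identity property when the attention path is zeroed.
Whether the exit 1×1 precedes or follows the combination is likewise not
recoverable from the description; it is placed before the combination.

## Fourier up-sampling

Cyclic padding tiles magnitude and phase 2×2 along H and W (factor fixed at
2, the ratio the surrounding network needs). The optional post-padding
convolution is a depthwise 3×3 pair applied to magnitude and phase
separately. Because the inverse transform at the doubled size divides by
4NM, the conv-bypass path is *exactly* zero-interleaving — `y[2i,2j] =
x[i,j]`, zero elsewhere, energy preserved — which is both a correctness
oracle and the reason no extra gain factor is applied.

## Network assembly

Backbones follow the nano-scale YOLOv8 convention (width multiplier 0.25,
depth 0.33 by default, every width overridable): a stride-2 stem, four
downsampling stages using ADown, RepNCSPELAN4 aggregation in the two
shallow stages, C2f-SE in the two deep stages, SPPELAN after the last
stage. MS-DFFM is inserted after stages 1–2 (shallow, where spatial/channel
detail lives) and MSF3M after stage 4 (deep, where its global frequency
support pays off); insertion stages are config lists validated at build
time. Re-parameterized bottlenecks are built directly in their deploy-time
single-convolution form. The segmentation variant adds a neck that
Fourier-up-samples P5 and P4, fuses with skip connections, and decodes
instances from a single-scale prototype-mask head (objectness, class
scores and mask coefficients from a 1×1 head; objectness bias initialized
to −5 so an untrained model predicts nothing). The head is deliberately
simpler than a full anchor-free multi-scale YOLO head; it implements the
prediction contract (per-instance class, confidence, mask/polygon, empty
set below threshold) without distribution-focal box regression.

All layers run on the package's own reverse-mode autodiff core over numpy
arrays (float64 throughout). Every primitive's gradient is verified against
central finite differences in the test suite, and the composite layers are
additionally gradient-checked end to end.

Published training defaults are kept verbatim (SGD, momentum 0.937, weight
decay 5e-4, lr0 0.01 decaying linearly to lr0·lrf with lrf 0.01, batch 16,
patience 50, 300 epochs, no pretraining); `smoke_config()` scales the
*problem* down (64×64 inputs, width multiplier 0.125, 12 epochs) without
touching the optimizer recipe. Training is single-process, so a fixed seed
reproduces the loss history bit for bit. Classification training is
implemented; segmentation models build, run forward and decode predictions,
but a segmentation training loop (target assignment, mask loss) is out of
scope at this problem size.

## Quality sorting

Where the written procedure is ambiguous the following readings were
adopted (each alternative that is defensible is exposed in
`SortingConfig`):

- the 3×3 neighborhood mean *includes* the center pixel (uniform 1/9
  kernel); the 8-neighbor variant is a flag;
- borders use replicate padding, so the border of a uniform image is flat;
- the global reference is the mean absolute deviation from the global mean
  (GAD), and the flat comparison is `vALD ≤ 0.10·GAD` with ≤ ties, so a
  perfectly uniform image (GAD = 0) is entirely flat;
- the scatter rule is read as: reject when black pixels exceed the
  per-window threshold in more than a given fraction of sliding windows —
  i.e. non-flatness spread across the granule is as bad as a concentrated
  blotch;
- sliding-window defaults: 16×16 windows, stride 16 (disjoint), per-window
  black threshold 0.5, scatter fraction 0.25, global black threshold 0.25.
  These are package defaults, fixed once against the synthetic fixtures;
- decisions are monotone: turning any flat pixel non-flat can never flip a
  rejection into an acceptance;
- front/back view pairs fuse conservatively — both views must accept.

Grayscale conversion uses the standard luma weights 0.299/0.587/0.114.
Maturity in the standalone sorter comes from a red/green color heuristic;
the trained classifier replaces it in the full pipeline.

## Synthetic imagery

The generators emulate field imagery at desk scale: cluster scenes
of 4–8 overlapping disk granules with 16-gon polygon labels, and 64×64
single-granule crops on black background for classification and sorting
(200 per class, split 8:2). Mature granules are a single red hue with a
low-frequency sinusoidal surface modulation (amplitude 3 intensity units)
and per-pixel Gaussian jitter (σ = 1.5); semi-mature granules mix a red and
a green hue through thresholded low-pass noise with patch scale σ = 1 px.
The patch scale was chosen once so that the two classes sit far apart under
both color statistics (≥ 5 fixture noise standard deviations, which makes
the 95% smoke-training bar a property of the architecture rather than of a
marginal dataset) and the vALD statistics (mottled crops' non-flat fraction
is well above the 0.25 global threshold, uniform crops' well below).

What passing these tests shows: the layers compute exactly what their
definitions say, the sorter implements its rules faithfully, and the
assembled network can fit a cleanly separable color-classification task
end to end. What they do not show: performance on real photographs —
the fixtures have no specular highlights, occlusion by stems and leaves,
lighting gradients, camera noise correlation, or intra-class ripeness
continua, all of which matter in the field.

## Numerical choices and degenerate inputs

- float64 everywhere; no stochastic layers, so forward passes are
  deterministic for fixed weights.
- `hypot`/`atan2` autodiff primitives define a zero (sub)gradient at the
  origin, keeping zero feature maps finite through the polar split.
- Non-finite inputs are rejected at module boundaries with diagnostics
  naming the failing stage (fft / branch / reconstruction / ifft).
- Confidence ties in AP ranking break by prediction order (stable);
  AP uses all-points interpolation.
- FPS uses the mean per-image duration; being hardware-dependent it is
  never asserted against any reference value.
- Model size in MB is reported at 4 bytes/parameter. Byte-level parity
  with any external size table is explicitly not a goal; the ablation
  property that removing MSF3M/MS-DFFM strictly shrinks the model is
  asserted instead.

## Known limitations

- Segmentation training (loss + assignment) is not implemented; the
  segmentation path is exercised structurally (build, forward, decode,
  empty-prediction contract).
- The numpy autodiff core is single-threaded and eager; it is sized for
  64×64 smoke experiments, not for 640×640 production training.
- The sorter's window statistics assume granule crops of at least the
  window size (16 px); smaller crops need a smaller configured window.
- The color-heuristic maturity call is a stand-in; it is only as good as
  the red/green separation of the input imagery.
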