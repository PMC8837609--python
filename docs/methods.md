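# Methods

This note documents the models and procedures implemented in `ivdquant`,
the parameters that matter, and the numerical choices made where the
design was open.

## Scene model and coordinate conventions

All operations work on a mid-sagittal 2-D scene with 14 anatomical
classes: background (id 0), vertebral bodies L1–L5 (ids 1–5, superior to
inferior), discs L1/L2–L5/S1 (ids 6–10), sacrum (11), presacral fat (12),
and the CSF band in the spinal canal (13). Pixels are addressed 0-based as
(row, col) with rows increasing inferiorly; by default the anterior side
is the low-column side (configurable flip). Lengths are in pixels unless a
(row, col) spacing in mm/px is supplied, in which case distances and areas
are computed in physical units; DHI and HDR are dimensionless either way.

## Signal-intensity model (ΔSI)

A non-degenerate disc has a bimodal intensity histogram: a bright
water-rich nucleus pulposus mode and a dark annulus fibrosus mode. ΔSI
measures the surviving contrast, normalized by the CSF peak so that
scanner gain cancels:

ΔSI = (SI₂ − SI₁)/SI_CSF × 255.

Numerical choices (none of which is standard in the literature, so all
are config-exposed under the `histogram:` block):

- **Binning**: 64 bins over [0, image max]. Using the *image* max (not
  the region max) keeps all regions of one image on a shared axis and
  makes ΔSI exactly invariant under global linear rescaling. 64 bins are
  adequate for both 8- and 16-bit inputs.
- **Peak detection**: counts are smoothed with a centered 3-bin moving
  average; local maxima with prominence ≥ 2% of the region pixel count
  and separation ≥ 4 bins are candidates; the two highest candidates,
  ordered by location, are the peaks. Peak location is the bin center of
  the smoothed maximum — no sub-bin interpolation. For plateaus created
  by smoothing a spike, the plateau middle is used (taking the first bin
  would bias the location half a bin low).
- **Degenerate discs**: a single admissible peak yields ΔSI = 0 rather
  than an error (interpreted as complete nucleus/annulus blurring) and is
  flagged `unimodal_histogram`. Severely collapsed discs genuinely lose
  their second mode, so this is a measurement outcome, not a failure.
- **Quantization budget**: SI₁, SI₂ and SI_CSF are each quantized to half
  a bin, so a single-disc ΔSI can deviate from the continuum value by up
  to ~1.5 bins in the worst phase alignment; on the noisy phantom batches
  used in the tests the agreement is within one bin for ≈95–100% of
  discs. Disc histograms are computed on raw intensities — the CSF
  normalization is what makes this admissible.

## Geometry

**Vertebral corners.** The Shi–Tomasi (minimum-eigenvalue) response is
computed on the binary class region (σ = 1). Candidate corners are local
response maxima above `quality` × (the response of an ideal right-angle
binary corner at the same σ); the ideal-corner reference makes the
threshold meaningful across region sizes. Default quality 0.4: rasterized
right angles respond at ≥ 1× the ideal while a smooth disk boundary
responds at ≈ 0.3×, so corner-free regions are rejected. Roles
(superior/inferior × anterior/posterior) are assigned by quadrant around
the region centroid, ties broken by distance to the bounding-box vertex.
Because the response peak of a rasterized corner sits up to ~2 px inside
the vertex, each retained corner is snapped to the outermost region pixel
(farthest along the outward direction) within a 2-px window; this is an
integer-pixel refinement, not subpixel interpolation, and it leaves
axis-aligned corners unchanged. Vertebrae with fewer than four admissible
corners are flagged and skipped, mirroring the clinical exclusion of
images whose corner detection fails.

**VD, VH.** VD is the distance between the midpoints of the anterior and
posterior corner pairs; VH = (pixel area)/VD, so VH·VD equals the area by
construction.

**Disc landmarks.** The four primary feature points are the disc-boundary
pixels nearest the upper vertebra's inferior corners and the lower
vertebra's superior corners (the construction needs only quantities the
pipeline already computes). Their anterior/posterior midpoints D_a, D_p
define the disc axis and diameter ‖D_a D_p‖; the boundary points with
extreme signed projection onto that axis give the anterior-most and
posterior-most points and the maximum diameter. Extreme-projection is
O(n) and agrees with the all-pairs farthest distance to within a pixel on
convex discs (an all-pairs oracle backs this in the tests). For L5/S1 the
"lower vertebra" is the sacrum, whose superior corners are detected the
same way; since the sacrum has no area-based height, the DHI denominator
uses 2·VH(L5), flagged `l5s1_dhi_uses_l5`. Discs whose vertical gap to
either endplate exceeds 3 px (+1 px rasterization allowance) raise an
adjacency error.

**DH, DHI, HDR.** DH = (number of disc pixels whose axis projection lies
in the central μ fraction of the diameter)/(μ·diameter), μ = 0.8 by
default. DHI = 2·DH/(VH_up + VH_low), HDR = DH/max-diameter.

Pixel-center geometry gives a measured diameter of w − 1 for a disc
rendered w pixels wide, so DH and HDR carry an O(1/w) positive bias
relative to continuum truth — about 1.3% and 2.7% respectively at the
default 76-px disc width. This is a property of any discrete landmark
scheme, is well inside the 5% recovery tolerance the tests enforce, and
vanishes as resolution grows.

## Grading and deviation scores

Criteria tables give per-grade (μ_g, σ_g) of ΔSI for the modified
Pfirrmann scale with the signal-poor grades collapsed (1, 2, 3, 4, 5–8);
μ must be strictly decreasing. The assignment rule is the minimum
σ-normalized distance argmin_g |ΔSI − μ_g|/σ_g with ties broken toward
the severer grade. This is equivalent to scanning the pairwise deviation

Δ_i = |ΔSI − μ_{i+1}|/σ_{i+1} − |ΔSI − μ_i|/σ_i

for its sign change, and with equal σ the decision boundaries are exactly
the midpoints of adjacent μ — both facts are asserted by tests. The
reported Δ for a disc is evaluated at i = min(grade, G−1), the boundary
that determined the assignment.

Baseline tables are keyed by (gender ∈ {0, 1}, segment, age band; bands
20–30 … 70–90). Normalized parameters (ΔSI, DHI, HDR) are reported as
signed deviations β = (x − μ)/σ — more negative means more degenerate —
while DH, the only non-normalized parameter, is reported as a collapse
percentage (1 − DH/healthy mean)×100, floored at 0 with an
`above_baseline` flag. The shipped tables are generated from the phantom
presets (10% relative SD) and are labelled synthetic; they exist so the
reporting path is executable and testable, not as clinical references.

## Segmentation network

The architecture is an encoder-decoder in the deeplabv3+ family with
three additions, faithfully reproduced at two scales:

- **Backbone**: 16× downsampling — strided stem, three residual stages,
  and a final stage at stride 1 with dilation-2 atrous *separable*
  convolutions (depthwise dilated + pointwise).
- **DFE** (depth feature extraction): pyramid pooling over multiple bin
  sizes whose concatenation exactly doubles the bottom channel count
  (2048 → 4096 on the full preset), followed by ASPP (1×1, three dilated
  3×3 branches, and a global-pool branch) projecting to a dense semantic
  map (256 channels on the full preset).
- **ST-SC** (Swin-transformer skip connection) on the 1/4 and 1/8
  resolution skip paths: two successive Swin blocks — window attention,
  then shifted-window attention, each LN → attention → residual, LN →
  2-layer GELU MLP → residual — run beside a 1×1 convolution of the same
  feature map; the two outputs are spliced channel-wise and the total is
  reduced to 1/8 of the tapped channels so the skip cannot swamp the
  decoder.
- **Decoder / MFF**: every upsampling step is a ×2 transpose convolution
  (no bilinear interpolation); after each of the first two steps the
  matching ST-SC features are concatenated and refined by a 3×3 double
  convolution, then two further ×2 transpose convolutions restore input
  resolution with one channel per class and a final SoftMax.

The loss is the channel-weighted soft dice on the SoftMax output with
weights ξ = 0.9 (vertebral bodies), 0.8 (discs), 1 (background, sacrum,
fat, CSF); p₀ is read as the per-channel SoftMax complement 1 − p₁. A
perfect one-hot prediction gives loss 0; a completely disjoint one gives
mean(ξ) = 12.5/14.

Everything runs on an in-repo reverse-mode autodiff engine over NumPy
(float64), with convolutions implemented as kernel-offset slice loops so
forward and backward are exactly adjoint; gradients are verified against
finite differences in the tests. Batch/layer norm use batch statistics
(no running averages — models here are trained and evaluated on the same
scenes). Weights are He-initialized from a seeded generator, so
construction is reproducible; no pretrained weights ship with the
package.

Presets: `tiny` (basic residual blocks, 32 base channels, window-2
shifted attention, ~3.5M parameters) mirrors the full topology path for
path and is what the test suite trains; `full` is a resnet101-style
bottleneck backbone (~72M parameters) that is constructed and
shape-checked but not trained in the tests. Pyramid-pooling bins —
(1, 2, 4) tiny, (1, 2, 4, 8) full — and ASPP rates — (1, 2, 3) tiny,
(6, 12, 18) full — follow the usual conventions, with bin sizes chosen as
powers of two so they tile the 1/16-resolution map; pooled maps are
restored by nearest-neighbour resize. Swin window size, head count and
MLP ratio are config-exposed. The tiny window of 2 guarantees the window
partition divides every feature map whose input is a multiple of 16.

Training at clinical scale (and hence reproducing cohort segmentation
accuracies) is out of scope; the overfit test — 200 Adam steps (lr 1e-2)
on a single 64×64 phantom scene driving the weighted dice loss below
0.1 — exercises every architectural path end to end, which is its only
purpose.

## Metrics

mDice and mIoU average per-class 2|G∩P|/(|G|+|P|) and |G∩P|/|G∪P| over
all C classes. A class absent from both masks scores 1 (vacuous perfect
agreement) and is flagged — clinical scenes always contain all 14
classes, but phantoms and crops may not. macro-F1 averages per-class F1
over classes with nonzero support in the truth, matching grade tables
that leave absent grades blank. ICC(A,1) is computed from the two-way
mean squares (subjects × raters) with the standard absolute-agreement
estimator and its F-based 95% confidence interval (Satterthwaite df); it
is cross-checked against `pingouin` in the tests.

## Synthetic phantom

The phantom renders the 14-class scene with known geometry: five
rectangular vertebral bodies and five discs stacked flush (so the real
adjacency structure holds), a tilted sacrum, a fat ellipse, and a
vertical CSF band. Discs carry a two-component intensity model — a
centered nucleus region covering 50% of the disc area (each dimension
scaled by √0.5) at `np_intensity` inside an annulus at `af_intensity` —
giving the bimodal histogram the ΔSI method assumes, with comparable peak
areas. Gaussian noise (clipped at zero) is the only corruption; `tilt_deg`
rotates the whole scene rigidly about the image center, preserving
adjacency while exercising rotated-corner detection.

Default conditions emulate a 512×512 mid-sagittal acquisition at roughly
0.55 mm/px: 76×50 px vertebrae, 76×18 px discs, nucleus 180 / annulus 60 /
CSF 200 / vertebra 110 / fat 230 SI units (T2-like contrast ordering, ΔSI
= 153 when healthy), noise SD 0–5. The degeneration series interpolates
nucleus intensity down to the annulus level and disc height down to 40%
linearly, so analytic ΔSI strictly decreases and DH is non-increasing by
construction.

Ground truth is closed-form from the generative parameters (continuum
geometry), never measured from the rendered mask. What passing tests
therefore show is that the measurement chain recovers known geometry and
contrast through rasterization and noise; what they cannot show is
robustness to real anatomy — curved endplates, osteophytes, partial
voluming, intensity inhomogeneity, herniation — none of which the
phantom renders. Clinical validity must come from real segmented MRI.

## Known limitations

- ΔSI inherits up to ~1.5 bins of combined peak quantization per disc;
  finer binning trades this against noise sensitivity.
- Corner snapping assumes the vertex is the locally outermost region
  pixel; heavily eroded or concave vertebral corners would defeat it (such
  images are excluded clinically).
- The L5/S1 DHI convention (2·VH(L5)) makes that index incomparable with
  the other segments' DHI across methods that use a sacral height.
- The network's batch-statistic normalization means inference-time
  behaviour depends on the input batch; shipped checkpoints are intended
  for the same-scene/fine-tune workflows the package tests, not for
  population-scale inference.
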