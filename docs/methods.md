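# Methods

## The model

`stratseg` implements a stratified approach to delineating organs at risk
(OARs) on radiotherapy planning CT. The 42 head-and-neck OAR classes are
partitioned by difficulty into three strata:

* **anchor** (9): large, high-contrast, low inter-reader-variability
  structures (brainstem, cerebellum, eyes, mandible halves, spinal cord,
  temporomandibular joints);
* **mid-level** (19): soft-tissue structures of limited contrast (parotids,
  submandibular glands, constrictors, larynx, esophagus, ...);
* **small & hard** (14): very small or very low-contrast structures (lenses,
  cochleae, optic nerves and chiasm, pituitary, pineal gland, ...).

Processing follows the strata. With a planning CT `X`, the anchor branch
produces per-voxel class probabilities

    Ŷ^A_c(j) = p^A(Y^A(j) = c | X; W^A).

Anchor probabilities are concatenated onto the intensity channel to condition
the mid-level branch, `Ŷ^M_c(j) = p^M(· | X, Ŷ^A; W^M)`, and a detection
module for the small structures, `Ĥ = f(X, Ŷ^A; W^D)`, which regresses one
localization heatmap per class — a 3D Gaussian bump (σ in mm, physical
distances) centred on the organ. The argmax voxel of each regressed heatmap
seeds a volume-of-interest (VOI) crop of **three times the class's maximum
per-axis extent**; a zoom-in branch segments the cropped intensity alone,
`Ŷ^S_c(j) = p^S(· | V; W^S)`, and the result is pasted back into the full
grid. Each branch is a single multi-class softmax problem with background
as class 0; cross-branch outputs are kept as separate masks and may overlap
(no cross-branch fusion is defined).

Every branch backbone is a U-Net-style encoder–decoder whose convolution
blocks are chosen per block from a six-operator search space

    Φ = {2D₃, 2D₅, 3D₃, 3D₅, P3D₃, P3D₅},

where each operator is a composite convolution → instance normalization →
leaky ReLU; 2D kernels are in-plane (1, k, k), and pseudo-3D (P3D) chains an
in-plane composite with a through-plane (k, 1, 1) composite. Block `b` holds
six logits α; operator weights are the softmax γ_k = exp(α_k)/Σ_m exp(α_m)
and the relaxed block output is φ′ = Σ_k γ_k φ_k(x). Search alternates
first-order Adam steps on the network weights (on a weight partition of the
cases) and on the logits (on a disjoint architecture partition, default 2:1
at case level). The discrete genotype keeps the top-weight operator per
block; exact ties resolve to the lowest index in the fixed ordering
(2D₃, 2D₅, 3D₃, 3D₅, P3D₃, P3D₅), so an unsearched (uniform) state yields
the all-2D₃ genotype. The detection module is not searched; it uses a fixed
genotype.

## Evaluation

Contouring accuracy: Dice similarity coefficient (DSC), Hausdorff distance
(HD, true maximum; the 95th-percentile variant is reported alongside since
conventions differ), and average surface distance (ASD, mean of the two
directed averages). Surfaces are foreground voxels with a 6-connected
background neighbour (volume borders count as background); distances are
between surface-voxel centres in physical mm with anisotropic spacing. Both
empty → DSC 1 with a flag; distances on an empty mask raise rather than
return a sentinel.

Dosimetric impact of contour substitution, with dose grids resampled-to by
nearest neighbour in physical coordinates (dose voxels are commonly 2–4 mm):

* **direct**: the planned dose grid is fixed and only contours change,
  `(metric(sub, Dose_ref) − metric(ref, Dose_ref)) / metric(ref, Dose_ref) × 100%`;
* **clinical**: a dose grid replanned around the substitute contours is
  supplied and both terms are evaluated on it with the reference contours
  overlaid.

Both are computed for mean dose and maximum voxel dose, signed; summaries
report signed and absolute means and the fractions of structures exceeding
10% and 30%. Cumulative DVH curves (fraction of structure volume receiving
at least each dose level) are exported for plotting. Replanning itself is
out of scope — replanned grids are inputs.

## The numerical engine

No GPU framework is used: layers are implemented directly in NumPy with
explicit backward passes (verified against `scipy.ndimage.correlate` and
central finite differences to ~1e-7). Convolution is a flat-shift im2col:
shifted windows of the flattened zero-padded tensor are contiguous slices,
so the column matrix is assembled with memcpys and reduced with one BLAS
GEMM per z-chunk; workspaces are cached per layer so large buffers are
allocated once. Downsampling is 2× average pooling, upsampling is nearest
neighbour, skip connections are concatenated and compressed by a 1×1×1
convolution to keep decoder widths (and CPU time) small. Optimization is
Adam. Inputs are z-scored per volume before entering a network; inputs to a
backbone are zero-padded to the next admissible shape (multiples of
2^(levels−1)) and outputs cropped back.

Losses: cross-entropy plus soft Dice for segmentation, mean squared error
for heatmap regression — with one important modification each. OARs occupy
well under 1% of the field of view, and at desk-scale iteration budgets
(hundreds of steps, not nnU-Net's ~10⁵) unweighted voxel losses sit on the
background class and never move. Cross-entropy therefore uses
inverse-frequency class balancing (each label value present contributes
equally, weights capped at 200), and the heatmap MSE up-weights voxels under
a Gaussian bump to match the background mass (cap 500). Both are parameters
(`class_balance`, `balance`) and on by default. The Dice term averages over
foreground classes with reference voxels, so cases annotated with a subset
of a stratum's organs (institutional protocols annotate 13–42 OARs) still
give a well-defined objective; full class coverage is enforced by default
and can be relaxed for partial-label training.

Training iterates whole (padded) volumes by default: the stationary sample
stream lets instance-normalized features converge in ~100–200 Adam steps.
Foreground-biased random patch sampling is available for larger volumes but
shifts per-patch normalization statistics and needs longer schedules; the
zoom-in branch always trains on per-structure VOI crops (each labelled small
structure contributes one crop per case, with the class's extents measured
from the training labels when not already set in the registry).

## The phantom generator

The generator emulates the study conditions at desk scale: one case is a
64×96×96 voxel volume at 1.5 mm isotropic spacing carrying all 42 registry
structures as non-overlapping ellipsoids (rejection-sampled placement,
≤1000 attempts, strictly inside the volume), additive Gaussian image noise
(std 10), and stratum contrasts 300 / 100 / 30 intensity units over
background — bone-like, soft-tissue-like, faint. Within a stratum each
instance's contrast is deterministically spread ±40% around the stratum
level, the way distinct organs differ in HU; without this, instances are
visually identical, class identity becomes purely positional, and no
translation-equivariant network could learn it. Analytic dose grids are
isotropic Gaussians around a target centroid (prescription 70 Gy, σ 20 mm,
3 mm dose voxels by default). Inter-reader contour variation is emulated by
`perturb_mask`: half the displacement budget as an exact
distance-transform-based uniform dilation/erosion, half as a smooth random
displacement field normalized to the requested mean boundary displacement;
magnitude 0 is the identity and everything is a pure function of
(config, seed).

What the phantom does **not** emulate — and hence what passing tests do not
show about clinical data: anatomical shape and topology (ellipsoids only),
CT artifacts, and, most importantly, the stable spatial layout of human
anatomy. Structure positions are random per case, so cross-case
generalization of the detection module (which in practice exploits the
stable spatial relation between small organs and anchors) is not exercised;
detection tests demonstrate single-case memorization through anchor-guidance
cues. Segmentation metrics and dosimetry are exercised exactly as they would
be on real grids.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `PhantomConfig.shape`, `spacing` | (64, 96, 96), 1.5 mm | CPU-trainable in minutes |
| stratum contrasts | 300 / 100 / 30 | anchor > mid > S&H ordering |
| `contrast_spread` | 0.8 | peak-to-peak within-stratum contrast spread |
| `noise_std` | 10 | image noise, ~1/3 of the faintest contrast |
| backbone `levels`, `base_channels` | 2, 8 | desk-scale micro backbone (detection uses 3 levels: localization needs long-range context) |
| `TrainConfig.lr`, `iterations` | 0.05, 200 | overfits one default phantom by ~iteration 125 |
| `heatmap_sigma_mm` | 3 | Gaussian bump scale; sharper bumps localize better |
| VOI factor | 3× max extent | fixed crop rule |
| `SearchConfig.weight_fraction` | 2/3 | case-level weight/architecture split |

## Numerical choices and degenerate inputs

Softmax uses max-subtraction; operator-weight softmax rejects non-finite
logits. `extract_peak` breaks ties toward the lexicographically smallest
(z, y, x) index and warns on all-constant maps (returning (0, 0, 0)). VOI
windows are half-open `[start, start+size)`, clamped by shifting (size is
preserved unless an axis is shorter than the window). Dose-percentage
differences raise on a zero reference metric rather than returning inf.
A zoom-in class with no recorded extent yields an empty mask with a warning
at inference. Instance-norm epsilon is 1e-5; metric oracle agreement is
asserted at 1e-9 (exact geometry, float arithmetic only).

## Known limitations

* Micro backbones (2 levels, 8 channels) have small receptive fields; the
  framework's accuracy claims are mechanism-level (wiring, losses, search
  algebra, geometry), not clinical-performance claims.
* Architecture search here demonstrates the mechanics (relaxation, alternating
  descent, genotype derivation) at micro scale; searched genotypes on phantoms
  are not expected to transfer to clinical data.
* No test-time augmentation, sliding-window ensembling, or deep supervision;
  inference is a single forward pass per branch with hard argmax.
* DICOM RTSTRUCT and replanning are out of scope; NIfTI is the interchange
  format and replanned dose grids are consumed, never produced.
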