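# Methods

## Problem and model

`mamlseg` addresses binary segmentation of 3D medical volumes (one organ per
task) when only a handful of annotated volumes are available for a new task.
The approach wraps model-agnostic meta-learning (MAML) around a residual 3D
U-Net:

* A **task** T_i is one segmentation problem (e.g. liver, spleen), represented
  as a pool of (volume, mask) pairs. An **episode** samples a disjoint support
  set and query set from one task.
* The **inner loop** adapts the shared parameters θ to one task by plain
  gradient descent on the support-set Dice loss:
  θ_i′ = θ − α ∇_θ L_i(f_θ).
* The **outer loop** minimizes Σ_i L_i(f_{θ_i′}) evaluated on query sets,
  updating θ with Adam (learning rate β, L2-style weight decay). Differentiating
  through θ_i′ introduces a second-order term; see *Numerics* below.
* Three phases: **meta-training** over source tasks yields θ′; **meta-testing**
  fine-tunes θ′ on k shots of a held-out task by ordinary Adam training on the
  Dice loss (no meta-machinery), yielding θ″; **final testing** evaluates θ″ on
  unseen images of that task.

Reference hyperparameters (`presets.reference_meta_config`): α = 1e-4, β = 1e-6,
weight decay 1e-5, batch size 1, dropout 0.1, early-stopping patience 20
(meta-training) / 10 (fine-tuning). A documented ambiguity: the source
experimental table lists "β = 1e-6" alongside the Adam optimizer; we read β as
the outer Adam learning rate (the meta-update step of the algorithm), not an
Adam moment coefficient, where 1e-6 would be atypical.

## Backbone

The backbone is an encoder-decoder with residual units: each encoder level is
a residual unit whose first 3×3×3 convolution carries stride 2 (no pooling);
each decoder level is a stride-2 3×3×3 transpose convolution followed by a
single-subunit residual refinement, concatenating the skip tensor from the
matching encoder level. Activations are PReLU with one learned slope per
layer; normalization is instance normalization with affine scale/shift;
dropout (rate 0.1) sits after the first convolution of each residual unit.
Shortcuts are strided 3×3×3 convolutions where the unit down-samples, 1×1×1
projections where only the channel count changes, identity otherwise. The
final convolution maps to 2 channels (background/foreground logits) with no
normalization or activation.

The channel widths and level count of the reference network are not published.
We reconstructed them as 5 levels with channels (16, 32, 64, 128, 256),
strides (2, 2, 2, 2) and 2 residual subunits — the standard enhanced-U-Net
default — and validated the reconstruction by the published total parameter
count: the configuration above yields **exactly 4,808,917** learnable scalars
(convolution/transpose-convolution weights and biases, normalization affines,
PReLU slopes). This count is reproduced by `build_backbone` +
`count_parameters` and independently by a per-layer enumeration oracle in the
test-suite. The source text mentions both instance and batch normalization;
instance normalization is the default here (it is intrinsic to the enhanced
U-Net design and gives batch-size-independent, deterministic evaluation), with
a batch-statistics variant behind `norm="batch"`. Our batch variant pools
statistics over the batch at all times rather than tracking running averages;
at the reference batch size of 1 the two normalizations coincide.

## Implementation of the network and its gradients

No deep-learning framework is used: convolutions, transpose convolutions,
normalization, PReLU, dropout, reverse-mode gradients and Adam are implemented
directly on NumPy arrays (one BLAS matrix product per kernel offset). This
keeps the meta-learning core fully inspectable and dependency-light; the cost
is that full-scale (128³, 16-256 channels) training is impractical on CPU,
which is why the package ships desk-scale presets (below). Every layer's
backward pass is validated against central finite differences in float64.

## Metrics

* **DSC** = 2|P∩G|/(|P|+|G|), **IoU** = |P∩G|/|P∪G|; both 1 when prediction
  and truth are both empty, 0 when exactly one is empty.
* **HD95**: boundary voxels are foreground voxels with ≥1 background
  face-neighbour (array edges count as background outside). All directed
  nearest-boundary distances are computed both ways in physical mm (via voxel
  spacing), pooled, and the 95th percentile taken with linear interpolation.
  HD95 is undefined (NaN) when either mask is empty; such cases are excluded
  from HD95 means and counted. These conventions follow the common evaluation
  framework; the source does not define its "95% HD" precisely.
* **Dice loss** (training): 1 − (2Σpg + s)/(Σp + Σg + s) on softmax foreground
  probabilities, smoothing s = 1e-5 on numerator and denominator.
* Predictions binarize by per-voxel argmax over the two logit channels.

## Numerics of the meta-gradient

For one inner step, d/dθ L_q(θ′) = (I − α H_s(θ)) ∇L_q(θ′), where H_s is the
support-loss Hessian; for T steps the factors chain. The Hessian-vector
products are computed by central finite differences of the analytic support
gradient, in the parameter dtype (float64 in gradient tests), with step
ε = `hvp_eps`/‖v‖ (default 1e-4). On quadratic objectives this is exact to
rounding; on the U-Net it matches central differences of the full outer
objective to better than 1e-3 relative (test-suite). `first_order=True` drops
the Hessian factors entirely — the standard first-order MAML approximation —
and is the desk-scale default since it halves the cost and CPU budgets bind.
With dropout active, gradient calls draw fresh masks, so second-order
finite-difference HVPs become noisy; use dropout 0 (or evaluation-mode
gradients) when exact second-order behaviour matters.

## Preprocessing

CT-style intensity windowing clips to [−200, 200] (configurable) and rescales
linearly to [0, 1]. The source states the window but not the mapping; clip +
min-max rescale is the framework-standard treatment and is recorded here as a
package decision. Resizing uses trilinear interpolation for images and
nearest-neighbour for masks (binarity preserved), rescaling spacing so the
physical extent is unchanged. Arrays keep the NIfTI header's axis order; RAS
reorientation is opt-in.

## Synthetic phantoms

Four phantom families stand in for the four-organ task roster: large
ellipsoids, small ellipsoids, lobed blobs (ellipsoid + 2-3 lobes) and
capsules, all with per-sample size, elongation, position (and for capsules,
orientation) jitter — the "inter-subject variability" axis. Intensities are
Hounsfield-like: background −60 ± 15 HU, foreground +60 ± 15 HU (per-sample
draws), voxel-level Gaussian texture of sd 40 HU; after the standard window
this puts background near 0.35 and foreground near 0.65 on the unit scale with
within-class noise sd ≈ 0.1 — a soft-tissue-like contrast chosen once for
learnability, not as a claim about any real dataset. A family constructor
rejects configurations whose fg/bg mean contrast is below twice the pooled
intensity sd, so every family is learnable by construction. Masks are
guaranteed nonempty and strictly inside a 1-voxel boundary ring. Rendering is
bitwise reproducible per (family, shape, seed).

What the phantoms do **not** model: anatomy (organ shape priors, neighbouring
structures, partial-volume edges), scanner physics (beam hardening, streaks,
anisotropic resolution), inter-scanner contrast shifts, and pathology.
Passing the desk-scale benchmark therefore shows the *machinery* (episodic
meta-training, adaptation, metrics) works and that meta-initialization helps
on a family-structured task distribution; it does not certify clinical
segmentation accuracy.

The noise-robustness probe follows the reference protocol: Gaussian noise,
mean 0.0, sd 0.2, added to already-windowed (unit-scale) test volumes and
re-clipped to [0, 1], training data left clean. Note that sd 0.2 on the unit
scale is a *strong* perturbation (≈ 80 HU); if the reference applied the same
numbers to intensities left on the [−200, 200] scale, the perturbation would
be 400× weaker, which would explain a near-zero reported effect. We record
the unit-scale reading as the package's convention.

## Desk-scale protocol

The reference experiments (128³ volumes, 4.8M parameters, GPU, hundreds of
epochs) are not reproducible on one CPU, so the package defines a scaled-down
protocol (`presets.desk_*`) used by the test-suite and
`scripts/acceptance.py`:

* volumes 32×32×32 (divisible by the stride product), spacing 1.5 mm;
* backbone channels (8, 16, 32), strides (2, 2), 2 residual subunits,
  dropout 0.1 — same topology, ~71k parameters;
* episodes of 10 support + 10 query per task, 10 evaluation and 10 test
  images — the reference task-roster layout;
* first-order meta-gradient, inner step α = 1e-2, outer Adam β = 1e-3,
  2 outer steps per epoch, meta-training early stop at patience 5 (cap 60
  epochs), fine-tuning 5 shots with Adam 1e-3, patience 5, cap 20 epochs
  (≈100 updates — deliberately few-step adaptation, which is the regime the
  method targets; with a much larger budget the phantom tasks become
  learnable from scratch and the initialization comparison dissolves).

Per epoch, meta-training monitors the mean *adapted* evaluation DSC: for each
task, adapt θ on a freshly sampled support set and score DSC on the task's
held-aside evaluation images. Early stopping returns the best (unadapted)
checkpoint. Fine-tuning monitors the epoch-mean training-shot loss and
likewise returns its best checkpoint; the number of epochs past the best one
never exceeds the patience.

The benchmark (`experiments.run_fewshot_benchmark`) meta-trains once, then
runs 5 paired fine-tuning seeds: each seed fine-tunes the meta-initialization
and a fresh random initialization on the *same* 5 shots with the same
schedule, and evaluates both on the same 10 unseen test volumes. The headline
quantity is the paired mean-DSC advantage of the meta-initialization. A
noise probe re-evaluates one fine-tuned model on the corrupted test set.

## Degenerate inputs and conventions

* Empty support sets, empty task pools, undersized pools, non-binary masks,
  mismatched shapes/spacings, and indivisible spatial extents raise
  immediately with the offending name/axis in the message.
* Both-empty mask pairs score DSC = IoU = 1; HD95 NaN cases are excluded from
  means and counted, never replaced by a sentinel.
* All randomness (rendering, initialization, episode sampling, dropout, noise)
  flows from explicit seeds; fixed-seed reruns are bitwise identical on one
  machine.

## Limitations

* CPU-scale only: the full-width backbone is provided and validated for
  parameter count and gradients, but training it at 128³ is out of reach
  without a GPU framework.
* Binary (2-class) heads only; one structure per task.
* The inner loop is plain gradient descent with a single default step;
  the reference's exact inner-step count is unstated.
* Second-order meta-gradients use finite-difference Hessian-vector products;
  they are accurate to ~1e-3 relative, not machine precision, and interact
  poorly with active dropout (see above).
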