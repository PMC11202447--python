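# mamlseg — few-shot 3D medical image segmentation with MAML

`mamlseg` is a library + CLI for segmenting a single anatomical structure in
3D volumes (CT-style NIfTI images) when only a handful of annotated examples
of a *new* structure are available. It implements model-agnostic
meta-learning (MAML) wrapped around an enhanced residual 3D U-Net, and ships
a seeded synthetic phantom generator so the complete pipeline runs and is
tested at desk scale with no data download.

**Who it is for:** researchers in medical image analysis who want an
inspectable, dependency-light reference implementation of episodic
meta-learning for segmentation — the task sampler, the inner/outer MAML
loops (including exact second-order meta-gradients), the backbone, and the
standard evaluation metrics (DSC, IoU, 95% Hausdorff distance in mm).

## The method

Each segmentation problem ("organ") is a task T_i with a pool of
(volume, mask) pairs. An episode draws a disjoint support and query set from
one task. MAML learns an initialization θ that adapts to any task in a few
gradient steps:

* inner loop (per task):  θ_i′ = θ − α ∇_θ L_{T_i}(f_θ)  on the support set,
* outer loop:  min_θ Σ_i L_{T_i}(f_{θ_i′})  on the query sets (Adam, rate β),

with L the soft Dice loss on softmax foreground probabilities. Three phases:
**meta-training** over source tasks → θ′; **meta-testing** fine-tunes θ′ on
k ∈ {5, 10} shots of a held-out task → θ″; **final testing** evaluates θ″ on
unseen images of that task. The backbone is a 3D U-Net whose encoder levels
are residual units with stride-2 convolutions and whose decoder uses stride-2
transpose convolutions with skip concatenation — PReLU activations (one
learned slope per layer), affine instance normalization, dropout 0.1. At the
reference width (channels 16→256) it has exactly **4,808,917** parameters,
which validates the reconstructed architecture against the published count.

The network and all of its gradients are implemented directly on NumPy
(BLAS-backed convolution kernels, hand-derived backward passes, Adam);
second-order meta-gradients use finite-difference Hessian-vector products and
match central differences of the outer objective to 1e-3 relative. See
`docs/methods.md` for conventions, numerics and the desk-scale protocol.

## Worked example

`examples/04_fewshot_pipeline.py` runs a miniature three-phase pipeline
(16³ phantoms, 3 shots, ~20 s):

```text
phase 1: meta-training on ellipsoid-large, ellipsoid-small, lobed
  18 epochs; adapted eval DSC 0.059 -> 0.232
phase 2+3: 3-shot fine-tune on held-out task 'capsule'
  meta-initialized:    test DSC 0.568, IoU 0.409, HD95 2.49 mm
  randomly initialized: test DSC 0.066, IoU 0.035, HD95 11.42 mm
the meta-learned initialization should adapt better from 3 shots
```

Reading the numbers: during meta-training the mean *adapted* evaluation DSC
(adapt on a fresh support set, score on held-aside images) rises as θ learns
an adaptable initialization. After identical 3-shot fine-tuning on the
held-out capsule family, the meta-initialized model reaches DSC 0.57 on
unseen test volumes while the randomly initialized one barely finds the
structure (0.07) — the few-shot benefit the method exists for. At the full
desk-scale benchmark (32³ volumes, 10/10 episodes, 5-shot, 5 paired seeds;
see below) the margin is 82.7 vs 79.4 DSC% (seed 0) and 83.2 vs 64.9 (seed 1).

The other examples are single-capability scripts: `01_generate_phantoms.py`
(synthetic task generation + NIfTI export), `02_backbone.py` (architecture
and the 4,808,917 parameter count), `03_metrics.py` (DSC/IoU/HD95 on known
geometry).

## Command-line interface

```bash
mamlseg simulate   --config cfg.yaml              # phantom dataset -> NIfTI tree + manifest
mamlseg meta-train --config cfg.yaml --seed 1     # -> theta_prime.npz + history.csv
mamlseg meta-test  --config cfg.yaml --checkpoint runs/theta_prime.npz --shots 5
mamlseg meta-test  ... --noise-sd 0.2             # corrupt test volumes only
mamlseg evaluate   pred_dir/ gt_dir/ --out metrics/   # standalone DSC/IoU/HD95
```

The YAML config mirrors the reference hyperparameter table (`alpha`, `beta`,
`weight_decay`, `dropout`, `batch_size`, patience); every command writes its
resolved config next to its outputs and is bit-reproducible per seed. The
same config schema points at NIfTI directories (`task_dirs`) for real data.

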