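# stratseg

Stratified organ-at-risk (OAR) segmentation for radiotherapy planning CT,
with contouring and dosimetric evaluation, exercisable end to end on
synthetic 3D phantoms at desk scale.

Radiotherapy planning for head-and-neck cancer requires delineating 40+
normal structures ("organs at risk") on the planning CT so their radiation
dose can be limited. These structures differ enormously in difficulty: bone
and brain boundaries are high-contrast; soft-tissue glands are faint; the
optic chiasm or a cochlea may span a handful of voxels. `stratseg`
implements a stratified pipeline for this problem:

* a canonical **42-OAR registry** partitioned into anchor (9), mid-level
  (19), and small-&-hard (14) strata, with laterality and a clinical-alias
  synonym table;
* three **anchor-guided branches**: anchor structures are segmented first
  from intensity, `Ŷ^A = p^A(·|X; W^A)`; their class probabilities become
  extra input channels for the mid-level branch,
  `Ŷ^M = p^M(·|X, Ŷ^A; W^M)`, and for a small-structure **detection
  module**, `Ĥ = f(X, Ŷ^A; W^D)`, that regresses one Gaussian heatmap per
  class; each heatmap peak seeds a volume-of-interest crop of 3× the class's
  maximum extent, segmented by a zoom-in branch `Ŷ^S = p^S(·|V; W^S)` and
  pasted back;
* **differentiable architecture search** over six convolution operators per
  backbone block — 2D, 3D, and pseudo-3D kernels of size 3 or 5, each as
  convolution → instance norm → leaky ReLU — via softmax-relaxed mixing
  weights γ_k = exp(α_k)/Σ_m exp(α_m) and top-weight genotype selection;
* **evaluation**: Dice, Hausdorff (max and 95th percentile) and average
  surface distance in physical mm; cumulative DVH curves; and direct /
  clinical dose-difference statistics for contour substitution,
  e.g. `Diff_mean = (mean(sub, Dose) − mean(ref, Dose)) / mean(ref, Dose) × 100%`;
* a **phantom generator** producing volumes with all 42 structures,
  analytic dose grids, and seeded contour perturbations emulating
  inter-reader variation — so every stage runs with no data download.

The neural networks are implemented directly in NumPy (BLAS-backed
convolutions with hand-written gradients), so the whole pipeline trains on
one CPU in minutes at phantom scale. See `docs/methods.md` for the model,
the numerics, and what phantom results do and do not demonstrate.

## Worked example

```python
import numpy as np
from stratseg import (
    PhantomConfig, StructureSpec, generate_phantom, generate_dose_grid,
    DoseFieldConfig, build_registry, TrainingSet, Genotype, TrainConfig,
    train_branch, dsc, perturb_mask, StructureSet, diff_direct,
)
from stratseg.pipeline import predict_anchor

registry = build_registry()
config = PhantomConfig(
    shape=(32, 48, 48),
    anchor=StructureSpec(9, (5.0, 8.0), 300.0),
    mid=StructureSpec(19, (3.0, 4.5), 100.0),
    small_hard=StructureSpec(14, (2.0, 3.0), 30.0),
    seed=5,
)
volume, structures = generate_phantom(config)
print(f"phantom: {volume.data.shape} voxels, {len(structures)} structures")

# overfit the anchor branch on this one case
genotype = Genotype.uniform("3D", 3, levels=2, base_channels=8)
model = train_branch(
    TrainingSet([(volume, structures)]), "anchor_seg", genotype, registry,
    TrainConfig(iterations=300), seed=0,
)
pred = predict_anchor(volume, model).argmax_masks()
largest = max(anchors := registry.names("anchor"),
              key=lambda n: structures[n].volume_voxels())
print(f"final training loss: {model.loss_log[-1]:.3f}")
print(f"training DSC for {largest}: {dsc(pred[largest], structures[largest]):.3f}")

# simulate an independent reader and measure the dosimetric impact
dose = generate_dose_grid(structures["brainstem"], DoseFieldConfig())
reader = StructureSet(
    {n: perturb_mask(structures[n], 2.0, seed=i) for i, n in enumerate(anchors)},
    structures.grid,
)
report = diff_direct(
    StructureSet({n: structures[n] for n in anchors}, structures.grid),
    reader, dose, substitute_name="simulated reader",
)
s = report.summary()
print(f"mean DSC vs simulated reader: "
      f"{np.mean([dsc(reader[n], structures[n]) for n in anchors]):.3f}")
print(f"mean |dose diff| (mean dose): {s['abs_mean_of_diff_mean_pct']:.2f}%")
print(f"structures with |diff| > 10%: {s['frac_mean_diff_gt_10pct']:.0%}")
```

Output (deterministic for these seeds):

```
phantom: (32, 48, 48) voxels, 42 structures
final training loss: 0.067
training DSC for eye_left: 0.986
mean DSC vs simulated reader: 0.931
mean |dose diff| (mean dose): 2.84%
structures with |diff| > 10%: 11%
```

Reading it: the anchor branch memorizes the case (training Dice 0.986 on the
largest anchor structure); a 2 mm contour perturbation — a typical
inter-reader disagreement scale — costs ~7 Dice points and shifts mean doses
by ~3% on average, with 1 of 9 structures exceeding a 10% mean-dose change.

## Command line

```bash
stratseg synth  --out data --cases 3 --seed 7          # phantom dataset + dose grids
stratseg search --data data --role anchor_seg --out genotype.json
stratseg train  --data data --role anchor_seg --genotype genotype.json --out models/anchor_seg.npz
stratseg infer  --volume data/case_000/volume.nii.gz --models models \
                --registry data/registry.json --out pred
stratseg evaluate  --pred pred/structures.json \
                   --ref data/case_000/structures/structures.json --out metrics.csv
stratseg dose-eval --ref ref.json --sub sub.json --dose dose.nii.gz --out dose.csv
```

All commands are seeded and write a provenance JSON (resolved parameters,
digest) next to their outputs; volumes, masks and dose grids are NIfTI.

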