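# fuseseg

Anatomy-guided intermediate-fusion PET-CT tumor segmentation, CPU-friendly
and fully reproducible.

## The problem

Head-and-neck tumor delineation uses two co-registered modalities with
complementary failure modes: **PET** shows where metabolically active tumor
tissue is (hot voxels) but blurs its boundary and lights up non-tumor tissue
(inflammation, physiological uptake); **CT** shows crisp anatomical boundaries
in Hounsfield Units but cannot tell a tumor from other soft-tissue structures
of similar density. Stacking the modalities as input channels (*early fusion*)
entangles the two signals; combining two separate models at the decision level
(*late fusion*) is expensive and ignores shared structure. This package
implements an *intermediate* fusion architecture in which each modality is
encoded separately and CT features steer the fusion — plus everything needed
to exercise it end to end on synthetic phantoms: data I/O, preprocessing,
metrics, training, cross-validation, and an ablation harness.

## The model

For input volumes M_PET and M_CT (each normalized beforehand — CT clipped to
[−1024, 1024] HU and mapped to [−1, 1], PET z-scored per volume):

* **Zero layers** (one per modality):
  `P = ReLU(Conv_k^F(M))`, then a *learnable* normalization
  `N(P) = γ · (P − μ(P)) / sqrt(σ²(P) + ε) + δ`
  with per-channel scale γ, shift δ, and a learnable stabilizer ε > 0
  (positivity enforced through a softplus reparameterization). Unlike fixed
  normalization, γ, δ, ε train with the network and absorb residual
  scanner-to-scanner intensity variation.
* **Squeeze-and-excite encoders**, one stack per modality, stage filters
  F = [128, 64, 32, 16]: each stage computes `Enc = ReLU(Conv₃(x))`, a channel
  attention `Exc = σ(FC₂(ReLU(FC₁(GAP(Enc)))))`, modulates `Enc ⊗ Exc`, then
  max-pools (stride 2) and normalizes.
* **Anatomy-guided fusion decoder**: at every stage the excited features are
  pooled (average then max, kernel 2, stride 1, shape-preserving), reduced by
  1×1 convolutions, summed and activated:
  `f_fused = ReLU(PET^pf ⊕ CT^pf)`;
  guidance multiplies element-wise with the excited CT features,
  `CT_guidance = CT_excited * f_fused`;
  and the stage head emits `Dec_out = N(σ(Conv₁ₓ₁(CT_guidance)))`. An
  upsampling path combines the stage outputs into a full-resolution sigmoid
  probability map.

Evaluation uses the Dice similarity coefficient
`DSC(x, y) = 2|x∩y| / (|x|+|y|)` and the 95th-percentile Hausdorff boundary
distance (HD95, millimetres, pooled directed distances), with precision and
recall as supporting metrics; cross-validation supports leave-one-center-out
and seeded random 80/20 splits, aggregated as fold average, median, and
maximum deviation from the median.

The network runs on a small numpy reverse-mode autodiff engine written for
this package (`fuseseg.autograd`) — every primitive is verified against
central-difference gradients in the test suite — so no deep-learning
framework is required.

## Worked example

```python
from fuseseg import PhantomSpec, generate_dataset, FusionSegmenter
from fuseseg.metrics import evaluate_case

# a synthetic 3-center PET-CT dataset with ground-truth masks
dataset = generate_dataset(PhantomSpec(shape=(64, 64), spacing=(1.0, 1.0)),
                           n_per_center=20, centers=["C0", "C1", "C2"], seed=1)
train, test = dataset[:48], dataset[48:]

model = FusionSegmenter(variant="CT_GUIDED", encoder_filters=(32, 16, 8, 8),
                        max_epochs=6, seed=0).fit(train)
pred = model.predict(test)[0]
report = evaluate_case(test[0].mask.data, pred, spacing=test[0].pet.spacing)
print(f"DSC={report.dsc:.3f}  HD95={report.hd95:.2f} mm")
```

This prints `DSC=0.945  HD95=1.00 mm` — the phantom tumor is recovered
almost exactly (DSC near 1, about one voxel of boundary error), the expected
regime for the full CT-guided model on these phantoms; the interesting
numbers are the *differences* between architecture variants, produced by the
ablation harness:

```python
from fuseseg.training import default_ablation_study
print(default_ablation_study()[["variant", "dsc_mean"]])
```

which prints mean held-out DSC per variant over three seeds, e.g. CT-only
≈ 0.40 (tumors are anatomically ambiguous in CT), early fusion in between,
and the attentive-fusion variants ≈ 0.97–0.98 with CT guidance above PET
guidance — mirroring, in direction, the method's motivating comparisons.

The same pipeline is available from the shell:

```bash
fuseseg phantom --out ds --centers 3 --per-center 20 --seed 1
fuseseg train --data ds --out run --variant full --epochs 6
fuseseg predict --model run --data ds --out preds
fuseseg evaluate --data ds --out eval --strategy center
fuseseg ablate --data ds --out abl --variants ct,pet,early,full,pet_guided
fuseseg overlay --pred preds/pred_C0_000.nii.gz --gt ds/mask_C0_000.nii.gz \
                --background ds/ct_C0_000.nii.gz --out overlay.png
```

## Layout

| module | contents |
| --- | --- |
| `fuseseg.volume_io` | NIfTI/PNG volume I/O, co-registration validation |
| `fuseseg.preprocessing` | CT clip/scale, PET z-score, flips/rotations, split protocols |
| `fuseseg.phantom` | seeded synthetic multi-center PET-CT phantom generator |
| `fuseseg.autograd` | numpy reverse-mode autodiff (conv, pooling, norm, …) |
| `fuseseg.network` | zero layers, SE encoders, fusion decoder, baseline UNet, parameter accounting |
| `fuseseg.metrics` | DSC, HD95, precision/recall, fold aggregation |
| `fuseseg.training` | Adam + plateau schedule, losses, cross-validation, ablation harness |
| `fuseseg.estimator` | scikit-learn style `FusionSegmenter` |
| `fuseseg.cli` | `fuseseg` command-line interface |

See `docs/methods.md` for modelling assumptions, parameter choices, and known
limitations.
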