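# amygseg

Automatic segmentation of the amygdala and its subnuclei — four
subnuclear groups per hemisphere (lateral, basal, centromedial,
cortico-superficial) — from 3D T1-weighted MRI, using a dual-branch
dilated residual 3D fully convolutional network with a top-down
attention-guided refinement unit.

The amygdala's subnuclei jointly occupy about 0.05% of the brain
volume, so this is small-structure segmentation under extreme class
imbalance. The model addresses the trade-off between context and
imbalance with two parallel convolution branches fused per layer by
element-wise summation,

    F_l = F_dilated + F_standard ,

a *standard* branch of nine 3×3×3 convolutions at dilation 1 whose
stacked receptive field (19³) just encloses an amygdala, and a
*dilated* branch with schedule D = {1, 2, 4, 2, 8, 2, 4, 2, 1} whose
receptive field, 1 + (k−1)·ΣD = 53³, captures surrounding context
without extra weights. Residual blocks carry low-level detail forward,
and on each skip a top-down attention unit computes per-channel
coefficients from the high-level features,

    α = σ(ReLU(BN(Conv₁ₓ₁ₓ₁(AvgPool(F_high))))),   α ∈ [0.5, 1],
    F'_high = F_high + d(α ⊗ F_low),

so semantically rich deep features select which fine spatial details to
reuse. Training minimizes voxel-wise categorical cross-entropy with
Adam under polynomial learning-rate decay lr = lr₀·(1 − t/T)^0.9,
with foreground-biased patch sampling against the imbalance.

The package is written for researchers who want to study or extend the
method: it includes the architecture (with local/global attention
variants and a squeeze-and-excitation baseline), the training and
cross-validation protocol, tiled whole-volume inference, Dice/ASSD
evaluation, NIfTI I/O and a CLI — plus a synthetic phantom generator
reproducing the task's statistical structure (tiny mirrored
multi-compartment targets, noise, bias field, 0.05% imbalance) so that
every stage runs and is tested without clinical data. The network runs
on a compact numpy autodiff engine; no GPU is required. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import amygseg as ag

# receptive-field analytics of the two branches
print("standard branch RF:", ag.receptive_field([1]*9))
print("dilated branch RF: ", ag.receptive_field([1, 2, 4, 2, 8, 2, 4, 2, 1]))
print("3^3 kernel at dilation 2 acts as:", ag.effective_kernel_size(3, 2))

# the full default 9-class model
net = ag.build_network(ag.NetworkConfig(), seed=0)
print("trainable parameters:", ag.count_parameters(net))

# the phantom generator reproduces the real cohort's class imbalance
vol, lab, brain = ag.generate_phantom(ag.PhantomSpec(), seed=1, return_mask=True)
print("phantom foreground fraction: %.4f%%" % (100*(lab.data>0).sum()/brain.sum()))
```

prints

```
standard branch RF: 19
dilated branch RF:  53
3^3 kernel at dilation 2 acts as: 5
trainable parameters: 769079
phantom foreground fraction: 0.0494%
```

— the two branches see 19³ and 53³ voxels of context respectively, a
dilation-2 kernel covers 5 voxels per axis, the default model has
~0.77M weights, and the default phantom reproduces the ~0.05%
foreground fraction of the real task.

A full phantom study from the shell:

```bash
amygseg generate --preset small --n 14 --seed 1 --out cohort/
amygseg train --manifest cohort/manifest.csv --seed 1 --out model.npz \
              --train-config train.txt --metrics-out epochs.csv
amygseg segment --in cohort/subject000_t1.nii.gz --model model.npz \
                --out pred.nii.gz --patch 48 --margin 6
amygseg evaluate --pred pred.nii.gz --truth cohort/subject000_labels.nii.gz \
                 --classes compartments5 --out report.csv
amygseg rf-calc
```

`evaluate` writes per-class Dice (%) and ASSD (mm) as `mean (sd)`
columns; `rf-calc` prints the two branch receptive fields for any
config. All commands are deterministic under `--seed`.

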