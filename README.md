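# renalmpr

Automated post-processing for **multiparametric renal MRI**: one
workflow that segments the kidneys, aligns every contrast to a common
reference, transfers annotations to contrasts that cannot be segmented
directly, and extracts the quantitative measurements nephrology studies
actually use.

## The problem

A multiparametric renal protocol acquires six contrasts — Dixon
water–fat images, T1 and T2 maps, T2\*/BOLD, renal blood flow (RBF,
mL/100 g/min) from arterial spin labeling, and ADC (10⁻⁶ mm²/s) from
diffusion imaging — each with its own resolution, field of view and
breath-hold position.  Quantifying cortex and medulla separately
requires masks on every map, but manual delineation takes hours per
scan, and on RBF/ADC the cortico-medullary contrast is too poor to
delineate at all.  `renalmpr` automates the chain:

1. **Segmentation** — a 2-D U-Net (depth 5, 16→256 channels, residual
   skips) initialized by *constrained contrastive pre-training*: pixel
   embeddings of T2/T2\* are supervised by a constraint map built from
   pixel-wise PCA (P=20) + k-means (K=4), via a patch-level
   supervised-contrastive loss (100 patches of 4×4, τ=0.1, N=64
   channels).  Fine-tuning uses a class-weighted Tversky loss
   (α=0.3, β=0.7) for 3-class (kidneys) and 5-class (cortex/medulla)
   schemes.
2. **Registration** — every contrast is mapped onto Dixon by a frozen
   affine stage (encoder + dense(16) → dense(6) head) cascaded into a
   non-rigid U-Net predicting a dense displacement field, trained with

   L = L_NMI + λ₁·L_DSC + λ₂·L_smooth + λ₃·L_consistency,  λ = (1, 0.1, 100)

   where L_NMI is negative normalized mutual information
   2·MI/(H₁+H₂), L_DSC a soft-Dice guidance on the kidney masks,
   L_smooth the L1 norm of the field gradient, and L_consistency the
   MSE between each image and its forward-then-inverse warp, the
   inverse computed by fixed-point iteration v ← −u(x+v(x)).
3. **Propagation & quantification** — Dixon masks are warped by the
   inverse composite field into the RBF/ADC frames; volumes (mL) and
   per-region parameter means are reported with provenance, plus the
   full evaluation suite (DSC, Hausdorff mm, NMI, PCA deformation
   index, Jacobian folding %, ICC/Bland–Altman agreement).

Because clinical studies cannot ship with the code, the package
includes a first-class synthetic phantom generator: kidney-shaped
objects with cortex/medulla/pelvis compartments, per-contrast intensity
profiles and noise, and *known* inter-contrast motion — so every stage
is testable against exact ground truth.  Everything runs on plain CPU
scientific Python; the networks train on a small bundled autodiff
engine (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from renalmpr import PhantomSpec, AffineRange, generate_phantom_study, UNetConfig
from renalmpr.registration import train_registration, register_study, warp
from renalmpr.metrics import dice_score

spec = PhantomSpec.tiny(seed=5, contrasts=("DIXON", "T1", "RBF"),
                        misalign_affine_range=AffineRange(4.0, 5.0, (0.97, 1.03)),
                        deform_amplitude_px=5.0)
study = generate_phantom_study(spec)

cfg = UNetConfig(depth=3, base_channels=4, max_channels=64,
                 in_channels=2, out_channels=2)
aff = train_registration("affine", None, [study], epochs=1,
                         iters_per_epoch=250, lr=5e-3, batch=4, seed=0, cfg=cfg)
nr = train_registration("nonrigid", None, [study], epochs=1,
                        iters_per_epoch=350, lr=3e-3, batch=4, seed=0,
                        cfg=cfg, affine_params=aff)
reg = register_study(aff, nr, study)

dixon = study.masks["DIXON"].labels > 0
for contrast in ("T1", "RBF"):
    moving = study.masks[contrast].labels
    warped = np.stack([warp(moving[s], reg.fields[contrast][s]["composite"],
                            "nearest") for s in range(moving.shape[0])])
    print(contrast, round(dice_score(moving > 0, dixon), 3),
          "->", round(dice_score(warped > 0, dixon), 3))
```

prints (seeded, deterministic on CPU):

```
T1 0.798 -> 0.955
RBF 0.847 -> 0.957
```

i.e. the kidney overlap between each misaligned contrast and the Dixon
reference rises from ~0.8 (unregistered) to ~0.96 after affine +
non-rigid registration, with zero folding
(`metrics.jacobian_nonpositive_pct` = 0 on every slice).

A command-line interface mirrors the library:
`renalmpr phantom|pretrain|train-seg|train-reg|segment|register|pipeline|evaluate`
(all I/O as NIfTI + CSV/JSON; `renalmpr --help` for details).

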