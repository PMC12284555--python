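# paomni

Context-conditioned, retraining-free artifact removal for sparse-sampled
photoacoustic tomography (PAT).

Photoacoustic scanners trade cost against image quality through the
number of transducer elements: sparse arrays are cheap and fast but
delay-and-sum (DAS) reconstructions from 16–128 elements are corrupted
by radial streak artifacts.  Deep networks remove these artifacts well,
but a conventional U-net must be retrained for every new system
configuration (element count, array geometry, subject type).
**PA OmniNet** instead adapts in a single forward pass: alongside the
target image it receives a *context set* of K = 4–32 labeled
input/output example pairs from the target configuration, and
Pairwise-Conv-Avg blocks transfer what the examples demonstrate onto the
target.  Because each block updates the target with the **mean** over
per-pair candidates

    target' = (1/K) Σₖ Conv₁ₓ₁([target*, inₖ*, outₖ*]),

the network is exactly invariant to context order and size, so the same
trained weights serve any context the user can supply.

The package is a complete desk-scale laboratory for this method, aimed
at researchers studying generalization in tomographic artifact removal:

* `paomni.geometry` / `paomni.phantom` / `paomni.acoustics` /
  `paomni.dataset` — a 2-D PAT simulator (ring, semicircle,
  multi-segment and linear arrays; arc-integral forward projection;
  DAS backprojection with realistic streak artifacts) writing paired
  HDF5 datasets with subject-wise train/val/test splits;
* `paomni.omninet` / `paomni.unet` — PA OmniNet and a conventional
  U-net baseline, built on a small numpy reverse-mode autodiff engine
  (`paomni.autodiff`);
* `paomni.losses` / `paomni.metrics` — MSE, SSIM (reference
  parameters), the Alpha loss `(1−α)·MSE + α·(1−SSIM)` with α = 0.84,
  PSNR/RMSE, Sobel edge maps and the edge-sensitivity statistic;
* `paomni.train` — a shared training harness (Adam, sliding-window
  training contexts, static first-16 inference context, validation-loss
  early stopping) whose `Trainer.fit()` returns a `TrainResult` with
  history, diagnostics and `summary()`;
* `paomni.report` — improvement tables, positive-fraction summaries and
  paired t-tests, plus the published PA OmniNet vs U-net improvement
  rows as a packaged fixture;
* `paomni.experiments` — canned studies: simulator quality curves and
  the context-identifiability experiment.

## Worked example

Simulate a 16-element-ring dataset, train a small PA OmniNet for a few
epochs, and score the held-out subjects under the static 16-pair
context:

```python
import numpy as np
from paomni import (TaskSpec, build_dataset, ModelConfig, OmniNet,
                    TrainConfig, Trainer, OmniNetAdapter,
                    static_context, infer, evaluate_pairs)

task = TaskSpec(geometry="ring", n_sparse=16, n_dense=128, grid_size=(32, 32))
bundle = build_dataset(n_items=100, n_groups=6, task=task,
                       split_fractions=(0.5, 0.2, 0.3), seed=0)

model = OmniNet(ModelConfig(base_channels=8, channel_multipliers=(1, 2, 2, 2), seed=0))
cfg = TrainConfig(loss="mse", learning_rate=1e-3, max_epochs=10,
                  early_stop_patience=10, batch_size=4, seed=0)
result = Trainer(OmniNetAdapter(model), bundle, cfg).fit()
print(result.summary())

ctx = static_context(bundle.train, 16)           # first training subject
preds = infer(result.adapter, [p.sparse_input for p in bundle.test], ctx)
rep = evaluate_pairs(preds, [p.ground_truth for p in bundle.test],
                     dataset="ring-16", model="omninet")
inp = evaluate_pairs([p.sparse_input for p in bundle.test],
                     [p.ground_truth for p in bundle.test],
                     dataset="ring-16", model="input")
print(f"input  SSIM {inp.mean_ssim:.4f}  RMSE {inp.mean_rmse:.4f}  PSNR {inp.mean_psnr:.2f} dB")
print(f"output SSIM {rep.mean_ssim:.4f}  RMSE {rep.mean_rmse:.4f}  PSNR {rep.mean_psnr:.2f} dB")
```

which prints (about half a minute on one CPU core):

```
Training results
========================================
model             OmniNet
parameters        56,081
loss              mse
optimizer         Adam(lr=0.001)
epochs run        10 (max 10)
best epoch        10 (val loss 0.001251)
early stopped     False
final train loss  0.001303
wall time         28.9 s
input  SSIM 0.7203  RMSE 0.0683  PSNR 23.51 dB
output SSIM 0.8182  RMSE 0.0448  PSNR 26.97 dB
```

Ten epochs of a 56k-parameter network lift the SSIM of the streaked
16-element input from 0.72 to 0.82 and gain 3.5 dB of PSNR; the network
output is conditioned on 16 example pairs from the *first training
subject* only, mirroring the static-context inference protocol.  The same harness
trains the U-net baseline (`UNetAdapter(BaselineUNet(...))`) with no
other change.

The same pipeline is scriptable from the shell:

```bash
paomni simulate --geometry ring --n-sparse 16 --n-dense 128 --grid-size 32 \
    --n-items 100 --n-groups 6 --split 0.5 0.2 0.3 --seed 0 --out data.h5
paomni train --data data.h5 --model omninet --base-channels 8 --out run/
paomni evaluate --ckpt run/checkpoint.npz --data data.h5 --context-size 16 \
    --out metrics.json
paomni describe --model omninet      # layer shapes + parameter count
```

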