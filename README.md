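# octa-se-unet

OCT angiography (OCTA) reconstruction toolkit: the sliding-window
L1-norm speckle-decorrelation baseline, a squeeze-and-excitation (SE)
U-Net that predicts high-SNR decorrelation maps from a small number of
co-located OCT B-scans, a dynamic-speckle phantom with per-pixel ground
truth, and the matching PSNR/SSIM/MIP evaluation stack.

## The problem

Speckle-based OCTA images blood flow by contrasting temporal speckle
change: over static tissue the interference pattern is stable, over
moving blood it decorrelates. The conventional estimator averages the
absolute intensity difference over the N−1 adjacent pairs of N
co-located B-scans,

    D(z,x) = (1/(N−1)) · Σ_t |I_t(z,x) − I_{t+1}(z,x)|,

box-averaged over a 6 × 6 (x × z) window. Its SNR grows with N, but
large N means long acquisitions and motion artifacts. The alternative
implemented here trains an encoder-decoder network to map the first
N = 2–3 B-scans directly to the 10-frame decorrelation map (the
highest-SNR label a block affords), using spatial context instead of
more frames. The SE variant adds channel attention — each co-located
B-scan is an input channel, and a global-pool → bottleneck-MLP →
sigmoid gate rescales each channel — which stabilises training and
improves accuracy.

Everything runs on synthetic dynamic speckle with known ground truth:
per-pixel complex Gaussian fields with AR(1) temporal correlation ρ
(ρ ≈ 1 static dermis, ρ low in vessel disks), exponential depth
attenuation and a noise floor. The neural-network stack (convolutions,
instance/batch norm, SE blocks, Adam, plateau scheduler) is pure
NumPy with hand-written, gradient-checked backpropagation, so the whole
package runs on one CPU with no framework dependency.

## Worked example

```python
from octa import (
    DecorrParams, PatchSpec, ModelConfig, TrainConfig,
    build_learning_set, generate_phantom, make_label, predict_volume,
    train_model, windowed_decorrelation, psnr, crop_roi,
)
from octa.experiments import heated_phantom_spec
from octa.metrics import detect_surface

phantoms = [generate_phantom(heated_phantom_spec(seed=s, n_y=10)) for s in range(10)]
roles = ["train"] * 8 + ["val", "test"]
test = phantoms[-1]
surface = detect_surface(test.volume.blocks[0].frames[0])

pairs = build_learning_set(
    [(p.volume, r) for p, r in zip(phantoms, roles)],
    PatchSpec(patch_h=32, patch_w=64, overlap_x=0, z_offset=surface),
    n_channels=2, decorr_params=DecorrParams(n_frames=10),
)
model, log = train_model(
    pairs,
    ModelConfig(n_channels_in=2, depth=2, base_features=16,
                se_enabled=True, se_reduction=4, pad_inputs=True),
    TrainConfig(epochs=16, lr=2e-3, seed=0),
)

labels = [make_label(b) for b in test.volume.blocks]
preds = predict_volume(model, test.volume, tile=(32, 64), z_start=surface)
sd2 = [windowed_decorrelation(b, DecorrParams(n_frames=2)) for b in test.volume.blocks]

import numpy as np
for tag, maps in [("unet_se_2", preds), ("sd_2", sd2)]:
    vals = [psnr(crop_roi(l, surface, 28), crop_roi(m, surface, 28))
            for l, m in zip(labels, maps)]
    print(f"{tag}: mean PSNR {np.mean(vals):.2f} dB")
```

prints (seeds fixed, exact values reproduce):

```
unet_se_2: mean PSNR 22.64 dB
sd_2: mean PSNR 21.95 dB
```

i.e. even this two-minute example trains the network fed 2 B-scans past
the 2-frame sliding-window baseline against the 10-frame label; the
full-size reference experiment (`octa.experiments.crossover_experiment`,
more data and a wider model) pushes it to the 4-frame baseline's level.

## Command line

```sh
octa phantom  --config phantom.yaml --output vol.h5 --truth truth.h5
octa decorr   --input vol.h5 --n 3 --window 6x6 --output maps.h5
octa dataset  --volume vol.h5 train --volume vol2.h5 val --n-channels 3 --output pairs.h5
octa train    --pairs pairs.h5 --n-channels 3 --se --out model.npz
octa predict  --checkpoint model.npz --input vol.h5 --output preds.h5
octa evaluate --label-volume labels.h5 --pred-volume sd_2 maps.h5 --out report.csv
octa run      --config pipeline.yaml --output-dir out/   # all stages, one config
```

`octa run` is deterministic given the config's seed and writes a
provenance manifest (config hash, seeds, version) beside its outputs.

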