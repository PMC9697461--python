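# mandifrac

Combined mandibular-fracture detection on panoramic radiographs: a
fracture-line U-Net, a tooth-region U-Net whose inverted and dilated output
suppresses false fracture lines between teeth, and fusion with box
detections — implemented and tested end-to-end on synthetic
panoramic-radiograph phantoms with exact ground truth.

## Who this is for

Researchers and engineers studying detector-fusion pipelines for dental
radiography who need a fully reproducible, CPU-only reference
implementation of the mechanism — not a clinical tool. No patient data is
included or required: a phantom generator produces radiograph-like images
with paired fracture-line masks, tooth-region masks and class-labelled
boxes for six anatomical fracture classes (symphysis, body, angle, ramus,
condyle, coronoid) and three morphologies (oblique gap, shear step,
displaced condyle).

## The method

For an image *I*, with U-Nets `U_frac` and `U_tooth` and a box source *B*
(external detections file or the built-in compact grid detector):

    T  = fill(dilate(U_tooth(I)))          # solid tooth band
    W  = 1 − T                             # binary weight map
    L  = despeckle(U_frac(I) ⊙ W)          # suppressed fracture lines
    D  = NMS(B(I))                         # de-duplicated boxes
    output = D ∪ components(L)             # union, no cross-suppression

Scoring uses precision = TP/(TP+FP), recall = TP/(TP+FN) and their harmonic
mean F1; no true negatives exist because every image contains fractures.
The headline property of the design — verified by the test suite on
phantoms — is that adding the suppressed U-Net lines to a box source that
is blind to the middle of the mandible raises recall substantially while
precision stays within a few points.

Both networks run on a small, dependency-free NumPy conv-net engine
(im2col convolutions, batch norm, ELU/ReLU/LeakyReLU, Adam, manual
backprop), so everything trains and runs on one CPU core.

## Worked example

```python
import numpy as np
import mandifrac as mf
from mandifrac import pipeline, segnet

cfg = pipeline.smoke_phantom_config(seed=0)          # 128x128 phantoms
train = [mf.generate_phantom(cfg, 1000 + i) for i in range(40)]
held  = [mf.generate_phantom(cfg, 5000 + i) for i in range(30)]

frac, tooth, *_ = pipeline.train_smoke_models(
    [(im, gt.line_mask) for im, gt in train],
    [(im, gt.tooth_mask) for im, gt in train])

dice = np.mean([segnet.dice_coefficient(
    segnet.predict_mask(frac, im, 0.5), gt.line_mask) for im, gt in held[:10]])
print(f"held-out fracture-line Dice: {dice:.3f}")

cmp = pipeline.middle_blind_comparison(pipeline.PipelineConfig(),
                                       held, frac, tooth)
print("box-only  P={precision:.3f} R={recall:.3f}".format(**cmp["box_only"]))
print("fused     P={precision:.3f} R={recall:.3f}".format(**cmp["fused"]))
```

Output from this exact script (seeded, deterministic):

```
held-out fracture-line Dice: 0.696
box-only  P=1.000 R=0.023
fused     P=1.000 R=0.705
```

The Dice score says the smoke-trained U-Net recovers fracture lines well on
unseen phantoms. The comparison lines show the fusion mechanism: a box
source restricted to side-region (condyle/coronoid) detections misses
nearly every middle-region fracture; adding the tooth-suppressed U-Net
lines lifts recall from 0.02 to 0.71 at unchanged precision on this
phantom set.

There is also a CLI for file-based use, mirroring the pipeline stages:

```sh
mandifrac generate --n 10 --seed 1 --size 128 --out data/
mandifrac train-seg --task fracture --data data/ --out frac.npz
mandifrac train-seg --task tooth    --data data/ --out tooth.npz
mandifrac predict data/phantom_0000.png --fracture-model frac.npz \
    --tooth-model tooth.npz --boxes data/phantom_0000.txt --out result
mandifrac profile data/phantom_0000.png --from 10,64 --to 117,64
```

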