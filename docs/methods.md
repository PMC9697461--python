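# Methods

## Problem and approach

Mandibular fractures on panoramic radiographs are hard to read: the
projection compresses the side regions (condyle, coronoid process), exposure
varies widely, and the radiolucent gaps between teeth mimic fracture lines.
`mandifrac` implements a combined detector that plays two model families
against their respective weaknesses:

1. a **fracture-line U-Net** segments crack-shaped fractures, which works
   well in the middle of the mandible (symphysis, body, angle, ramus) where
   box detectors under-detect;
2. a **tooth-region U-Net** segments the tooth row; its output is dilated,
   hole-filled, inverted into a binary weight map and **multiplied** into
   the fracture mask, erasing the characteristic false positives between
   teeth;
3. a **box source** (an external detections file or the built-in compact
   grid detector) contributes box detections, which are the only way to
   catch condylar dislocations — these have no crack line at all and are
   deliberately not labelled for segmentation;
4. surviving boxes (after class-wise NMS) and line components are reported
   **jointly** (union semantics, no cross-modality suppression).

The intended effect, which the acceptance suite measures on phantoms, is
that fusion raises recall where boxes are blind while suppression keeps the
precision cost small.

## Synthetic phantoms

No clinical radiographs ship with the package, so every stage is exercised
on synthetic panoramic phantoms with exact ground truth. A phantom has:

* a U-shaped mandible arch (parabolic-sine band, half-width ≈ 4% of the
  image side) on a darker soft-tissue background, with per-phantom jitter of
  span, height and depth;
* six anatomical sectors at fixed, left/right-symmetric arc fractions of the
  arch (condyle 0–0.07, coronoid 0.07–0.12, ramus 0.12–0.20, angle
  0.20–0.30, body 0.30–0.42 per side, symphysis 0.42–0.58);
* a striped tooth band offset to the interior of the arch over the
  tooth-bearing part;
* smooth global/local shading (random linear ramp plus two Gaussian blobs)
  and additive Gaussian noise (default σ = 5 gray levels, 4 in the smoke
  profile);
* fractures drawn per image as 1 + Poisson(0.73) (clinical mean ≈ 1.73 per
  radiograph), with anatomical class frequencies set to the clinical
  training distribution (24.5 / 23.2 / 29.3 / 14.6 / 6.25 / 2.08% over 624
  fractures).

Three morphologies are rendered: an **oblique gap** (radiolucent band of
2.5–5.5 px crossing the bone), a **shear step** (+26 gray levels on one side
of the line with a faint 1-px seam), and a **displaced** condylar
dislocation (the condylar bone segment duplicated with an offset — doubled
contours, no crack). Morphology frequencies default to 0.55 / 0.30 / 0.15;
no published breakdown exists, so these are a fixed package choice, and the
displaced morphology is restricted to the condyle, where dislocation occurs
anatomically.

Ground truth pairs each image with: the fracture-line mask (polylines
dilated to 3 px; displaced fractures excluded — they have no line to
label), the filled tooth-band mask, and one class-labelled box per fracture
including displaced ones. What the phantoms deliberately do **not** model:
spine/sinus shadows, restorations, soft-tissue texture, patient-motion blur,
and the left–right compression gradient of real panoramic geometry. Passing
tests therefore demonstrate the pipeline's mechanics (suppression algebra,
fusion arithmetic, trainability of the networks on line-on-band imagery),
not clinical-grade detection.

## Tone mapping (SLAT/MLAT surrogate)

The luminance-adaptation transform is implemented as a surround-adaptive
operator: with surround s = Gaussian blur of the image (σ = 25 px) in
[0, 1], each pixel v maps to

    out = s^γ(s) + (1 + k·(1 − s)) · (v − s),   γ(s) = 1 − k·(1 − s)

with strength k (default 0.7), clipped to [0, 1]. Dark surrounds get a
small exponent (brightening) and a detail gain > 1 (local contrast up);
bright surrounds are near identity. The single-stage form (SLAT) enhances
local detail; the multi-stage form (MLAT) cascades the per-stage transform
with strength k/stages (default 3 stages), compounding the tone curve into
global compression. This surrogate satisfies the behavioural contract used
throughout the tests — flat fields invariant, k = 0 identity, dark images
brightened, profile contrast raised on dark radiograph-like images, bright
dynamic range not expanded — without claiming fidelity to any specific
published LAT algorithm. Gamma correction is the classic 255·(v/255)^γ with
default augmentation exponents {0.75, 1.25}.

Training-set expansion appends one tone-mapped copy per enabled variant, so
SLAT + MLAT triple a set (360 → 1080), matching the augmentation arithmetic
of the combined module.

## Networks

Because the package targets plain CPU-only scientific Python, both networks
run on a small in-repo NumPy engine (`_nn.py`): im2col 3×3/1×1
convolutions, batch normalization, ReLU/LeakyReLU/ELU, 2×2 max pooling,
nearest upsampling and Adam, with hand-written backprop (verified against
numerical gradients). All computation is float32 and deterministic given
the seed.

**U-Net.** Standard contracting/expanding layout: per level two
(conv 3×3 → BN → activation) blocks; pooling halves resolution while
channels double; the decoder upsamples and concatenates the same-level
encoder features. The activation is a config toggle; ELU (α = 1) is the
default since its nonzero negative-branch derivative avoids dead units on
the sparse fracture-line target. Defaults mirror the clinical-scale recipe
(512×512, depth 5, lr 1e-4, batch 6, 300 epochs, Adam); the **smoke
profile** used by tests and the acceptance script is 128×128, depth 3,
8 base channels, lr 2e-3, batch 4, 30 epochs — about two minutes per model
on one CPU. The loss is BCE plus a soft-Dice term (weight 1), which
counteracts the ~2% foreground fraction of line masks; plain BCE is
available in `TrainConfig`. Inference resizes bilinearly to the network
size, thresholds the sigmoid strictly (> t, so t = 1 gives an empty and
t = 0 a full mask) and maps back by nearest neighbour.

**Grid detector.** The pluggable reference box detector is a single-scale
convolutional grid (128×128 → 8×8 cells; per cell one objectness logit,
four box parameters — sigmoid in-cell center offsets and sqrt-scaled
width/height — and six class logits), trained with BCE objectness, MSE box
regression and BCE class terms on center cells. It stands in for a full
YOLO-family detector, whose backbone is out of scope; the detections-file
path lets any external detector drive the fusion stage. Its smoke recipe
trains on a condyle-heavy phantom mix, since at n = 40 the clinical class
mix contains too few side fractures to learn from.

## Post-processing and fusion

Tooth-mask filling: dilation with a disk of radius 3, 2 iterations,
followed by flood-fill hole closing (dilated-then-inverted is the
configurable default; the raw mask can be inverted instead). Suppression is
the exact Boolean product `frac AND NOT filled_tooth`. Components under 20
px (at 512²; same value kept at 128² where it removes specks of < 0.13% of
the image) are dropped — thresholded network output needs despeckling even
though the original procedure does not mention it. Duplicate boxes are
removed by class-wise greedy NMS at IoU 0.5, confidence-descending with
area-then-left-edge tie-breaks. Fusion keeps all box classes (not only side
classes): combined outputs are shown with middle-region boxes in the source
material, and a `boxes_side_only` flag preserves the stricter reading.

## Evaluation protocol

There are no fracture-free images, so no true negatives exist and only
precision (misdetection), recall (undetection) and F1 are reported.
TP adjudication is not published for the clinical study (it was visual);
the package fixes an explicit rule: one-to-one maximum matching (assignment
problem on the compatibility matrix), boxes first — a predicted box matches
a ground-truth box at IoU ≥ 0.5 — then line components — a component
matches a fracture line when ≥ 50% of its pixels lie within the 5-px
dilated ground-truth polyline; displaced fractures have no line and can
only be box-matched. A fracture matched by both modalities counts one TP
and consumes both predictions; an extra line fragment along an
already-detected fracture is likewise consumed rather than counted as a
false positive (fragments of one crack are one finding, not a
misdetection). Consequently tp + fp = |predictions| holds exactly for
single-modality predictions and is otherwise reduced by the consumed
doubles. All thresholds live in `MatchCriteria`.

Line profiles (max/min/mean/std along a Bresenham segment) use the
population standard deviation — the printed reference values cannot
distinguish population from sample std, so this is fixed by decision.
Class-distribution percentages are rounded half-up at 3 decimals.

## Problem sizes and determinism

Tests and the acceptance script run at phantom size 128×128 with 40
training and 30 held-out phantoms, 30 epochs — sizes chosen so the whole
suite runs in minutes on a single CPU while leaving the learning problems
non-trivial. Every stochastic stage (phantom sampling, weight init, batch
shuffling) draws from an explicit `numpy` Generator seeded from one global
seed; identical (config, seed) reproduce datasets bit-for-bit and loss
trajectories exactly.

## Known limitations

* The phantom is geometric, not photometric: absolute Dice/precision values
  on phantoms say nothing quantitative about clinical images.
* The NumPy engine is CPU-bound and desk-scale; clinical-scale
  512×512 / depth-5 / 300-epoch training, while configured, is not a
  practical target on one core.
* The reference grid detector has no anchors and one cell per object; it
  cannot separate two fractures whose centers fall in the same cell.
* The matching rule is a package decision; different adjudication (e.g.
  center-in-box) would shift absolute P/R on the same outputs.
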