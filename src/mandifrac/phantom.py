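"""Synthetic panoramic-radiograph phantoms with paired ground truth.

A phantom emulates the features of a mandibular panoramic radiograph that the
detection pipeline depends on: a U-shaped mandible arch (bright bone band on a
darker soft-tissue background), a tooth-row band sitting on the arch, smooth
global/local shading variation, additive sensor noise, and one or more
fractures drawn from six anatomical classes (symphysis, body, angle, ramus,
condyle, coronoid) with three morphologies:

* ``oblique_gap``   — a radiolucent (dark) gap crossing the bone,
* ``shear_step``    — a brightness step discontinuity along the fracture line,
* ``displaced``     — condylar dislocation: two overlapping bone contours with
                      no visible crack line.

Ground truth pairs every image with a fracture-line mask (displaced fractures
are deliberately *not* marked — they have no line to label), a tooth-region
mask, and one class-labelled bounding box per fracture (displaced included).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

CLASS_NAMES = ("symphysis", "body", "angle", "ramus", "condyle", "coronoid")
SHAPE_NAMES = ("oblique_gap", "shear_step", "displaced")

#: Anatomical class frequencies of the reference clinical training
#: distribution (624 fractures: 153/145/183/91/39/13).
DEFAULT_CLASS_PROBS = (
    153 / 624, 145 / 624, 183 / 624, 91 / 624, 39 / 624, 13 / 624,
)

#: Morphology mix. Not clinically calibrated (no published breakdown exists);
#: oblique gaps dominate, displaced applies to condyle fractures only.
DEFAULT_SHAPE_PROBS = (0.55, 0.30, 0.15)


class PhantomError(ValueError):
    """Invalid phantom configuration or geometry."""


@dataclass(frozen=True)
class PhantomConfig:
    width: int = 512
    height: int = 512
    class_probs: tuple = DEFAULT_CLASS_PROBS
    shape_probs: tuple = DEFAULT_SHAPE_PROBS
    #: fractures per image = ``min_fractures + Poisson(extra_fracture_rate)``;
    #: the clinical mean is 624/360 ~ 1.73 fractures per radiograph.
    min_fractures: int = 1
    extra_fracture_rate: float = 0.73
    noise_sigma: float = 5.0
    line_thickness_px: int = 3
    seed: int = 0

    def __post_init__(self):
        validate_probs(self.class_probs, 6, "class_probs")
        validate_probs(self.shape_probs, 3, "shape_probs")
        if self.width < 128 or self.height < 128:
            raise PhantomError("width and height must be >= 128")
        if self.min_fractures < 1:
            raise PhantomError("min_fractures must be >= 1")
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be >= 0")


def validate_probs(probs, n: int, name: str) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (n,):
        raise PhantomError(f"{name} must have length {n}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise PhantomError(f"{name} must be nonnegative and sum to 1")
    return p


@dataclass(frozen=True)
class MandibleScene:
    """Geometry of one phantom: arch, anatomical sectors, tooth band."""

    width: int
    height: int
    arch_polyline: np.ndarray        # (n, 2) float, (x, y), t = 0..1 left->right
    arch_halfwidth: float            # bone band half-width, px
    sector_map: dict                 # class name -> list of (t0, t1) intervals
    tooth_polygon: np.ndarray        # (m, 2) float, closed (x, y) polygon

    def arch_point(self, t: float) -> np.ndarray:
        n = len(self.arch_polyline)
        idx = min(int(round(t * (n - 1))), n - 1)
        return self.arch_polyline[idx]

    def arch_normal(self, t: float) -> np.ndarray:
        n = len(self.arch_polyline)
        idx = min(max(int(round(t * (n - 1))), 1), n - 2)
        tang = self.arch_polyline[idx + 1] - self.arch_polyline[idx - 1]
        tang /= np.linalg.norm(tang) + 1e-12
        return np.array([-tang[1], tang[0]])


@dataclass(frozen=True)
class FractureSpec:
    klass: str
    shape: str
    polyline: np.ndarray             # (k, 2) float pixel coords (x, y)
    gap_px: float
    box: tuple                       # (x0, y0, x1, y1) half-open pixel rect

    def __post_init__(self):
        if self.klass not in CLASS_NAMES:
            raise PhantomError(f"unknown class {self.klass!r}")
        if self.shape not in SHAPE_NAMES:
            raise PhantomError(f"unknown shape {self.shape!r}")
        if len(self.polyline) < 2:
            raise PhantomError("polyline needs >= 2 points")
        if self.shape == "displaced" and self.klass != "condyle":
            raise PhantomError("displaced morphology is condyle-only")
        if self.gap_px < 0:
            raise PhantomError("gap_px must be >= 0")
        x0, y0, x1, y1 = self.box
        xs, ys = self.polyline[:, 0], self.polyline[:, 1]
        if xs.min() < x0 or ys.min() < y0 or xs.max() >= x1 or ys.max() >= y1:
            raise PhantomError("box must contain the polyline")


@dataclass
class GroundTruth:
    specs: list
    line_mask: np.ndarray            # uint8 {0,1}, fracture lines, displaced excluded
    tooth_mask: np.ndarray           # uint8 {0,1}
    boxes: list                      # [(klass, (x0, y0, x1, y1))], one per spec


# ---------------------------------------------------------------------------
# class sampling

def sample_fracture_classes(n: int, probs, rng: np.random.Generator) -> list:
    """Draw ``n`` i.i.d. anatomical class labels from a 6-class distribution."""
    if n < 1:
        raise PhantomError("n must be >= 1")
    p = validate_probs(probs, 6, "probs")
    idx = rng.choice(6, size=n, p=p)
    return [CLASS_NAMES[i] for i in idx]


def _sample_shape(klass: str, shape_probs, rng: np.random.Generator) -> str:
    p = np.asarray(shape_probs, dtype=float)
    if klass != "condyle":
        # displaced is anatomically a condylar dislocation; renormalise over
        # the two crack-line morphologies for every other class
        q = p[:2]
        if q.sum() <= 0:
            return "oblique_gap"
        q = q / q.sum()
        return SHAPE_NAMES[rng.choice(2, p=q)]
    return SHAPE_NAMES[rng.choice(3, p=p / p.sum())]


# ---------------------------------------------------------------------------
# scene geometry

# sector boundaries as fractions of the arch parameter, symmetric about
# t = 0.5 (the symphysis).  Left half: condyle, coronoid, ramus, angle, body.
_SECTOR_EDGES = (0.0, 0.07, 0.12, 0.20, 0.30, 0.42)
_SECTOR_ORDER = ("condyle", "coronoid", "ramus", "angle", "body")


def build_scene(config: PhantomConfig, rng: np.random.Generator) -> MandibleScene:
    """Lay out the mandible arch, its anatomical sectors and the tooth band."""
    w, h = config.width, config.height
    if w < 128 or h < 128:
        raise PhantomError("image too small to fit the mandible arch")
    cx = w / 2.0
    # mild per-phantom variation so phantoms are not all congruent
    a = (0.36 + 0.03 * rng.random()) * w          # half-span
    y_top = (0.18 + 0.04 * rng.random()) * h      # condyle height
    depth = (0.50 + 0.05 * rng.random()) * h      # arch drop to the symphysis

    t = np.linspace(0.0, 1.0, 257)
    x = cx + a * np.sin(np.pi * (t - 0.5))
    y = y_top + depth * np.cos(np.pi * (t - 0.5)) ** 0.9
    arch = np.stack([x, y], axis=1)

    sector_map = {}
    for name, t0, t1 in zip(_SECTOR_ORDER, _SECTOR_EDGES[:-1], _SECTOR_EDGES[1:]):
        sector_map[name] = [(t0, t1), (1.0 - t1, 1.0 - t0)]
    sector_map["symphysis"] = [(_SECTOR_EDGES[-1], 1.0 - _SECTOR_EDGES[-1])]

    halfwidth = 0.040 * min(w, h)

    # tooth band: arch offset toward the interior (smaller y) over the
    # tooth-bearing part of the arch (body + symphysis)
    t_lo, t_hi = 0.27, 0.73
    sel = (t >= t_lo) & (t <= t_hi)
    pts = arch[sel]
    normals = _polyline_normals(pts)
    inner = pts + normals * (halfwidth * 1.1)
    outer = pts + normals * (halfwidth * 1.1 + 0.085 * h)
    poly = np.concatenate([inner, outer[::-1]], axis=0)
    poly[:, 0] = np.clip(poly[:, 0], 1, w - 2)
    poly[:, 1] = np.clip(poly[:, 1], 1, h - 2)

    return MandibleScene(
        width=w, height=h, arch_polyline=arch, arch_halfwidth=halfwidth,
        sector_map=sector_map, tooth_polygon=poly,
    )


def _polyline_normals(pts: np.ndarray) -> np.ndarray:
    """Unit normals pointing toward +y cross of the local tangent."""
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True) + 1e-12
    return np.stack([tang[:, 1], -tang[:, 0]], axis=1)


# ---------------------------------------------------------------------------
# fracture placement

def sample_fracture_specs(
    scene: MandibleScene, config: PhantomConfig, rng: np.random.Generator,
    n: int | None = None,
) -> list:
    """Place fractures on the scene: class, morphology, crossing polyline."""
    if n is None:
        n = config.min_fractures + int(rng.poisson(config.extra_fracture_rate))
    classes = sample_fracture_classes(n, config.class_probs, rng)
    specs = []
    for klass in classes:
        shape = _sample_shape(klass, config.shape_probs, rng)
        specs.append(_place_fracture(scene, klass, shape, config, rng))
    return specs


def _place_fracture(scene, klass, shape, config, rng) -> FractureSpec:
    intervals = scene.sector_map[klass]
    t0, t1 = intervals[int(rng.integers(len(intervals)))]
    t = float(t0 + (0.15 + 0.7 * rng.random()) * (t1 - t0))
    p = scene.arch_point(t)
    nrm = scene.arch_normal(t)
    # crossing direction: arch normal rotated by a random oblique angle
    ang = np.deg2rad(rng.uniform(-25, 25))
    c, s = np.cos(ang), np.sin(ang)
    d = np.array([c * nrm[0] - s * nrm[1], s * nrm[0] + c * nrm[1]])
    reach = scene.arch_halfwidth * 1.45
    ends = np.stack([p - d * reach, p + d * reach])
    # a midpoint jitter makes the line a genuine polyline
    mid = p + d * rng.uniform(-0.3, 0.3) * reach
    mid += np.array([-d[1], d[0]]) * rng.uniform(-0.15, 0.15) * reach
    poly = np.stack([ends[0], mid, ends[1]])
    poly[:, 0] = np.clip(poly[:, 0], 1, scene.width - 2)
    poly[:, 1] = np.clip(poly[:, 1], 1, scene.height - 2)
    gap = 0.0 if shape == "displaced" else float(rng.uniform(2.5, 5.5))
    margin = max(gap, 4.0) + 3.0
    if shape == "displaced":
        margin += 0.6 * scene.arch_halfwidth + 8.0
    box = _bbox_of(poly, margin, scene.width, scene.height)
    return FractureSpec(klass=klass, shape=shape, polyline=poly, gap_px=gap, box=box)


def _bbox_of(poly: np.ndarray, margin: float, w: int, h: int) -> tuple:
    x0 = int(np.floor(poly[:, 0].min() - margin))
    y0 = int(np.floor(poly[:, 1].min() - margin))
    x1 = int(np.ceil(poly[:, 0].max() + margin)) + 1
    y1 = int(np.ceil(poly[:, 1].max() + margin)) + 1
    return (max(x0, 0), max(y0, 0), min(x1, w), min(y1, h))


# ---------------------------------------------------------------------------
# rendering

_BG, _BONE, _TOOTH = 52.0, 168.0, 205.0


def render_phantom(
    scene: MandibleScene, specs: list, noise_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render an 8-bit grayscale phantom for a scene plus fracture specs."""
    h, w = scene.height, scene.width
    img = np.full((h, w), _BG, dtype=float)

    bone = _band_mask(scene.arch_polyline, scene.arch_halfwidth, h, w)
    img[bone] = _BONE

    # tooth band: brighter, with a periodic stripe pattern suggesting teeth
    rr, cc = draw_polygon(scene.tooth_polygon[:, 1], scene.tooth_polygon[:, 0],
                          shape=(h, w))
    stripes = 0.5 * (1 + np.sin(np.arange(w) * (2 * np.pi / max(8, w // 28))))
    img[rr, cc] = _TOOTH - 25.0 * stripes[cc]

    for spec in specs:
        _render_fracture(img, bone, spec, scene)

    # smooth the hard edges a little, as a radiograph never has 1-px edges
    img = gaussian_filter(img, 1.2)

    # global + local shading variation
    img += _shading_field(h, w, rng)

    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=(h, w))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _shading_field(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Global linear gradient plus two soft local blobs, zero-mean-ish."""
    yy, xx = np.mgrid[0:h, 0:w]
    theta = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(4.0, 12.0)
    field = amp * ((xx / w) * np.cos(theta) + (yy / h) * np.sin(theta))
    for _ in range(2):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        sig = rng.uniform(0.2, 0.45) * min(h, w)
        a = rng.uniform(-10.0, 10.0)
        field += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig * sig))
    return field - field.mean()


def _band_mask(polyline: np.ndarray, halfwidth: float, h: int, w: int) -> np.ndarray:
    normals = _polyline_normals(polyline)
    upper = polyline - normals * halfwidth
    lower = polyline + normals * halfwidth
    poly = np.concatenate([upper, lower[::-1]], axis=0)
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(np.clip(poly[:, 1], 0, h - 1),
                          np.clip(poly[:, 0], 0, w - 1), shape=(h, w))
    mask[rr, cc] = True
    return mask


def rasterize_polyline(polyline: np.ndarray, shape: tuple) -> np.ndarray:
    """1-px raster of a polyline (Bresenham segments), bool mask."""
    mask = np.zeros(shape, dtype=bool)
    p = np.round(polyline).astype(int)
    for a, b in zip(p[:-1], p[1:]):
        rr, cc = draw_line(a[1], a[0], b[1], b[0])
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    return mask


def _disk(radius: int) -> np.ndarray:
    r = max(int(radius), 1)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return xx * xx + yy * yy <= r * r


def _render_fracture(img, bone, spec: FractureSpec, scene) -> None:
    h, w = img.shape
    if spec.shape == "displaced":
        # dislocation: duplicate the condylar bone segment, shifted; the
        # overlap reads as doubled (brighter) bone contours, no dark crack
        x0, y0, x1, y1 = spec.box
        local = np.zeros_like(bone)
        local[y0:y1, x0:x1] = bone[y0:y1, x0:x1]
        dx, dy = int(0.35 * scene.arch_halfwidth) + 3, int(0.3 * scene.arch_halfwidth) + 2
        shifted = np.zeros_like(local)
        shifted[max(dy, 0):h, max(dx, 0):w] = local[0:h - dy, 0:w - dx]
        img[shifted & ~bone] = _BONE - 12.0       # displaced fragment over soft tissue
        img[shifted & bone] = _BONE + 34.0        # doubled-bone overlap
        return

    line = rasterize_polyline(spec.polyline, (h, w))
    if spec.shape == "oblique_gap":
        band = binary_dilation(line, structure=_disk(max(round(spec.gap_px / 2), 1)))
        img[band & bone] = _BG + 18.0             # radiolucent gap
    else:  # shear_step
        side = _side_field(spec.polyline, h, w, spec.box)
        near = binary_dilation(line, structure=_disk(int(2.2 * scene.arch_halfwidth)))
        img[near & bone & side] += 26.0           # step discontinuity
        seam = binary_dilation(line, structure=_disk(1))
        img[seam & bone] -= 20.0                  # faint crack seam


def _side_field(polyline, h, w, box) -> np.ndarray:
    """Boolean half-plane split by the fracture chord, limited to its box."""
    p0, p1 = polyline[0], polyline[-1]
    d = p1 - p0
    yy, xx = np.mgrid[0:h, 0:w]
    cross = (xx - p0[0]) * d[1] - (yy - p0[1]) * d[0]
    side = cross > 0
    lim = np.zeros((h, w), dtype=bool)
    x0, y0, x1, y1 = box
    lim[y0:y1, x0:x1] = True
    return side & lim


# ---------------------------------------------------------------------------
# ground truth

def make_ground_truth(
    scene: MandibleScene, specs: list, line_thickness_px: int = 3,
) -> GroundTruth:
    """Label masks and boxes: lines for crack morphologies only, boxes for all."""
    h, w = scene.height, scene.width
    line_mask = np.zeros((h, w), dtype=np.uint8)
    for spec in specs:
        if spec.shape == "displaced":
            continue
        raster = rasterize_polyline(spec.polyline, (h, w))
        raster = binary_dilation(raster, structure=_disk(max(line_thickness_px // 2, 1)))
        line_mask[raster] = 1

    tooth_mask = np.zeros((h, w), dtype=np.uint8)
    rr, cc = draw_polygon(scene.tooth_polygon[:, 1], scene.tooth_polygon[:, 0],
                          shape=(h, w))
    tooth_mask[rr, cc] = 1

    boxes = [(s.klass, s.box) for s in specs]
    return GroundTruth(specs=list(specs), line_mask=line_mask,
                       tooth_mask=tooth_mask, boxes=boxes)


def generate_phantom(config: PhantomConfig, seed: int) -> tuple:
    """One (image, GroundTruth) pair, deterministic in (config, seed)."""
    rng = np.random.default_rng(seed)
    scene = build_scene(config, rng)
    specs = sample_fracture_specs(scene, config, rng)
    img = render_phantom(scene, specs, config.noise_sigma, rng)
    gt = make_ground_truth(scene, specs, config.line_thickness_px)
    return img, gt


# ---------------------------------------------------------------------------
# dataset files

def generate_dataset(config: PhantomConfig, n_images: int, out_dir) -> dict:
    """Write ``n_images`` phantoms as PNG + masks + YOLO txt + manifest JSON."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n_images):
        seed = config.seed * 1_000_003 + i
        img, gt = generate_phantom(config, seed)
        stem = f"phantom_{i:04d}"
        paths = {
            "image": f"{stem}.png",
            "line_mask": f"{stem}_line.png",
            "tooth_mask": f"{stem}_tooth.png",
            "boxes": f"{stem}.txt",
        }
        try:
            iio.imwrite(out / paths["image"], img)
            iio.imwrite(out / paths["line_mask"], gt.line_mask * 255)
            iio.imwrite(out / paths["tooth_mask"], gt.tooth_mask * 255)
            _write_yolo(out / paths["boxes"], gt.boxes, config.width, config.height)
        except OSError as e:
            raise OSError(f"failed writing phantom files under {out}: {e}") from e
        records.append({
            "seed": seed,
            "files": paths,
            "fractures": [
                {"class": s.klass, "shape": s.shape, "gap_px": s.gap_px,
                 "box": list(s.box)}
                for s in gt.specs
            ],
        })
    manifest = {
        "seed": config.seed,
        "n_images": n_images,
        "width": config.width,
        "height": config.height,
        "images": records,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_yolo(path: Path, boxes: list, w: int, h: int) -> None:
    lines = []
    for klass, (x0, y0, x1, y1) in boxes:
        cid = CLASS_NAMES.index(klass)
        cx, cy = (x0 + x1) / 2 / w, (y0 + y1) / 2 / h
        bw, bh = (x1 - x0) / w, (y1 - y0) / h
        lines.append(f"{cid} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def dataset_digest(out_dir) -> str:
    """SHA-256 over all dataset files, for determinism checks."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
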