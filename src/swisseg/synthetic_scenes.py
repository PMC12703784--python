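"""Seeded simulator of paired laboratory-like and field-like paddy scenes.

The generator emulates the *structure* of a two-domain crop/weed dataset, not
its photographic appearance: a laboratory domain (uniform tray background,
flat illumination) and a field domain whose appearance is shifted by a single
magnitude parameter delta — background reflectance moves toward wet paddy
soil, an illumination gradient and global brightness jitter appear, specular
water-glare blobs and background clutter are scattered over the scene.

Plants are rendered as rotated superellipse blobs with class-specific
elongation, color and band-pass noise texture, composited back-to-front; the
label mask records the top-most class per pixel and the instance map the
top-most instance. delta = 0 reproduces the laboratory distribution exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from imageio.v3 import imwrite
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .metrics_eval import ClassMap

__all__ = [
    "DomainParams",
    "SceneSpec",
    "SyntheticSample",
    "generate_scene",
    "generate_dataset",
    "domain_gap_probe",
]

# per-unit-delta shift of the field domain relative to the laboratory reference
_COLOR_SHIFT = np.array([-0.08, 0.04, 0.12])
_NOISE_SHIFT = 0.03
_ILLUM_SHIFT = 0.30
_SPECULAR_RATE = 3.0
_CLUTTER_RATE = 4.0
_BRIGHTNESS_JITTER = 0.25

# class appearance: color, texture smoothing sigma, superellipse exponent, elongation
_CLASS_STYLE = {
    "crop": {"color": (0.20, 0.55, 0.20), "tex_sigma": 0.8, "exponent": 2.0,
             "elongation": 0.30},
    "weed": [
        {"color": (0.50, 0.62, 0.12), "tex_sigma": 1.6, "exponent": 1.4,
         "elongation": 0.85},
        {"color": (0.10, 0.42, 0.32), "tex_sigma": 3.0, "exponent": 4.0,
         "elongation": 0.65},
        {"color": (0.55, 0.45, 0.15), "tex_sigma": 1.0, "exponent": 2.5,
         "elongation": 0.50},
        {"color": (0.30, 0.60, 0.40), "tex_sigma": 2.2, "exponent": 1.8,
         "elongation": 0.75},
        {"color": (0.60, 0.55, 0.30), "tex_sigma": 1.3, "exponent": 3.0,
         "elongation": 0.40},
        {"color": (0.18, 0.50, 0.15), "tex_sigma": 2.6, "exponent": 2.2,
         "elongation": 0.90},
    ],
}


@dataclass
class DomainParams:
    """Appearance parameters of one acquisition domain.

    ``delta`` scales every shift relative to the laboratory reference;
    delta = 0 is the laboratory distribution itself.
    """

    background_color: tuple = (0.32, 0.28, 0.22)
    background_noise: float = 0.02
    illum_direction: float = 0.0
    illum_amplitude: float = 0.05
    specular_rate: float = 0.0
    clutter_density: float = 0.0
    brightness_jitter: float = 0.0
    delta: float = 0.0

    @classmethod
    def lab(cls) -> "DomainParams":
        return cls()

    @classmethod
    def field(cls, delta: float = 1.0) -> "DomainParams":
        if delta < 0:
            raise ValueError("delta must be nonnegative")
        ref = cls.lab()
        return cls(
            background_color=tuple(np.asarray(ref.background_color)
                                   + delta * _COLOR_SHIFT),
            background_noise=ref.background_noise + delta * _NOISE_SHIFT,
            illum_direction=0.6 * min(delta, 1.0),
            illum_amplitude=ref.illum_amplitude + delta * _ILLUM_SHIFT,
            specular_rate=delta * _SPECULAR_RATE,
            clutter_density=delta * _CLUTTER_RATE,
            brightness_jitter=delta * _BRIGHTNESS_JITTER,
            delta=delta,
        )


@dataclass
class SceneSpec:
    """Geometry and class composition of a rendered scene."""

    image_size: tuple = (64, 64)
    n_classes: int = 4  # background + crop + weeds
    plants_per_image: tuple = (3, 7)
    instance_size_range: tuple = (8, 26)  # blob diameter in pixels
    overlap_allowed: bool = True
    class_weights: tuple | None = None  # foreground classes 1..n_classes-1

    def __post_init__(self):
        if self.n_classes < 3:
            raise ValueError("need at least background + crop + one weed class")
        if self.instance_size_range[1] > min(self.image_size):
            raise ValueError(
                f"instance size {self.instance_size_range[1]} exceeds image "
                f"bounds {self.image_size}")
        n_fg = self.n_classes - 1
        if self.class_weights is None:
            self.class_weights = tuple([1.0 / n_fg] * n_fg)
        if len(self.class_weights) != n_fg:
            raise ValueError("one weight per foreground class required")

    def class_map(self) -> ClassMap:
        return ClassMap.default(n_weeds=self.n_classes - 2)


@dataclass
class SyntheticSample:
    """One rendered scene: image in [0,1], class mask, instance map, domain tag."""

    image: np.ndarray  # (H, W, 3) float32
    mask: np.ndarray  # (H, W) uint8
    instance_ids: np.ndarray  # (H, W) int32, 0 = background
    domain: str  # "lab" | "field"


def _smooth_noise(rng, shape, sigma):
    n = gaussian_filter(rng.standard_normal(shape), sigma=sigma, axes=(0, 1))
    s = n.std()
    return n / s if s > 0 else n


def _superellipse_mask(H, W, cy, cx, a, b, angle, exponent):
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    u = np.cos(angle) * dx + np.sin(angle) * dy
    v = -np.sin(angle) * dx + np.cos(angle) * dy
    r = (np.abs(u / a) ** exponent + np.abs(v / b) ** exponent)
    return r <= 1.0


def _class_style(class_id: int):
    if class_id == 1:
        return _CLASS_STYLE["crop"]
    weeds = _CLASS_STYLE["weed"]
    return weeds[(class_id - 2) % len(weeds)]


def generate_scene(spec: SceneSpec, dom: DomainParams,
                   rng: np.random.Generator) -> SyntheticSample:
    """Render one scene; bit-deterministic given (spec, dom, rng state)."""
    H, W = spec.image_size
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = np.asarray(dom.background_color)
    img += dom.background_noise * _smooth_noise(rng, (H, W, 3), sigma=2.0)

    # background clutter: stones / debris, labeled background
    n_clutter = rng.poisson(dom.clutter_density)
    for _ in range(n_clutter):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        a = rng.uniform(2, 6)
        b = a * rng.uniform(0.5, 1.0)
        m = _superellipse_mask(H, W, cy, cx, a, b, rng.uniform(0, np.pi), 2.0)
        shade = rng.uniform(-0.12, 0.12, size=3)
        img[m] = np.clip(img[m] + shade, 0, 1)

    # specular water glare: saturated near-white blobs on the background
    n_glare = rng.poisson(dom.specular_rate)
    for _ in range(n_glare):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        a = rng.uniform(1.5, 5)
        b = a * rng.uniform(0.4, 1.0)
        m = _superellipse_mask(H, W, cy, cx, a, b, rng.uniform(0, np.pi), 2.0)
        img[m] = rng.uniform(0.92, 1.0)

    mask = np.zeros((H, W), dtype=np.uint8)
    inst = np.zeros((H, W), dtype=np.int32)
    n_plants = int(rng.integers(spec.plants_per_image[0],
                                spec.plants_per_image[1] + 1))
    weights = np.asarray(spec.class_weights) / np.sum(spec.class_weights)
    inst_id = 0
    for _ in range(n_plants):
        inst_id += 1
        cls = int(rng.choice(np.arange(1, spec.n_classes), p=weights))
        style = _class_style(cls)
        size = rng.uniform(*spec.instance_size_range)
        b_half = size / 2.0
        a_half = b_half * style["elongation"]
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        angle = rng.uniform(0, np.pi)
        m = _superellipse_mask(H, W, cy, cx, a_half, b_half, angle,
                               style["exponent"])
        if not spec.overlap_allowed:
            m &= mask == 0
        if not m.any():
            # fully occluded or off-image draw; keep rng stream aligned
            _ = rng.standard_normal((H, W))
            continue
        tex = 0.08 * _smooth_noise(rng, (H, W), sigma=style["tex_sigma"])
        color = np.asarray(style["color"])
        img[m] = np.clip(color[None, :] * (1.0 + tex[m][:, None]), 0, 1)
        mask[m] = cls
        inst[m] = inst_id

    # multiplicative illumination: directional gradient + global brightness
    theta = dom.illum_direction + rng.uniform(-0.5, 0.5)
    yy, xx = np.mgrid[0:H, 0:W]
    proj = (np.cos(theta) * (xx / W - 0.5) + np.sin(theta) * (yy / H - 0.5))
    illum = 1.0 + 2.0 * dom.illum_amplitude * proj
    scale = 1.0 + dom.brightness_jitter * rng.uniform(-1.0, 1.0)
    img *= scale * illum[:, :, None]

    img += 0.01 * rng.standard_normal((H, W, 3))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SyntheticSample(image=img, mask=mask, instance_ids=inst,
                           domain="field" if dom.delta > 0 else "lab")


def _per_class_pixel_counts(mask: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(mask.ravel(), minlength=n_classes)[:n_classes]


def generate_dataset(spec: SceneSpec, dom_lab: DomainParams,
                     dom_field: DomainParams, n_lab: int, n_field: int,
                     seed: int, out_dir) -> pd.DataFrame:
    """Render and write a two-domain dataset; returns (and writes) the manifest.

    Laboratory images form the training split; field images are split 10%
    validation / 90% test. Images and masks are 8-bit PNGs; the manifest is a
    TSV with file paths, domain and split tags, and per-class pixel counts.
    """
    if n_lab < 1 or n_field < 1:
        raise ValueError("need at least one image per domain")
    out_dir = Path(out_dir)
    try:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise ValueError(f"cannot create output directory {out_dir}: {e}") from e

    rng = np.random.default_rng(seed)
    rows = []
    n_val = max(1, round(0.1 * n_field))
    for domain, dom, n in (("lab", dom_lab, n_lab), ("field", dom_field, n_field)):
        for i in range(n):
            sample = generate_scene(spec, dom, rng)
            img_rel = f"images/{domain}_{i:04d}.png"
            mask_rel = f"masks/{domain}_{i:04d}.png"
            imwrite(out_dir / img_rel,
                    (sample.image * 255).round().astype(np.uint8))
            imwrite(out_dir / mask_rel, sample.mask)
            if domain == "lab":
                split = "train"
            else:
                split = "val" if i < n_val else "test"
            counts = _per_class_pixel_counts(sample.mask, spec.n_classes)
            rows.append({"image": img_rel, "mask": mask_rel, "domain": domain,
                         "split": split,
                         **{f"n_px_{c}": int(counts[c])
                            for c in range(spec.n_classes)}})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    cm = spec.class_map()
    with open(out_dir / "classes.json", "w") as fh:
        json.dump({"names": cm.names, "roles": cm.roles}, fh, indent=2)
    return manifest


def domain_gap_probe(images_a, images_b) -> float:
    """Energy distance between per-image channel-moment summaries of two sets.

    Each image is summarized by (mean_R, mean_G, mean_B, std_R, std_G, std_B);
    the energy distance 2 E d(X,Y) - E d(X,X') - E d(Y,Y') between the two
    summary clouds is returned. Zero for identical sets, symmetric, and grows
    with the domain shift magnitude.
    """
    feats = []
    for images in (images_a, images_b):
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[0] == 0:
            raise ValueError("each dataset must be a nonempty (N, H, W, 3) array")
        f = np.concatenate([images.mean(axis=(1, 2)), images.std(axis=(1, 2))],
                           axis=1)
        feats.append(f)
    fa, fb = feats
    d_ab = cdist(fa, fb).mean()
    d_aa = cdist(fa, fa).mean()
    d_bb = cdist(fb, fb).mean()
    return float(2.0 * d_ab - d_aa - d_bb)
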