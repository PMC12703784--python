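"""Dataset reading/writing, LabelMe import, preprocessing, augmentation and
class-balanced sampling.

Masks are single-channel integer PNGs: 0 = background, 1..K-1 = classes,
255 = ignore. Coordinates are row-major with the origin at the top-left.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .metrics_eval import IGNORE, ClassMap

logger = logging.getLogger(__name__)

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "load_manifest",
    "read_sample",
    "write_sample",
    "import_labelme",
    "preprocess",
    "augment",
    "AugmentConfig",
    "stratified_batches",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


def load_manifest(dataset_dir) -> pd.DataFrame:
    """Read a dataset manifest TSV, verifying the referenced files exist."""
    dataset_dir = Path(dataset_dir)
    manifest = pd.read_csv(dataset_dir / "manifest.tsv", sep="\t")
    for col in ("image", "mask", "domain", "split"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    for rel in pd.concat([manifest["image"], manifest["mask"]]):
        if not (dataset_dir / rel).exists():
            raise FileNotFoundError(f"manifest references missing file {rel}")
    return manifest


def read_sample(record, root, n_classes: int | None = None):
    """Load one (image, mask) pair: float RGB in [0,1] plus integer mask."""
    root = Path(root)
    img_path, mask_path = root / record["image"], root / record["mask"]
    with Image.open(img_path) as im:
        if im.mode == "RGBA":
            logger.warning("dropping alpha channel of %s", img_path)
            im = im.convert("RGB")
        elif im.mode != "RGB":
            im = im.convert("RGB")
        image = np.asarray(im, dtype=np.float32) / 255.0
    with Image.open(mask_path) as mm:
        if mm.mode not in ("L", "P", "I", "I;16"):
            raise ValueError(f"mask {mask_path} is not single-channel")
        mask = np.asarray(mm.convert("I")).astype(np.int64)
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"dimension mismatch for {img_path}: image {image.shape[:2]}, "
            f"mask {mask.shape}")
    if n_classes is not None:
        bad = (mask >= n_classes) & (mask != IGNORE)
        if bad.any():
            raise ValueError(
                f"mask {mask_path} contains unknown label id "
                f"{int(mask[bad][0])} (n_classes={n_classes})")
    return image, mask.astype(np.uint8)


def write_sample(image, mask, img_path, mask_path) -> None:
    """Write an image/mask pair as 8-bit PNGs (lossless for masks)."""
    img8 = (np.clip(np.asarray(image), 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(img8).save(img_path)
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(mask_path)


def import_labelme(json_doc: dict, class_map: ClassMap, image_size) -> np.ndarray:
    """Rasterize LabelMe polygons into a label mask.

    Polygons are filled in listed order (later polygons overwrite earlier
    ones). A pixel (row r, col c) belongs to a polygon when its center
    (c + 0.5, r + 0.5) lies inside or on the polygon boundary.
    """
    H, W = image_size
    mask = np.zeros((H, W), dtype=np.uint8)
    name_to_id = {n: i for i, n in enumerate(class_map.names)}
    yy, xx = np.mgrid[0:H, 0:W]
    cx = (xx + 0.5).ravel()
    cy = (yy + 0.5).ravel()
    for shape in json_doc.get("shapes", []):
        label = shape["label"]
        if label not in name_to_id:
            raise ValueError(f"unknown class name {label!r} in LabelMe document")
        poly = Polygon([(float(x), float(y)) for x, y in shape["points"]])
        inside = shapely.intersects_xy(poly, cx, cy).reshape(H, W)
        mask[inside] = name_to_id[label]
    return mask


def _resize_mask_nearest(mask: np.ndarray, size) -> np.ndarray:
    """Nearest-neighbour mask resize via exact index mapping (no new labels)."""
    H, W = mask.shape
    Ho, Wo = size
    rows = np.minimum((np.arange(Ho) + 0.5) * H / Ho, H - 1).astype(int)
    cols = np.minimum((np.arange(Wo) + 0.5) * W / Wo, W - 1).astype(int)
    return mask[np.ix_(rows, cols)]


def preprocess(image, mask, size=None, normalize: bool = True):
    """Resize (bilinear image / nearest mask) and standardize with ImageNet stats."""
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if size is not None and tuple(size) != image.shape[:2]:
        image = _sk_resize(image, size, order=1, preserve_range=True,
                           anti_aliasing=False).astype(np.float32)
        mask = _resize_mask_nearest(mask, size)
    if normalize:
        image = (image - IMAGENET_MEAN) / IMAGENET_STD
    return image, mask


class AugmentConfig:
    """Default augmentation: flip p=0.5, rotation +-15 deg, color jitter
    (brightness 0.2, contrast 0.2, saturation 0.2, hue 0.1)."""

    def __init__(self, flip_prob: float = 0.5, max_rotation: float = 15.0,
                 brightness: float = 0.2, contrast: float = 0.2,
                 saturation: float = 0.2, hue: float = 0.1):
        self.flip_prob = flip_prob
        self.max_rotation = max_rotation
        self.brightness = brightness
        self.contrast = contrast
        self.saturation = saturation
        self.hue = hue


def augment(image, mask, rng: np.random.Generator,
            config: AugmentConfig | None = None):
    """Random flip / rotation / color jitter; geometry shared with the mask.

    Rotation-exposed corners get ignore (255) in the mask and black in the
    image. Photometric jitter touches the image only.
    """
    if config is None:
        config = AugmentConfig()
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask, dtype=np.uint8)

    if rng.uniform() < config.flip_prob:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    angle = rng.uniform(-config.max_rotation, config.max_rotation)
    if config.max_rotation > 0:
        image = _sk_rotate(image, angle, resize=False, order=1,
                           mode="constant", cval=0.0,
                           preserve_range=True).astype(np.float32)
        mask = _sk_rotate(mask.astype(np.float32), angle, resize=False,
                          order=0, mode="constant", cval=float(IGNORE),
                          preserve_range=True).round().astype(np.uint8)

    if config.brightness > 0:
        image = image * rng.uniform(1 - config.brightness, 1 + config.brightness)
    if config.contrast > 0:
        gray = image.mean()
        image = (image - gray) * rng.uniform(1 - config.contrast,
                                             1 + config.contrast) + gray
    image = np.clip(image, 0, 1)
    if config.saturation > 0 or config.hue > 0:
        hsv = rgb2hsv(image)
        if config.saturation > 0:
            hsv[..., 1] = np.clip(
                hsv[..., 1] * rng.uniform(1 - config.saturation,
                                          1 + config.saturation), 0, 1)
        if config.hue > 0:
            hsv[..., 0] = (hsv[..., 0] + rng.uniform(-config.hue, config.hue)) % 1.0
        image = hsv2rgb(hsv).astype(np.float32)
    return np.clip(image, 0, 1), mask


def _presence_from_manifest(manifest: pd.DataFrame) -> np.ndarray:
    """(N, n_fg) boolean presence of each foreground class, from n_px columns."""
    px_cols = sorted([c for c in manifest.columns if c.startswith("n_px_")],
                     key=lambda c: int(c.split("_")[-1]))
    if not px_cols:
        raise ValueError("manifest has no n_px_<class> columns")
    counts = manifest[px_cols].to_numpy()
    return counts[:, 1:] > 0  # skip background


def stratified_batches(manifest: pd.DataFrame, batch_size: int,
                       rng: np.random.Generator, presence=None):
    """Infinite iterator of index batches with class-presence-balanced sampling.

    Each image is weighted by the mean inverse frequency of the foreground
    classes it contains, so rare-class images are oversampled. Every epoch
    consists of weighted draws plus a coverage top-up that guarantees each
    image appears at least once per epoch.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    if presence is None:
        presence = _presence_from_manifest(manifest)
    presence = np.asarray(presence, dtype=bool)
    n = len(manifest)
    freq = presence.mean(axis=0)
    inv = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-12), 0.0)
    weights = np.array([
        inv[row].mean() if row.any() else (inv[freq > 0].mean() if (freq > 0).any() else 1.0)
        for row in presence])
    if weights.sum() == 0:
        weights = np.ones(n)
    probs = weights / weights.sum()

    def gen():
        buffer = []
        while True:
            drawn = rng.choice(n, size=n, replace=True, p=probs)
            missing = np.setdiff1d(np.arange(n), drawn)
            epoch = np.concatenate([drawn, missing])
            rng.shuffle(epoch)
            buffer.extend(epoch.tolist())
            while len(buffer) >= batch_size:
                yield np.array(buffer[:batch_size])
                buffer = buffer[batch_size:]

    return gen()
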