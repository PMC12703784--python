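"""Dataset I/O, LabelMe rasterization, preprocessing, augmentation, sampling."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from swisseg.data_io import (
    IMAGENET_MEAN,
    AugmentConfig,
    augment,
    import_labelme,
    preprocess,
    read_sample,
    stratified_batches,
    write_sample,
)
from swisseg.metrics_eval import IGNORE, ClassMap


@pytest.fixture
def pair(rng):
    image = rng.random((16, 16, 3)).astype(np.float32)
    mask = rng.integers(0, 4, (16, 16)).astype(np.uint8)
    return image, mask


def _write_pair(tmp_path, image, mask):
    write_sample(image, mask, tmp_path / "img.png", tmp_path / "mask.png")
    return {"image": "img.png", "mask": "mask.png"}


def test_write_read_roundtrip_mask_lossless(tmp_path, pair):
    image, mask = pair
    rec = _write_pair(tmp_path, image, mask)
    image2, mask2 = read_sample(rec, tmp_path, n_classes=4)
    np.testing.assert_array_equal(mask2, mask)
    np.testing.assert_allclose(image2, image, atol=1 / 255 + 1e-6)


def test_rgba_alpha_dropped_with_warning(tmp_path, pair, caplog):
    image, mask = pair
    rgba = np.concatenate([(image * 255).astype(np.uint8),
                           np.full((16, 16, 1), 128, np.uint8)], axis=2)
    Image.fromarray(rgba, mode="RGBA").save(tmp_path / "img.png")
    Image.fromarray(mask, mode="L").save(tmp_path / "mask.png")
    with caplog.at_level("WARNING"):
        image2, _ = read_sample({"image": "img.png", "mask": "mask.png"}, tmp_path)
    assert image2.shape == (16, 16, 3)
    assert any("alpha" in r.message for r in caplog.records)


def test_unknown_label_id_rejected(tmp_path, pair):
    image, mask = pair
    mask = mask.copy()
    mask[0, 0] = 7  # beyond n_classes, not ignore
    rec = _write_pair(tmp_path, image, mask)
    with pytest.raises(ValueError, match="mask.png"):
        read_sample(rec, tmp_path, n_classes=4)


def test_dimension_mismatch_rejected(tmp_path, rng):
    write_sample(rng.random((16, 16, 3)), np.zeros((8, 8), np.uint8),
                 tmp_path / "img.png", tmp_path / "mask.png")
    with pytest.raises(ValueError, match="mismatch"):
        read_sample({"image": "img.png", "mask": "mask.png"}, tmp_path)


CM = ClassMap.default(n_weeds=2)


def test_labelme_square_polygon():
    doc = {"shapes": [{"label": "weed_1",
                       "points": [[0, 0], [10, 0], [10, 10], [0, 10]]}]}
    mask = import_labelme(doc, CM, (16, 16))
    assert (mask == 2).sum() == 100
    assert mask[:10, :10].min() == 2 and mask[10:, :].max() == 0


def test_labelme_point_in_polygon_loop_oracle():
    tri = [[1.0, 1.0], [11.0, 2.0], [4.0, 12.0]]
    doc = {"shapes": [{"label": "crop", "points": tri}]}
    mask = import_labelme(doc, CM, (14, 14))

    def inside(px, py):
        # ray casting with boundary tolerance
        n, cnt = len(tri), 0
        on_edge = False
        for i in range(n):
            x1, y1 = tri[i]
            x2, y2 = tri[(i + 1) % n]
            cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
            if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 \
                    and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
                on_edge = True
            if (y1 > py) != (y2 > py):
                x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                if px < x_int:
                    cnt += 1
        return on_edge or cnt % 2 == 1

    for r in range(14):
        for c in range(14):
            assert (mask[r, c] == 1) == inside(c + 0.5, r + 0.5), (r, c)


def test_labelme_empty_overlap_and_unknown():
    assert import_labelme({"shapes": []}, CM, (8, 8)).max() == 0
    doc = {"shapes": [
        {"label": "crop", "points": [[0, 0], [8, 0], [8, 8], [0, 8]]},
        {"label": "weed_2", "points": [[2, 2], [6, 2], [6, 6], [2, 6]]},
    ]}
    mask = import_labelme(doc, CM, (8, 8))
    assert mask[4, 4] == 3  # later polygon wins
    assert mask[0, 0] == 1
    with pytest.raises(ValueError):
        import_labelme({"shapes": [{"label": "dandelion", "points": [[0, 0], [1, 0], [1, 1]]}]},
                       CM, (4, 4))


def test_preprocess_contracts(rng):
    image = rng.random((32, 24, 3)).astype(np.float32)
    mask = rng.integers(0, 4, (32, 24)).astype(np.uint8)
    img2, mask2 = preprocess(image, mask, size=(16, 12), normalize=False)
    assert img2.shape == (16, 12, 3) and mask2.shape == (16, 12)
    assert set(np.unique(mask2)) <= set(np.unique(mask))  # nearest: no new ids

    const = np.broadcast_to(IMAGENET_MEAN, (8, 8, 3)).astype(np.float32)
    norm, _ = preprocess(const, np.zeros((8, 8), np.uint8))
    np.testing.assert_allclose(norm, 0.0, atol=1e-6)

    same, same_mask = preprocess(image, mask, size=(32, 24), normalize=False)
    np.testing.assert_array_equal(same, image)
    np.testing.assert_array_equal(same_mask, mask)


def test_flip_is_involution(rng, pair):
    image, mask = pair
    cfg = AugmentConfig(flip_prob=1.0, max_rotation=0, brightness=0,
                        contrast=0, saturation=0, hue=0)
    r = np.random.default_rng(0)
    once = augment(image, mask, r, cfg)
    twice = augment(*once, r, cfg)
    np.testing.assert_allclose(twice[0], image, atol=1e-6)
    np.testing.assert_array_equal(twice[1], mask)


def test_flip_frequency_matches_half(rng):
    cfg = AugmentConfig(flip_prob=0.5, max_rotation=0, brightness=0,
                        contrast=0, saturation=0, hue=0)
    img = np.zeros((2, 2, 3), np.float32)
    img[0, 0, 0] = 1.0
    mask = np.zeros((2, 2), np.uint8)
    n = 10_000
    flips = sum(augment(img, mask, rng, cfg)[0][0, 0, 0] == 0.0
                for _ in range(n))
    se = np.sqrt(0.25 / n)
    assert abs(flips / n - 0.5) < 3 * se


def test_augment_labels_subset_and_ignore_fill(rng, pair):
    image, mask = pair
    for _ in range(5):
        _, m2 = augment(image, mask, rng)
        assert set(np.unique(m2)) <= set(np.unique(mask)) | {IGNORE}
    # a large rotation must expose ignore-filled corners
    cfg = AugmentConfig(flip_prob=0, max_rotation=15, brightness=0,
                        contrast=0, saturation=0, hue=0)
    seen_ignore = False
    r = np.random.default_rng(1)
    for _ in range(10):
        _, m2 = augment(image, mask, r, cfg)
        seen_ignore |= (m2 == IGNORE).any()
    assert seen_ignore


def _manifest_with_presence(presence):
    n = len(presence)
    df = pd.DataFrame({"i": range(n)})
    return df, np.asarray(presence, dtype=bool)


def test_stratified_single_class_uniform(rng):
    df, presence = _manifest_with_presence([[True]] * 40)
    it = stratified_batches(df, 8, rng, presence=presence)
    counts = np.zeros(40)
    for _ in range(100):
        counts[next(it)] += 1
    # uniform sampling: counts concentrate around the mean
    assert counts.min() > 0
    assert counts.std() / counts.mean() < 0.5


def test_stratified_oversamples_minority_class(rng):
    # 36 images with only class A, 4 with only class B (9:1)
    presence = [[True, False]] * 36 + [[False, True]] * 4
    df, presence = _manifest_with_presence(presence)
    it = stratified_batches(df, 8, rng, presence=presence)
    minority_presence = 0
    for _ in range(200):
        idx = next(it)
        minority_presence += (idx >= 36).any()
    # raw per-batch presence probability of B is 1-(0.9)^8 ~ 0.57; balanced
    # sampling should push it well above that
    assert minority_presence / 200 > 0.75


def test_stratified_epoch_coverage_and_determinism():
    presence = [[True, False]] * 9 + [[False, True]] * 1
    df, presence = _manifest_with_presence(presence)
    it1 = stratified_batches(df, 5, np.random.default_rng(3), presence=presence)
    it2 = stratified_batches(df, 5, np.random.default_rng(3), presence=presence)
    seen = set()
    for _ in range(4):  # two epochs' worth of draws
        b1, b2 = next(it1), next(it2)
        np.testing.assert_array_equal(b1, b2)
        seen.update(b1.tolist())
    assert seen == set(range(10))

    with pytest.raises(ValueError):
        stratified_batches(pd.DataFrame(), 4, np.random.default_rng(0))
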