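"""Determinism, label fidelity and domain-shift control of the scene simulator."""

import hashlib

import numpy as np
import pytest
from scipy.stats import ks_2samp

from swisseg.swis_pipeline import load_benchmark
from swisseg.synthetic_scenes import (
    DomainParams,
    SceneSpec,
    domain_gap_probe,
    generate_dataset,
    generate_scene,
)


def test_same_seed_bit_identical():
    spec = SceneSpec()
    a = generate_scene(spec, DomainParams.field(1.0), np.random.default_rng(5))
    b = generate_scene(spec, DomainParams.field(1.0), np.random.default_rng(5))
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)
    assert np.array_equal(a.instance_ids, b.instance_ids)


def test_zero_delta_field_matches_lab_distribution():
    """delta=0 field parameters reproduce the laboratory background exactly."""
    spec = SceneSpec()
    lab_px, field_px = [], []
    rng_a, rng_b = np.random.default_rng(11), np.random.default_rng(12)
    for _ in range(50):
        sa = generate_scene(spec, DomainParams.lab(), rng_a)
        sb = generate_scene(spec, DomainParams.field(0.0), rng_b)
        lab_px.append(sa.image[sa.mask == 0].mean(axis=1))
        field_px.append(sb.image[sb.mask == 0].mean(axis=1))
    lab_px = np.concatenate(lab_px)[::37]
    field_px = np.concatenate(field_px)[::37]
    assert ks_2samp(lab_px, field_px).pvalue > 0.01


def test_mask_labels_have_rendered_instances():
    spec = SceneSpec()
    rng = np.random.default_rng(3)
    for _ in range(10):
        s = generate_scene(spec, DomainParams.field(1.0), rng)
        # every labeled pixel belongs to exactly one instance and vice versa
        assert np.array_equal(s.mask > 0, s.instance_ids > 0)
        for inst in np.unique(s.instance_ids[s.instance_ids > 0]):
            labels = np.unique(s.mask[s.instance_ids == inst])
            assert len(labels) == 1 and labels[0] > 0


def test_objects_rendered_where_labeled(rng):
    """Image statistics inside labeled regions differ from the background."""
    spec = SceneSpec()
    diffs = []
    for _ in range(10):
        s = generate_scene(spec, DomainParams.lab(), rng)
        if (s.mask > 0).sum() < 50:
            continue
        inside = s.image[s.mask > 0].mean(axis=0)
        outside = s.image[s.mask == 0].mean(axis=0)
        diffs.append(np.abs(inside - outside).max())
    assert np.mean(diffs) > 0.05


def test_impossible_spec_rejected():
    with pytest.raises(ValueError):
        SceneSpec(image_size=(16, 16), instance_size_range=(8, 32))
    with pytest.raises(ValueError):
        SceneSpec(n_classes=2)


def test_class_frequency_weights_reproduced(rng):
    """Requested foreground class frequencies hold within binomial error."""
    spec = SceneSpec(class_weights=(0.6, 0.3, 0.1), plants_per_image=(5, 5))
    counts = np.zeros(3)
    total = 0
    for _ in range(120):
        s = generate_scene(spec, DomainParams.lab(), rng)
        for inst in np.unique(s.instance_ids[s.instance_ids > 0]):
            cls = s.mask[s.instance_ids == inst][0]
            counts[cls - 1] += 1
            total += 1
    freq = counts / total
    for f_obs, f_exp in zip(freq, (0.6, 0.3, 0.1)):
        se = np.sqrt(f_exp * (1 - f_exp) / total)
        assert abs(f_obs - f_exp) < 4 * se


def test_dataset_counts_and_split(tmp_path):
    m = generate_dataset(SceneSpec(), DomainParams.lab(), DomainParams.field(1.0),
                         n_lab=10, n_field=10, seed=0, out_dir=tmp_path)
    lab = m[m.domain == "lab"]
    assert len(lab) == 10 and (lab.split == "train").all()
    field = m[m.domain == "field"]
    assert (field.split == "val").sum() == 1  # 10% of 10
    assert (field.split == "test").sum() == 9
    with pytest.raises(ValueError):
        generate_dataset(SceneSpec(), DomainParams.lab(), DomainParams.field(),
                         n_lab=0, n_field=1, seed=0, out_dir=tmp_path)


def test_manifest_pixel_counts_match_disk_recount(tmp_path):
    from swisseg.data_io import read_sample

    m = generate_dataset(SceneSpec(), DomainParams.lab(), DomainParams.field(1.0),
                         n_lab=4, n_field=4, seed=1, out_dir=tmp_path)
    for _, rec in m.iterrows():
        _, mask = read_sample(rec, tmp_path, n_classes=4)
        for c in range(4):
            assert rec[f"n_px_{c}"] == int((mask == c).sum())


def test_same_seed_identical_datasets_on_disk(tmp_path):
    args = (SceneSpec(), DomainParams.lab(), DomainParams.field(1.0), 3, 3, 9)
    m1 = generate_dataset(*args, out_dir=tmp_path / "a")
    m2 = generate_dataset(*args, out_dir=tmp_path / "b")
    assert m1.drop(columns=["image", "mask"]).equals(
        m2.drop(columns=["image", "mask"]))
    for rel in list(m1["image"]) + list(m1["mask"]):
        h1 = hashlib.sha256((tmp_path / "a" / rel).read_bytes()).hexdigest()
        h2 = hashlib.sha256((tmp_path / "b" / rel).read_bytes()).hexdigest()
        assert h1 == h2


def test_domain_gap_probe_properties(rng):
    spec = SceneSpec(image_size=(32, 32), instance_size_range=(6, 14))

    def sample_set(dom, seed, n=12):
        r = np.random.default_rng(seed)
        return np.stack([generate_scene(spec, dom, r).image for _ in range(n)])

    lab = sample_set(DomainParams.lab(), 0)
    assert domain_gap_probe(lab, lab) == pytest.approx(0.0, abs=1e-9)

    field = sample_set(DomainParams.field(1.0), 1)
    g_ab = domain_gap_probe(lab, field)
    g_ba = domain_gap_probe(field, lab)
    assert g_ab == pytest.approx(g_ba, rel=1e-9)

    with pytest.raises(ValueError):
        domain_gap_probe(np.empty((0, 8, 8, 3)), lab)


def test_domain_gap_monotone_in_delta():
    """Larger shift magnitude gives a larger measured gap, seed-averaged."""
    spec = SceneSpec(image_size=(32, 32), instance_size_range=(6, 14))
    gaps = {0.5: [], 2.0: []}
    for seed in range(5):
        r = np.random.default_rng(seed)
        lab = np.stack([generate_scene(spec, DomainParams.lab(), r).image
                        for _ in range(10)])
        for delta in gaps:
            fld = np.stack([generate_scene(spec, DomainParams.field(delta), r).image
                            for _ in range(10)])
            gaps[delta].append(domain_gap_probe(lab, fld))
    assert np.mean(gaps[2.0]) > np.mean(gaps[0.5])


def test_load_benchmark_structure(tiny_data):
    assert tiny_data["train_images"].shape[0] == 20
    assert tiny_data["style_images"].shape[0] == 1
    assert tiny_data["test_images"].shape[0] == 9
    assert tiny_data["train_images"].dtype == np.float32
    assert tiny_data["class_map"].n_classes == 4
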