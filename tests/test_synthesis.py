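"""Paste operator: placement planning, compositing, occlusion, datasets."""

import numpy as np
import pytest

from conftest import solid_square
from weedsynth import fixtures as fx
from weedsynth.coco_io import decode_segmentation, write_coco
from weedsynth.synthesis import (
    Placement,
    SceneSpec,
    composite_scene,
    downscale_scene,
    generate_dataset,
    plan_random_placements,
    plan_row_placements,
)


def _spec(size=256, seed=1, **kw):
    return SceneSpec(background=fx.make_background(size, seed=seed), **kw)


# ----------------------------------------------------------- placements

def test_row_spacing_formula(rng):
    spec = _spec(size=2048, row_y=1000, jitter=0.0)
    plan = plan_row_placements(spec, 4, rng)
    assert [p.center_x for p in plan] == [410, 819, 1229, 1638]
    assert all(p.center_y == 1000 for p in plan)
    assert plan_row_placements(spec, 0, rng) == []


def test_row_jitter_is_bounded_and_perpendicular(rng):
    spec = _spec(row_y=100, jitter=12.0)
    ys = [p.center_y for p in plan_row_placements(spec, 50, rng)]
    assert all(abs(y - 100) <= 12 for y in ys)
    assert np.var(ys) <= 12**2 / 3 + 1  # uniform-jitter variance bound


def test_row_y_outside_image_raises():
    with pytest.raises(ValueError):
        _spec(size=128, row_y=500)


def test_random_placements_uniform_moments(rng):
    plan = plan_random_placements(2000, (0, 256, 0, 256), rng)
    xs = np.array([p.center_x for p in plan])
    ys = np.array([p.center_y for p in plan])
    se = 256 / np.sqrt(12 * 2000)
    assert abs(xs.mean() - 128) < 3 * se and abs(ys.mean() - 128) < 3 * se
    assert ys.var() == pytest.approx(256**2 / 12, rel=0.15)


def test_random_placements_deterministic():
    a = plan_random_placements(10, (0, 100, 0, 100), np.random.default_rng(5))
    b = plan_random_placements(10, (0, 100, 0, 100), np.random.default_rng(5))
    assert a == b
    assert plan_random_placements(0, (0, 1, 0, 1), np.random.default_rng(0)) == []


# ----------------------------------------------------------- compositing

def test_single_opaque_instance_bbox_and_area():
    spec = _spec(min_visible_px=1, min_visible_frac=0.0)
    inst = solid_square(40)
    scene = composite_scene(spec, [(inst, Placement("cotton", 128, 128))])
    assert len(scene.annotations) == 1
    ann = scene.annotations[0]
    assert ann.area == inst.footprint_area == 1600
    assert ann.bbox == [108.0, 108.0, 40.0, 40.0]
    assert ann.category_id == 1


def test_full_occlusion_drops_lower_instance():
    spec = _spec(min_visible_px=1, min_visible_frac=0.0)
    a, b = solid_square(20, label="MG"), solid_square(40, label="grass")
    scene = composite_scene(
        spec,
        [(a, Placement("MG", 128, 128, z_order=0)),
         (b, Placement("grass", 128, 128, z_order=1))],
    )
    assert len(scene.annotations) == 1
    assert scene.annotations[0].category_id == 3
    assert scene.annotations[0].area == 1600  # B unaffected by hidden A


def test_partial_occlusion_visible_masks_are_disjoint():
    spec = _spec(min_visible_px=1, min_visible_frac=0.0)
    a, b = solid_square(40, label="cotton"), solid_square(40, label="MG")
    scene = composite_scene(
        spec,
        [(a, Placement("cotton", 120, 120, z_order=0)),
         (b, Placement("MG", 140, 140, z_order=1))],
    )
    m0, m1 = (ann.visible_mask for ann in scene.annotations)
    assert not np.any(m0 & m1)
    assert np.count_nonzero(m1) == 1600        # top instance fully visible
    assert np.count_nonzero(m0) == 1600 - 400  # 20x20 overlap hidden


def test_scene_pixels_are_background_or_topmost_instance():
    spec = _spec(min_visible_px=1, min_visible_frac=0.0)
    placed = [
        (solid_square(30, color=(60, 150, 50), label="cotton"),
         Placement("cotton", 60, 60, z_order=0)),
        (solid_square(30, color=(20, 220, 20), label="MG"),
         Placement("MG", 75, 75, z_order=1)),
    ]
    scene = composite_scene(spec, placed)
    union = np.zeros(spec.background.shape[:2], dtype=bool)
    for ann in scene.annotations:
        assert np.all(scene.image[ann.visible_mask] != 0)
        union |= ann.visible_mask
    assert np.array_equal(scene.image[~union], spec.background[~union])


def test_default_scene_yields_four_annotations_per_category(small_pool):
    rng = np.random.default_rng(11)
    backgrounds = [fx.make_background(512, seed=2)]
    scenes, aset = generate_dataset(
        3, backgrounds, small_pool, rng, placement_strategy="row_oriented",
        jitter=20.0,
    )
    for scene in scenes:
        cats = [a.category_id for a in scene.annotations]
        # sparse 512-px scenes: occlusion drops are rare but possible
        assert len(cats) <= 12
    total = sum(len(s.annotations) for s in scenes)
    assert total >= 3 * 12 - 4


def test_dataset_ids_unique_and_shares_near_equal(small_pool):
    rng = np.random.default_rng(3)
    backgrounds = [fx.make_background(512, seed=k) for k in range(3)]
    # visible-area floor scaled with the test-bed scene scale (512 vs 2048)
    scenes, aset = generate_dataset(20, backgrounds, small_pool, rng,
                                    min_visible_px=3)
    img_ids = [im["id"] for im in aset.images]
    ann_ids = [a["id"] for a in aset.annotations]
    assert len(set(img_ids)) == 20 and len(set(ann_ids)) == len(ann_ids)
    counts = {c: 0 for c in (1, 2, 3)}
    for a in aset.annotations:
        counts[a["category_id"]] += 1
    for c in counts.values():
        assert abs(c / len(aset.annotations) - 1 / 3) < 0.02


def test_generation_is_deterministic_to_the_byte(small_pool, tmp_path):
    files = []
    for run in range(2):
        rng = np.random.default_rng(77)
        _, aset = generate_dataset(
            4, [fx.make_background(256, seed=0)], small_pool, rng,
            per_class_count={"cotton": 2, "MG": 2, "grass": 2},
            min_visible_px=10,
        )
        path = tmp_path / f"run{run}.json"
        write_coco(aset, path)
        files.append(path.read_bytes())
    assert files[0] == files[1]


def test_empty_pool_class_raises(small_pool, rng):
    with pytest.raises(ValueError):
        generate_dataset(
            1, [fx.make_background(256)], small_pool, rng,
            per_class_count={"cotton": 2, "ragweed": 1},
        )


def test_oversized_instance_is_downscaled_to_fit(rng):
    from weedsynth.augment import InstancePool

    pool = InstancePool({"cotton": [solid_square(300)]})
    scenes, aset = generate_dataset(
        1, [fx.make_background(128)], pool, rng,
        per_class_count={"cotton": 1}, placement_strategy="random",
        min_visible_px=10,
    )
    assert len(scenes[0].annotations) == 1
    bbox = scenes[0].annotations[0].bbox
    assert bbox[2] <= 128 and bbox[3] <= 128


def test_downscale_scene_reduces_by_factor(small_pool):
    rng = np.random.default_rng(5)
    scenes, _ = generate_dataset(
        1, [fx.make_background(256, seed=1)], small_pool, rng,
        min_visible_px=10,
    )
    small = downscale_scene(scenes[0], factor=4)
    assert small.image.shape[:2] == (64, 64)
    by_id = {a.annotation_id: a for a in scenes[0].annotations}
    assert small.annotations  # at least broadleaf instances survive the vote
    for little in small.annotations:
        big = by_id[little.annotation_id]
        # majority-vote oracle via block mean; thin blades may vanish, which
        # is why empty downscaled masks are dropped rather than kept
        expected = big.visible_mask.reshape(64, 4, 64, 4).mean(axis=(1, 3)) > 0.5
        assert np.array_equal(little.visible_mask, expected)
        assert little.area == int(expected.sum())
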