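"""Procedural test bed: soil backgrounds, plant-like cut-outs, ground-truthed
scenes, controlled fake detections, and area/biomass tables.

The generators stand in for field imagery that is not publicly deposited.
They exaggerate the colour separation between vegetation and soil so that
excess-green/Otsu segmentation is exact *by construction*: every plant
pixel's ExG exceeds every soil pixel's ExG. That isolates the geometry and
bookkeeping of downstream code from segmentation noise — and it means a
passing test says nothing about segmentation quality on real imagery.

Two silhouette archetypes are produced: ``broadleaf`` (overlapping
elliptical lobes; compact, bbox-filling — stands in for cotton and
morningglory) and ``grass_blade`` (thin curved blades; sparse in its
bbox — stands in for grass weeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .augment import InstancePool
from .clipper import PlantInstance
from .coco_io import AnnotationSet, decode_segmentation
from .evaluation import Detection
from .synthesis import Placement, SceneSpec, SyntheticScene, composite_scene

__all__ = [
    "FixtureSpec",
    "PerturbationSpec",
    "SOIL_BASE",
    "PLANT_GREEN",
    "make_background",
    "make_instance",
    "make_pool",
    "make_test_scene",
    "perturb_detections",
    "make_biomass_data",
    "make_area_pairs",
]

# soil base keeps 2g - r - b = -30; the red/blue swap noise below leaves
# both the ExG numerator and denominator unchanged, so soil ExG is exactly
# -30/315 at every pixel. Plant green keeps 2g - r - b = +190, ExG > 0.5.
SOIL_BASE = (140, 95, 80)
PLANT_GREEN = (60, 150, 50)
_SOIL_SWAP_NOISE = 25
_PLANT_LUMA_NOISE = 20


@dataclass
class FixtureSpec:
    """Recipe for one synthetic plant cut-out."""

    archetype: str = "broadleaf"
    size: int = 64
    lobe_count: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ("broadleaf", "grass_blade"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.size < 8:
            raise ValueError("instance size must be >= 8 px")


@dataclass
class PerturbationSpec:
    """Controlled degradation of ground truth into fake detections.

    ``drop_rate`` removes round(rate * n) ground truths per class;
    survivors become detections with scores in (0.75, 0.95), optionally
    jittered. ``spurious_rate`` adds that many random false positives per
    image with scores in (0.05, 0.25) — strictly below every true
    positive, so with jitter 0 the 11-point AP is analytically a function
    of the drop rate alone.
    """

    drop_rate: float = 0.0
    jitter: float = 0.0
    spurious_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_rate <= 1.0:
            raise ValueError("drop_rate must be in [0, 1]")
        if self.spurious_rate < 0 or self.jitter < 0:
            raise ValueError("rates must be non-negative")


def make_background(
    size: int | tuple[int, int] = 256,
    base_color: tuple[int, int, int] = SOIL_BASE,
    noise_scale: int = _SOIL_SWAP_NOISE,
    seed: int = 0,
) -> np.ndarray:
    """Brown-dominant textured soil image with *constant* negative ExG.

    Texture is an anti-correlated red/blue swap (r gains what b loses),
    which leaves both the excess-green numerator 2g - r - b and the sum
    r + g + b untouched: every soil pixel carries the identical ExG value,
    so per-image Otsu segmentation of a plant-free background raises the
    degenerate-input condition instead of thresholding pure noise, and in
    composed scenes the soil forms a single histogram spike strictly below
    every plant pixel.
    """
    if isinstance(size, int):
        size = (size, size)
    h, w = size
    if min(h, w) < 64:
        raise ValueError("background must be at least 64 px on a side")
    rng = np.random.default_rng(seed)
    swap = rng.integers(-noise_scale, noise_scale + 1, size=(h, w))
    img = np.empty((h, w, 3), dtype=np.int32)
    img[..., 0] = base_color[0] + swap
    img[..., 1] = base_color[1]
    img[..., 2] = base_color[2] - swap
    return np.clip(img, 0, 255).astype(np.uint8)


def _broadleaf_mask(size: int, lobes: int, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    c = size / 2
    for _ in range(lobes):
        theta = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0, size / 6)
        rr = c + dist * np.sin(theta)
        cc = c + dist * np.cos(theta)
        a = rng.uniform(size / 5, size / 3.2)
        b = rng.uniform(size / 7, size / 4.5)
        ys, xs = ellipse(rr, cc, a, b, shape=(size, size),
                         rotation=rng.uniform(0, np.pi))
        mask[ys, xs] = True
    return mask


def _grass_mask(size: int, blades: int, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    c = size / 2
    thick = max(1.0, size / 55)
    for _ in range(blades):
        theta = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.65, 0.98) * (size / 2 - 2)
        bend = rng.uniform(-0.8, 0.8)  # radians of curvature over the blade
        for t in np.linspace(0.0, 1.0, int(3 * length)):
            ang = theta + bend * t
            r = c + length * t * np.sin(ang)
            x = c + length * t * np.cos(ang)
            radius = max(1.0, thick * (1.0 - 0.6 * t))
            ys, xs = disk((r, x), radius, shape=(size, size))
            mask[ys, xs] = True
    return mask


def make_instance(spec: FixtureSpec) -> tuple[PlantInstance, np.ndarray]:
    """A plant-like RGBA cut-out plus its exact boolean footprint.

    Broadleaf silhouettes fill >= 40% of their tight bbox; grass blades
    fill <= 25% (checked by the construction's own tests, not enforced
    here). Plant pixels are green-dominant with luminance-only noise, so
    their ExG stays above 0.5.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.archetype == "broadleaf":
        mask = _broadleaf_mask(spec.size, spec.lobe_count, rng)
        label = "cotton"
    else:
        mask = _grass_mask(spec.size, max(3, spec.lobe_count // 2), rng)
        label = "grass"
    luma = rng.integers(-_PLANT_LUMA_NOISE, _PLANT_LUMA_NOISE + 1,
                        size=(spec.size, spec.size, 1))
    rgb = np.clip(np.array(PLANT_GREEN)[None, None, :] + luma, 0, 255).astype(np.uint8)
    rgba = np.dstack([rgb, np.where(mask, 255, 0).astype(np.uint8)])
    rgba[~mask] = 0
    # tight crop to the footprint
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    inst = PlantInstance(
        raster=np.ascontiguousarray(rgba[r0:r1, c0:c1]),
        class_label=label,
        source_id=f"fixture_{spec.archetype}_{spec.seed}",
        offset=(int(r0), int(c0)),
    )
    return inst, mask[r0:r1, c0:c1].copy()


def make_pool(
    ip_size: int = 10,
    size: int = 64,
    seed: int = 0,
    classes: tuple[str, ...] = ("cotton", "MG", "grass"),
) -> InstancePool:
    """Instance pool with ``ip_size`` cut-outs per class.

    Cotton and MG use the broadleaf archetype, grass the blade archetype;
    seeds are derived deterministically from the master seed.
    """
    pool = InstancePool()
    for ci, cls in enumerate(classes):
        arch = "grass_blade" if cls == "grass" else "broadleaf"
        for k in range(ip_size):
            inst, _ = make_instance(
                FixtureSpec(archetype=arch, size=size, seed=seed * 10_000 + ci * 1_000 + k)
            )
            inst.class_label = cls
            pool.add(inst)
    return pool


def make_test_scene(
    background: np.ndarray,
    instances: list[PlantInstance],
    centers: list[tuple[float, float]],
    image_id: int = 1,
    min_visible_px: int = 1,
) -> tuple[SyntheticScene, AnnotationSet]:
    """Composite instances at known centers and return exact ground truth.

    With binary alpha and integer placements the paste is bit-exact, so
    the returned annotation masks are the planted footprints (minus any
    deliberate overlap occlusion).
    """
    placed = [
        (inst, Placement(inst.class_label, cx, cy, z_order=i))
        for i, (inst, (cx, cy)) in enumerate(zip(instances, centers))
    ]
    spec = SceneSpec(
        background=background,
        placement_strategy="random",
        min_visible_px=min_visible_px,
        min_visible_frac=0.0,
    )
    scene = composite_scene(spec, placed, image_id=image_id)
    aset = AnnotationSet(
        images=[{
            "id": image_id, "file_name": f"fixture_{image_id:04d}.png",
            "height": spec.height, "width": spec.width,
        }],
        annotations=[a.to_coco() for a in scene.annotations],
    )
    return scene, aset


def _shift_mask(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def perturb_detections(gt: AnnotationSet, spec: PerturbationSpec) -> list[Detection]:
    """Degrade ground truth into a fake detection list with known structure.

    Exactly ``round(drop_rate * n)`` ground truths per class are dropped;
    the rest become detections (scores 0.75-0.95, optional pixel jitter).
    ``round(spurious_rate * n_images)`` spurious low-score boxes are
    appended per run. Fully deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = {im["id"]: (im["height"], im["width"]) for im in gt.images}
    by_class: dict[int, list[dict]] = {}
    for ann in gt.annotations:
        by_class.setdefault(ann["category_id"], []).append(ann)

    dets: list[Detection] = []
    for cat in sorted(by_class):
        anns = by_class[cat]
        n_drop = int(round(spec.drop_rate * len(anns)))
        dropped = set(rng.choice(len(anns), size=n_drop, replace=False).tolist())
        for j, ann in enumerate(anns):
            if j in dropped:
                continue
            bbox = list(ann["bbox"])
            seg = ann.get("segmentation")
            if spec.jitter > 0:
                dy = int(round(rng.normal(0, spec.jitter)))
                dx = int(round(rng.normal(0, spec.jitter)))
                bbox = [bbox[0] + dx, bbox[1] + dy, bbox[2], bbox[3]]
                if seg is not None:
                    h, w = sizes[ann["image_id"]]
                    from .coco_io import encode_rle

                    seg = encode_rle(_shift_mask(decode_segmentation(seg, h, w), dy, dx))
            dets.append(
                Detection(
                    image_id=ann["image_id"],
                    category_id=cat,
                    score=float(rng.uniform(0.75, 0.95)),
                    bbox=bbox,
                    segmentation=seg,
                )
            )
    n_spurious = int(round(spec.spurious_rate * len(gt.images)))
    cats = sorted(by_class) or [1]
    for _ in range(n_spurious):
        im = gt.images[int(rng.integers(len(gt.images)))]
        h, w = im["height"], im["width"]
        bw, bh = float(rng.uniform(4, w / 4)), float(rng.uniform(4, h / 4))
        dets.append(
            Detection(
                image_id=im["id"],
                category_id=int(rng.choice(cats)),
                score=float(rng.uniform(0.05, 0.25)),
                bbox=[float(rng.uniform(0, w - bw)), float(rng.uniform(0, h - bh)), bw, bh],
                segmentation=None,
            )
        )
    return dets


def make_biomass_data(
    n: int,
    beta: float = 0.01,
    target_r2: float = 0.66,
    rng: np.random.Generator | None = None,
    area_range: tuple[float, float] = (500.0, 5000.0),
) -> pd.DataFrame:
    """Area/biomass pairs with a linear-plus-noise structure.

    Biomass = beta * mask_area + N(0, sigma^2), truncated at 0, with
    sigma^2 = Var(beta * area) * (1 - R^2) / R^2 so the *design* R^2 of
    the fit equals ``target_r2`` in expectation.
    """
    rng = rng or np.random.default_rng(0)
    areas = rng.uniform(*area_range, size=n)
    signal_var = np.var(beta * areas)
    sigma = np.sqrt(signal_var * (1.0 - target_r2) / target_r2)
    biomass = np.maximum(0.0, beta * areas + rng.normal(0.0, sigma, size=n))
    return pd.DataFrame(
        {"plant_id": [f"p{i:04d}" for i in range(n)],
         "mask_area": areas, "dry_biomass_g": biomass}
    )


def make_area_pairs(
    n: int,
    beta: float = 0.01,
    target_r2: float = 0.66,
    rng: np.random.Generator | None = None,
    fill_range: tuple[float, float] = (0.10, 0.85),
) -> pd.DataFrame:
    """Paired mask/bbox areas where biomass tracks the mask area.

    The bbox inflates the mask area by a per-plant random fill factor,
    mimicking sprawling canopies whose boxes over-cover them erratically;
    a biomass fit on bbox area is therefore noisier than on mask area.
    """
    rng = rng or np.random.default_rng(0)
    df = make_biomass_data(n, beta=beta, target_r2=target_r2, rng=rng)
    fill = rng.uniform(*fill_range, size=n)
    df["bbox_area"] = df["mask_area"] / fill
    return df
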