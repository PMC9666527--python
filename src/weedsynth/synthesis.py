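"""Scene synthesis: placement planning, alpha compositing, annotation records.

A scene is composed by pasting modified plant cut-outs over a soil
background in ascending z-order (paste order). Each pasted instance is
annotated with its *visible* (post-occlusion) mask: its own opaque
footprint minus the union of all later-pasted footprints. Instances whose
visible area falls below a floor — 50 px or 10% of the footprint,
whichever is larger — are dropped from the annotations, since fully
hidden plants would be unlearnable ground truth.

Two placement strategies mirror field layouts: ``row_oriented`` lines the
crop (cotton) up along a planting row with perpendicular jitter, while
weeds scatter uniformly; ``random`` scatters every class uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import block_reduce

from .augment import (
    InstancePool,
    ModifierConfig,
    ModificationRecord,
    apply_random_modifications,
    sample_instance,
)
from .clipper import PlantInstance
from .coco_io import AnnotationSet, encode_rle, mask_to_bbox
from .imaging_core import full_scale, validate_raster

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_IDS",
    "SceneSpec",
    "Placement",
    "InstanceAnnotation",
    "SyntheticScene",
    "plan_row_placements",
    "plan_random_placements",
    "composite_scene",
    "generate_dataset",
    "downscale_scene",
]

#: fixed category table shared by every generated annotation set
CATEGORY_IDS = {"cotton": 1, "MG": 2, "grass": 3}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    ``per_class_count`` defaults to 4 instances for each of the three
    categories (cotton, MG, grass). ``row_y`` is the pixel row of the
    cotton planting line when ``placement_strategy`` is ``row_oriented``;
    ``jitter`` is the half-width of the uniform perpendicular offset.
    """

    background: np.ndarray
    per_class_count: dict[str, int] = field(
        default_factory=lambda: {"cotton": 4, "MG": 4, "grass": 4}
    )
    placement_strategy: str = "row_oriented"
    row_y: int | None = None
    jitter: float = 0.0
    min_visible_px: int = 50
    min_visible_frac: float = 0.10

    def __post_init__(self) -> None:
        self.background = validate_raster(self.background, min_channels=3)
        if self.placement_strategy not in ("row_oriented", "random"):
            raise ValueError(f"unknown placement strategy {self.placement_strategy!r}")
        if any(v < 0 for v in self.per_class_count.values()):
            raise ValueError("per_class_count values must be >= 0")
        h = self.background.shape[0]
        if self.row_y is None:
            self.row_y = h // 2
        if self.placement_strategy == "row_oriented" and not 0 <= self.row_y < h:
            raise ValueError(f"row_y={self.row_y} outside image of height {h}")

    @property
    def height(self) -> int:
        return self.background.shape[0]

    @property
    def width(self) -> int:
        return self.background.shape[1]


@dataclass
class Placement:
    """Where and in what paste rank an instance lands in the scene."""

    class_label: str
    center_x: float
    center_y: float
    z_order: int = 0


@dataclass
class InstanceAnnotation:
    """Per-instance ground truth: category, tight bbox of the visible mask,
    the visible mask itself, its pixel area, and provenance metadata."""

    annotation_id: int
    image_id: int
    category_id: int
    bbox: list[float]
    visible_mask: np.ndarray
    area: int
    modification: ModificationRecord | None = None
    source_instance_id: str = ""

    def to_coco(self) -> dict:
        rec = {
            "id": self.annotation_id,
            "image_id": self.image_id,
            "category_id": self.category_id,
            "bbox": self.bbox,
            "area": int(self.area),
            "segmentation": encode_rle(self.visible_mask),
            "iscrowd": 0,
            "source_instance_id": self.source_instance_id,
        }
        if self.modification is not None:
            rec["modification"] = {
                "angle": self.modification.angle,
                "scale": self.modification.scale,
                "hue_shift": self.modification.hue_shift,
                "sat_shift": self.modification.sat_shift,
            }
        return rec


@dataclass
class SyntheticScene:
    """A composited image plus the annotations that survived occlusion."""

    image: np.ndarray
    annotations: list[InstanceAnnotation]
    image_id: int = 1


def plan_row_placements(
    spec: SceneSpec, n: int, rng: np.random.Generator
) -> list[Placement]:
    """Evenly space *n* cotton centers along ``spec.row_y``.

    Centers sit at x = i * width / (n + 1) for i = 1..n, each offset
    perpendicular to the row by a uniform draw in [-jitter, +jitter].
    """
    if spec.placement_strategy != "row_oriented":
        raise ValueError("row placements require the row_oriented strategy")
    out = []
    spacing = spec.width / (n + 1)
    for i in range(n):
        dy = float(rng.uniform(-spec.jitter, spec.jitter)) if spec.jitter > 0 else 0.0
        y = float(np.clip(spec.row_y + dy, 0, spec.height - 1))
        out.append(Placement("cotton", round(spacing * (i + 1)), y, z_order=i))
    return out


def plan_random_placements(
    n: int,
    bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
    class_label: str = "unlabeled",
) -> list[Placement]:
    """*n* centers i.i.d. uniform over ``bounds = (x_lo, x_hi, y_lo, y_hi)``."""
    x_lo, x_hi, y_lo, y_hi = bounds
    return [
        Placement(
            class_label,
            float(rng.uniform(x_lo, x_hi)),
            float(rng.uniform(y_lo, y_hi)),
            z_order=i,
        )
        for i in range(n)
    ]


def _paste_footprint(
    canvas: np.ndarray, inst: PlantInstance, placement: Placement
) -> np.ndarray:
    """Alpha-composite *inst* onto float *canvas* in place; return the
    instance's opaque footprint in scene coordinates (clipped at edges)."""
    H, W = canvas.shape[:2]
    h, w = inst.height, inst.width
    top = int(round(placement.center_y)) - h // 2
    left = int(round(placement.center_x)) - w // 2
    r0, r1 = max(top, 0), min(top + h, H)
    c0, c1 = max(left, 0), min(left + w, W)
    scene_fp = np.zeros((H, W), dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return scene_fp
    ir0, ic0 = r0 - top, c0 - left
    patch = inst.raster[ir0 : ir0 + (r1 - r0), ic0 : ic0 + (c1 - c0)]
    scale = full_scale(inst.raster)
    alpha = patch[..., 3].astype(np.float64) / scale
    rgb = patch[..., :3].astype(np.float64)
    region = canvas[r0:r1, c0:c1]
    region[...] = rgb * alpha[..., None] + region * (1.0 - alpha[..., None])
    scene_fp[r0:r1, c0:c1] = patch[..., 3] > scale // 2
    return scene_fp


def composite_scene(
    spec: SceneSpec,
    placed: list[tuple[PlantInstance, Placement]],
    image_id: int = 1,
    first_annotation_id: int = 1,
    records: list[ModificationRecord] | None = None,
) -> SyntheticScene:
    """Composite placed instances over the background in ascending z-order
    and record one annotation per instance surviving occlusion.

    An instance's visible mask is its own footprint minus the union of
    higher-z footprints; annotations with visible area below
    ``max(min_visible_px, min_visible_frac * footprint)`` are dropped and
    bboxes are recomputed from the visible mask.
    """
    order = sorted(range(len(placed)), key=lambda i: placed[i][1].z_order)
    canvas = spec.background[..., :3].astype(np.float64)
    bg_scale = full_scale(spec.background)
    footprints: list[np.ndarray] = []
    for i in order:
        inst, plc = placed[i]
        footprints.append(_paste_footprint(canvas, inst, plc))

    image = np.clip(np.rint(canvas), 0, bg_scale).astype(spec.background.dtype)

    annotations: list[InstanceAnnotation] = []
    ann_id = first_annotation_id
    occluders = np.zeros((spec.height, spec.width), dtype=bool)
    # walk from topmost down, accumulating the union of higher-z footprints
    visibles: list[np.ndarray | None] = [None] * len(order)
    for k in range(len(order) - 1, -1, -1):
        visibles[k] = footprints[k] & ~occluders
        occluders |= footprints[k]
    for k, i in enumerate(order):
        inst, plc = placed[i]
        visible = visibles[k]
        area = int(np.count_nonzero(visible))
        floor = max(spec.min_visible_px, int(spec.min_visible_frac * inst.footprint_area))
        if area < floor:
            continue
        annotations.append(
            InstanceAnnotation(
                annotation_id=ann_id,
                image_id=image_id,
                category_id=CATEGORY_IDS.get(plc.class_label, 0) or _unknown(plc),
                bbox=mask_to_bbox(visible),
                visible_mask=visible,
                area=area,
                modification=records[i] if records is not None else None,
                source_instance_id=inst.source_id,
            )
        )
        ann_id += 1
    return SyntheticScene(image=image, annotations=annotations, image_id=image_id)


def _unknown(plc: Placement) -> int:
    raise ValueError(f"placement class {plc.class_label!r} has no category id")


def _fit_instance(inst: PlantInstance, H: int, W: int) -> PlantInstance:
    """Downscale an instance that outgrew the frame so it fits (logged)."""
    from .augment import scale_instance

    if inst.height < H and inst.width < W:
        return inst
    factor = 0.9 * min(H / inst.height, W / inst.width)
    logger.info(
        "instance %s (%dx%d) exceeds %dx%d frame; downscaling by %.3f",
        inst.source_id, inst.height, inst.width, H, W, factor,
    )
    return scale_instance(inst, factor)


def generate_dataset(
    n_images: int,
    backgrounds: list[np.ndarray],
    pool: InstancePool,
    rng: np.random.Generator,
    per_class_count: dict[str, int] | None = None,
    placement_strategy: str = "row_oriented",
    row_y: int | None = None,
    jitter: float = 0.0,
    modifier: ModifierConfig | None = None,
    min_visible_px: int = 50,
    min_visible_frac: float = 0.10,
    first_image_id: int = 1,
) -> tuple[list[SyntheticScene], AnnotationSet]:
    """Generate ``n_images`` scenes and one merged COCO-style set.

    Each scene draws instances from the pool with replacement, pushes them
    through the random modifier, plans placements (cotton along the row
    when ``row_oriented``, uniform otherwise; weeds always uniform), and
    composites them. Backgrounds are assigned round-robin starting from a
    random offset. Ids are unique across the dataset.
    """
    if not backgrounds:
        raise ValueError("at least one background is required")
    per_class_count = per_class_count or {"cotton": 4, "MG": 4, "grass": 4}
    for cls, cnt in per_class_count.items():
        if cnt > 0 and (cls not in pool.instances or not pool.instances[cls]):
            raise ValueError(f"pool has no instances for requested class {cls!r}")
    modifier = modifier or ModifierConfig()

    scenes: list[SyntheticScene] = []
    images_meta: list[dict] = []
    coco_anns: list[dict] = []
    bg_start = int(rng.integers(len(backgrounds)))
    ann_id = 1
    for j in range(n_images):
        bg = backgrounds[(bg_start + j) % len(backgrounds)]
        spec = SceneSpec(
            background=bg,
            per_class_count=dict(per_class_count),
            placement_strategy=placement_strategy,
            row_y=row_y,
            jitter=jitter,
            min_visible_px=min_visible_px,
            min_visible_frac=min_visible_frac,
        )
        H, W = spec.height, spec.width
        placed: list[tuple[PlantInstance, Placement]] = []
        records: list[ModificationRecord] = []

        def _modified(cls: str) -> tuple[PlantInstance, ModificationRecord]:
            inst, rec = apply_random_modifications(
                sample_instance(pool, cls, rng), modifier, rng
            )
            return _fit_instance(inst, H, W), rec

        z = 0
        n_cotton = per_class_count.get("cotton", 0)
        if placement_strategy == "row_oriented" and n_cotton > 0:
            row_plan = plan_row_placements(spec, n_cotton, rng)
            for plc in row_plan:
                inst, rec = _modified("cotton")
                plc.z_order = z
                placed.append((inst, plc))
                records.append(rec)
                z += 1
            random_classes = [c for c in per_class_count if c != "cotton"]
        else:
            random_classes = list(per_class_count)
        for cls in random_classes:
            for _ in range(per_class_count[cls]):
                inst, rec = _modified(cls)
                # whole plant inside the frame: center confined by half-extents
                x = float(rng.uniform(inst.width / 2, W - inst.width / 2))
                y = float(rng.uniform(inst.height / 2, H - inst.height / 2))
                placed.append((inst, Placement(cls, x, y, z_order=z)))
                records.append(rec)
                z += 1

        image_id = first_image_id + j
        scene = composite_scene(
            spec, placed, image_id=image_id, first_annotation_id=ann_id, records=records
        )
        ann_id += len(scene.annotations)
        scenes.append(scene)
        images_meta.append(
            {"id": image_id, "file_name": f"synthetic_{image_id:06d}.png",
             "height": H, "width": W}
        )
        coco_anns.extend(a.to_coco() for a in scene.annotations)

    aset = AnnotationSet(
        images=images_meta,
        annotations=coco_anns,
        categories=[{"id": v, "name": k} for k, v in CATEGORY_IDS.items()],
    )
    aset.validate()
    return scenes, aset


def downscale_scene(scene: SyntheticScene, factor: int = 4) -> SyntheticScene:
    """Reduce resolution by an integer factor (e.g. 2048 -> 512).

    The image is block-averaged (area-weighted); visible masks are reduced
    by majority vote within each block and bboxes/areas recomputed.
    """
    img = scene.image
    H, W = img.shape[:2]
    if H % factor or W % factor:
        raise ValueError(f"extent {H}x{W} not divisible by factor {factor}")
    small = block_reduce(img.astype(np.float64), (factor, factor, 1), np.mean)
    small = np.clip(np.rint(small), 0, full_scale(img)).astype(img.dtype)
    anns = []
    for a in scene.annotations:
        mask_small = block_reduce(
            a.visible_mask.astype(np.float64), (factor, factor), np.mean
        ) > 0.5
        area = int(np.count_nonzero(mask_small))
        if area == 0:
            continue
        anns.append(
            InstanceAnnotation(
                annotation_id=a.annotation_id,
                image_id=a.image_id,
                category_id=a.category_id,
                bbox=mask_to_bbox(mask_small),
                visible_mask=mask_small,
                area=area,
                modification=a.modification,
                source_instance_id=a.source_instance_id,
            )
        )
    return SyntheticScene(image=small, annotations=anns, image_id=scene.image_id)
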