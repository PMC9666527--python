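"""Instance pool and the random modifier: rotation, scaling, hue/sat jitter.

A modifier draw applies, in a fixed order, (1) rotation by a uniform random
angle in [0, 180] degrees, (2) uniform scaling by a factor in [0.6, 1.2],
and (3) a hue/saturation shift of 0-10% (hue: additive rotation of the hue
circle with random sign; saturation: multiplicative increase, clamped).
Geometric operations run first so colour jitter is never resampled.

Every draw is logged as a :class:`ModificationRecord`; replaying a record
through :func:`apply_modifications` reproduces the instance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize, rotate

from .clipper import PlantInstance, tight_crop
from .imaging_core import full_scale

__all__ = [
    "InstancePool",
    "ModifierConfig",
    "ModificationRecord",
    "sample_instance",
    "rotate_instance",
    "scale_instance",
    "shift_hue_saturation",
    "apply_random_modifications",
    "apply_modifications",
]


@dataclass
class ModifierConfig:
    """Ranges for the random modifier, as (low, high) tuples.

    ``hue_sat_shift_range`` is in percent: hue shifts by that fraction of
    the full hue circle (sign randomized per draw), saturation is scaled
    by ``1 + shift/100``.
    """

    rotation_range: tuple[float, float] = (0.0, 180.0)
    scale_range: tuple[float, float] = (0.6, 1.2)
    hue_sat_shift_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("rotation_range", "scale_range", "hue_sat_shift_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if self.scale_range[0] <= 0:
            raise ValueError("scale bounds must be > 0")


@dataclass
class ModificationRecord:
    """Logged parameters of one modifier draw (hue shift is signed)."""

    angle: float
    scale: float
    hue_shift: float
    sat_shift: float


@dataclass
class InstancePool:
    """Per-class lists of plant cut-outs from which scenes are composed.

    ``ip_size`` is the number of instances per class. Subsetting keeps the
    first k instances of each class, so pools built from a common master
    pool are nested.
    """

    instances: dict[str, list[PlantInstance]] = field(default_factory=dict)

    def add(self, inst: PlantInstance) -> None:
        self.instances.setdefault(inst.class_label, []).append(inst)

    @property
    def classes(self) -> list[str]:
        return list(self.instances)

    @property
    def ip_size(self) -> int:
        if not self.instances:
            return 0
        return min(len(v) for v in self.instances.values())

    def subset(self, ip_size: int) -> "InstancePool":
        if ip_size < 1:
            raise ValueError("ip_size must be >= 1")
        if ip_size > self.ip_size:
            raise ValueError(f"pool holds only {self.ip_size} instances per class")
        return InstancePool(
            {cls: lst[:ip_size] for cls, lst in self.instances.items()}
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self.instances.values())


def sample_instance(
    pool: InstancePool, class_label: str, rng: np.random.Generator
) -> PlantInstance:
    """Uniform draw with replacement from one class of the pool."""
    if class_label not in pool.instances or not pool.instances[class_label]:
        raise ValueError(f"class {class_label!r} not present in pool")
    lst = pool.instances[class_label]
    return lst[int(rng.integers(len(lst)))]


def _to_float(raster: np.ndarray) -> tuple[np.ndarray, int]:
    scale = full_scale(raster)
    return raster.astype(np.float64) / scale, scale


def _from_float(arr: np.ndarray, scale: int, dtype: np.dtype) -> np.ndarray:
    return np.clip(np.rint(arr * scale), 0, scale).astype(dtype)


def _premultiply(rgba: np.ndarray) -> np.ndarray:
    out = rgba.copy()
    out[..., :3] *= rgba[..., 3:4]
    return out


def _unpremultiply(rgba: np.ndarray) -> np.ndarray:
    out = rgba.copy()
    alpha = rgba[..., 3:4]
    safe = np.where(alpha > 1e-6, alpha, 1.0)
    out[..., :3] = np.where(alpha > 1e-6, rgba[..., :3] / safe, 0.0)
    return out


def _retighten(rgba: np.ndarray, inst: PlantInstance) -> PlantInstance:
    crop, _ = tight_crop(rgba)
    return PlantInstance(
        raster=crop,
        class_label=inst.class_label,
        source_id=inst.source_id,
        offset=inst.offset,
    )


def rotate_instance(inst: PlantInstance, angle: float) -> PlantInstance:
    """Rotate counter-clockwise by *angle* degrees, expanding the canvas.

    Exact multiples of 90 degrees are grid permutations (no resampling, so
    the footprint area is preserved exactly); other angles use bilinear
    resampling on alpha-premultiplied colour, and the result is
    re-tight-cropped.
    """
    angle = float(angle) % 360.0
    if angle == 0.0:
        return inst
    if angle % 90.0 == 0.0:
        rotated = np.rot90(inst.raster, k=int(angle // 90))
        return PlantInstance(
            raster=np.ascontiguousarray(rotated),
            class_label=inst.class_label,
            source_id=inst.source_id,
            offset=inst.offset,
        )
    fimg, scale = _to_float(inst.raster)
    pre = _premultiply(fimg)
    rot = rotate(pre, angle, resize=True, order=1, mode="constant", cval=0.0)
    out = _from_float(_unpremultiply(rot), scale, inst.raster.dtype)
    return _retighten(out, inst)


def scale_instance(inst: PlantInstance, factor: float) -> PlantInstance:
    """Resize by *factor*; the alpha footprint scales roughly as factor^2."""
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    if factor == 1.0:
        return inst
    new_h = int(round(inst.height * factor))
    new_w = int(round(inst.width * factor))
    if new_h < 1 or new_w < 1:
        raise ValueError(
            f"scaling {inst.height}x{inst.width} by {factor} collapses below 1 px"
        )
    fimg, scale = _to_float(inst.raster)
    pre = _premultiply(fimg)
    res = resize(pre, (new_h, new_w), order=1, anti_aliasing=factor < 1.0)
    out = _from_float(_unpremultiply(res), scale, inst.raster.dtype)
    return _retighten(out, inst)


def shift_hue_saturation(
    inst: PlantInstance, hue_shift: float, sat_shift: float
) -> PlantInstance:
    """Rotate hue by ``hue_shift`` percent of the hue circle (wraparound)
    and scale saturation by ``1 + sat_shift/100`` (clamped to full scale).

    The value channel and the alpha channel are untouched.
    """
    if hue_shift == 0.0 and sat_shift == 0.0:
        return inst
    fimg, scale = _to_float(inst.raster)
    hsv = rgb2hsv(fimg[..., :3])
    hsv[..., 0] = (hsv[..., 0] + hue_shift / 100.0) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + sat_shift / 100.0), 0.0, 1.0)
    rgb = hsv2rgb(hsv)
    out = inst.raster.copy()
    out[..., :3] = _from_float(rgb, scale, inst.raster.dtype)
    return PlantInstance(
        raster=out,
        class_label=inst.class_label,
        source_id=inst.source_id,
        offset=inst.offset,
    )


def apply_modifications(inst: PlantInstance, record: ModificationRecord) -> PlantInstance:
    """Replay a logged draw: rotate, then scale, then hue/saturation."""
    out = rotate_instance(inst, record.angle)
    out = scale_instance(out, record.scale)
    return shift_hue_saturation(out, record.hue_shift, record.sat_shift)


def apply_random_modifications(
    inst: PlantInstance, config: ModifierConfig, rng: np.random.Generator
) -> tuple[PlantInstance, ModificationRecord]:
    """Draw angle, scale, hue and saturation shifts independently and apply
    them in the fixed order rotate -> scale -> hue/sat.

    The hue shift's sign is randomized; its magnitude and every other
    value are uniform over the configured ranges.
    """
    angle = float(rng.uniform(*config.rotation_range))
    scale = float(rng.uniform(*config.scale_range))
    hue_mag = float(rng.uniform(*config.hue_sat_shift_range))
    hue_sign = 1.0 if rng.random() < 0.5 else -1.0
    sat = float(rng.uniform(*config.hue_sat_shift_range))
    record = ModificationRecord(
        angle=angle, scale=scale, hue_shift=hue_sign * hue_mag, sat_shift=sat
    )
    return apply_modifications(inst, record), record
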