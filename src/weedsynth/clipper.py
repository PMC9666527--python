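"""Automated plant clipping: from an RGB frame to tight RGBA plant cut-outs.

The pipeline is: ExG vegetation masking (``imaging_core``), connected
component labelling of the foreground, a minimum-area speck filter, and a
tight crop of each surviving component into a 4-band instance. Overlapping
or touching plants merge into one component; no splitting is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .imaging_core import attach_alpha, full_scale, validate_raster, vegetation_mask

__all__ = ["PlantInstance", "clip_image", "extract_instances", "tight_crop"]

#: default speck filter, sized for 2048 x 2048 frames
DEFAULT_MIN_AREA = 100


@dataclass(eq=False)  # raster arrays make field equality ill-defined
class PlantInstance:
    """A tight-cropped RGBA plant cut-out.

    Attributes
    ----------
    raster : ndarray, shape (h, w, 4)
        Unsigned-integer RGBA crop; opaque pixels (alpha > half scale)
        form the plant footprint.
    class_label : str
        One of ``cotton``, ``MG``, ``grass``, or ``unlabeled``. Labels are
        assigned from the declared content of the source image, never
        inferred from pixels.
    source_id : str
        Identifier of the image the instance was clipped from.
    offset : tuple of int
        (row, col) of the crop's top-left corner in the source frame;
        allows bit-exact re-compositing.
    """

    raster: np.ndarray
    class_label: str = "unlabeled"
    source_id: str = ""
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.raster = validate_raster(self.raster, min_channels=3)
        if self.raster.shape[2] != 4:
            raise ValueError("PlantInstance raster must have 4 channels")
        if self.footprint_area == 0:
            raise ValueError("PlantInstance must have at least 1 opaque pixel")

    @property
    def footprint(self) -> np.ndarray:
        """Boolean opaque-pixel mask (alpha above half scale)."""
        return self.raster[..., 3] > full_scale(self.raster) // 2

    @property
    def footprint_area(self) -> int:
        return int(np.count_nonzero(self.raster[..., 3] > full_scale(self.raster) // 2))

    @property
    def height(self) -> int:
        return self.raster.shape[0]

    @property
    def width(self) -> int:
        return self.raster.shape[1]


def tight_crop(rgba: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop an RGBA raster to the bounding box of its opaque pixels.

    Returns the crop and the (row, col) offset of the crop in the input.
    Raises ``ValueError`` when no opaque pixel exists.
    """
    arr = validate_raster(rgba)
    if arr.shape[2] != 4:
        raise ValueError("tight_crop expects a 4-band raster")
    opaque = arr[..., 3] > full_scale(arr) // 2
    rows = np.flatnonzero(opaque.any(axis=1))
    cols = np.flatnonzero(opaque.any(axis=0))
    if rows.size == 0:
        raise ValueError("no opaque pixels to crop to")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return arr[r0:r1, c0:c1], (r0, c0)


def clip_image(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Full-frame RGBA clip: alpha from the ExG/Otsu vegetation mask.

    Equivalent to ``attach_alpha(image, vegetation_mask(image))``; the
    degenerate-input error for vegetation-free frames propagates.
    """
    return attach_alpha(image, vegetation_mask(image, n_bins=n_bins))


def extract_instances(
    image: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
    n_bins: int = 256,
    class_label: str = "unlabeled",
    source_id: str = "",
) -> list[PlantInstance]:
    """Extract one tight-cropped :class:`PlantInstance` per foreground blob.

    Connected components of the vegetation mask with area >= ``min_area``
    are kept; smaller specks are discarded. Instances are returned sorted
    by descending footprint area.

    Parameters
    ----------
    connectivity : {4, 8}
        Pixel adjacency; 8 joins diagonal neighbours (default, suits
        touching leaves), 4 does not.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    arr = validate_raster(image, min_channels=3)
    mask = vegetation_mask(arr, n_bins=n_bins)
    rgba = attach_alpha(arr, mask)
    labels = label(mask, connectivity=1 if connectivity == 4 else 2)
    instances: list[PlantInstance] = []
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        crop = rgba[r0:r1, c0:c1].copy()
        # zero alpha on pixels of other components sharing the bbox
        component = labels[r0:r1, c0:c1] == region.label
        crop[..., 3] = np.where(component, crop[..., 3], 0)
        instances.append(
            PlantInstance(
                raster=crop,
                class_label=class_label,
                source_id=source_id,
                offset=(int(r0), int(c0)),
            )
        )
    instances.sort(key=lambda inst: -inst.footprint_area)
    return instances
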