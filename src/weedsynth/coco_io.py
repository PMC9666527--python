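"""COCO-style annotation sets: containers, (de)serialization, merge, split.

Annotations follow the COCO conventions: 0-based pixel coordinates,
``bbox = [x_min, y_min, width, height]`` with x right / y down, instance
masks as uncompressed run-length encodings (column-major counts, first run
counting zeros) or as polygon vertex lists. The codec here is self
contained and round-trips masks bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "encode_rle",
    "decode_rle",
    "decode_segmentation",
    "mask_to_bbox",
    "write_coco",
    "read_coco",
    "merge_sets",
    "split_set",
]

DEFAULT_CATEGORIES = [
    {"id": 1, "name": "cotton"},
    {"id": 2, "name": "MG"},
    {"id": 3, "name": "grass"},
]


def encode_rle(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed column-major RLE.

    The counts alternate runs of 0s and 1s over the Fortran-order
    flattening of the mask, starting with the 0-run (possibly of length
    zero).
    """
    m = np.asarray(mask, dtype=bool)
    flat = m.ravel(order="F").astype(np.int8)
    if flat.size == 0:
        return {"size": list(m.shape), "counts": [0]}
    boundaries = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], boundaries, [flat.size]]))
    counts = runs.tolist()
    if flat[0] == 1:  # RLE must start with a zero-run
        counts = [0] + counts
    return {"size": [int(m.shape[0]), int(m.shape[1])], "counts": [int(c) for c in counts]}


def decode_rle(rle: dict) -> np.ndarray:
    """Decode an uncompressed column-major RLE back to a boolean mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def polygons_to_mask(polys: list[list[float]], height: int, width: int) -> np.ndarray:
    """Rasterize COCO polygon lists ([x1, y1, x2, y2, ...]) to a mask."""
    mask = np.zeros((height, width), dtype=bool)
    for poly in polys:
        xs = np.asarray(poly[0::2], dtype=float)
        ys = np.asarray(poly[1::2], dtype=float)
        rr, cc = draw_polygon(ys, xs, shape=(height, width))
        mask[rr, cc] = True
    return mask


def decode_segmentation(seg, height: int, width: int) -> np.ndarray:
    """Decode either an RLE dict or a polygon list to a boolean mask."""
    if isinstance(seg, dict):
        return decode_rle(seg)
    if isinstance(seg, list):
        return polygons_to_mask(seg, height, width)
    raise ValueError(f"unsupported segmentation type: {type(seg)!r}")


def mask_to_bbox(mask: np.ndarray) -> list[float]:
    """Tight [x, y, w, h] box of a boolean mask (0-based, half-open)."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return [0.0, 0.0, 0.0, 0.0]
    return [
        float(cols[0]),
        float(rows[0]),
        float(cols[-1] - cols[0] + 1),
        float(rows[-1] - rows[0] + 1),
    ]


@dataclass
class AnnotationSet:
    """A COCO-style ground-truth container.

    ``images`` are dicts with ``id``, ``file_name``, ``height``, ``width``;
    ``annotations`` carry ``id``, ``image_id``, ``category_id``, ``bbox``,
    ``segmentation`` (RLE or polygons), ``area``; ``categories`` are
    ``{"id", "name"}`` records.
    """

    images: list[dict] = field(default_factory=list)
    annotations: list[dict] = field(default_factory=list)
    categories: list[dict] = field(default_factory=lambda: [dict(c) for c in DEFAULT_CATEGORIES])

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def n_annotations(self) -> int:
        return len(self.annotations)

    def category_name(self, category_id: int) -> str:
        for c in self.categories:
            if c["id"] == category_id:
                return c["name"]
        raise KeyError(f"unknown category id {category_id}")

    def validate(self) -> None:
        """Check id uniqueness and referential integrity; raise on violation."""
        image_ids = [im["id"] for im in self.images]
        if len(set(image_ids)) != len(image_ids):
            raise ValueError("duplicate image ids")
        ann_ids = [a["id"] for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise ValueError("duplicate annotation ids")
        cat_ids = {c["id"] for c in self.categories}
        image_id_set = set(image_ids)
        sizes = {im["id"]: (im["height"], im["width"]) for im in self.images}
        for a in self.annotations:
            if a["image_id"] not in image_id_set:
                raise ValueError(
                    f"annotation {a['id']} references missing image_id {a['image_id']}"
                )
            if a["category_id"] not in cat_ids:
                raise ValueError(
                    f"annotation {a['id']} references missing category_id {a['category_id']}"
                )
            seg = a.get("segmentation")
            if seg is not None and "bbox" in a:
                h, w = sizes[a["image_id"]]
                mask = decode_segmentation(seg, h, w)
                tight = mask_to_bbox(mask)
                if any(abs(t - b) > 1.0 for t, b in zip(tight, a["bbox"])):
                    logger.warning(
                        "annotation %s: bbox %s deviates from mask tight box %s by > 1 px",
                        a["id"], a["bbox"], tight,
                    )

    def to_dict(self) -> dict:
        return {
            "images": self.images,
            "annotations": self.annotations,
            "categories": self.categories,
        }


def write_coco(aset: AnnotationSet, path: str | Path) -> None:
    """Write the set as a standard COCO JSON file (deterministic bytes)."""
    aset.validate()
    Path(path).write_text(
        json.dumps(aset.to_dict(), sort_keys=True, separators=(",", ":")) + "\n"
    )


def read_coco(path: str | Path) -> AnnotationSet:
    """Read and validate a COCO JSON file."""
    raw = json.loads(Path(path).read_text())
    aset = AnnotationSet(
        images=raw.get("images", []),
        annotations=raw.get("annotations", []),
        categories=raw.get("categories", []),
    )
    aset.validate()
    return aset


def merge_sets(a: AnnotationSet, b: AnnotationSet) -> AnnotationSet:
    """Merge two sets; ``b``'s ids are re-indexed after ``a``'s maxima.

    Category tables must agree on names; the merged table is ``a``'s.
    Original ids of ``b`` are retained in ``orig_id`` provenance fields.
    Image and annotation counts are strictly additive.
    """
    names_a = {c["name"] for c in a.categories}
    names_b = {c["name"] for c in b.categories}
    if names_a != names_b:
        raise ValueError(f"category name mismatch: {sorted(names_a)} vs {sorted(names_b)}")
    name_to_id = {c["name"]: c["id"] for c in a.categories}
    b_cat_map = {c["id"]: name_to_id[c["name"]] for c in b.categories}

    img_offset = max((im["id"] for im in a.images), default=0)
    ann_offset = max((ann["id"] for ann in a.annotations), default=0)

    images = [dict(im) for im in a.images]
    for im in b.images:
        rec = dict(im)
        rec["orig_id"] = im["id"]
        rec["id"] = im["id"] + img_offset
        images.append(rec)
    annotations = [dict(ann) for ann in a.annotations]
    for ann in b.annotations:
        rec = dict(ann)
        rec["orig_id"] = ann["id"]
        rec["id"] = ann["id"] + ann_offset
        rec["image_id"] = ann["image_id"] + img_offset
        rec["category_id"] = b_cat_map[ann["category_id"]]
        annotations.append(rec)
    merged = AnnotationSet(
        images=images, annotations=annotations, categories=[dict(c) for c in a.categories]
    )
    merged.validate()
    return merged


def split_set(
    aset: AnnotationSet, n_first: int, rng: np.random.Generator
) -> tuple[AnnotationSet, AnnotationSet]:
    """Randomly partition by image into (n_first, rest); annotations follow
    their images. The union reconstructs the original counts exactly.
    """
    n = len(aset.images)
    if not 0 <= n_first <= n:
        raise ValueError(f"n_first={n_first} out of range for {n} images")
    order = rng.permutation(n)
    first_idx = set(order[:n_first].tolist())
    imgs_a = [aset.images[i] for i in range(n) if i in first_idx]
    imgs_b = [aset.images[i] for i in range(n) if i not in first_idx]
    ids_a = {im["id"] for im in imgs_a}
    anns_a = [a for a in aset.annotations if a["image_id"] in ids_a]
    anns_b = [a for a in aset.annotations if a["image_id"] not in ids_a]
    cats = [dict(c) for c in aset.categories]
    return (
        AnnotationSet(images=imgs_a, annotations=anns_a, categories=cats),
        AnnotationSet(images=imgs_b, annotations=anns_b, categories=[dict(c) for c in cats]),
    )
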