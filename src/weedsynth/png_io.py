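"""PNG read/write for 3- and 4-band rasters at 8- or 16-bit depth.

8-bit images go through Pillow. 16-bit colour PNGs need a dedicated code
path: Pillow reads 16-bit RGB(A) files but silently truncates them to
8 bits per sample, which would corrupt high-bit-depth survey imagery.
The codec here handles non-interlaced 16-bit RGB/RGBA with the full set
of scanline filters (None/Sub/Up/Average/Paeth) and writes filter-0
scanlines, zlib-compressed.
"""

from __future__ import annotations

import struct
import zlib
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_png", "write_png"]

_SIGNATURE = b"\x89PNG\r\n\x1a\n"


def _chunk(tag: bytes, data: bytes) -> bytes:
    return (
        struct.pack(">I", len(data))
        + tag
        + data
        + struct.pack(">I", zlib.crc32(tag + data))
    )


def write_png(path: str | Path, image: np.ndarray) -> None:
    """Write an (H, W, 3|4) uint8 or uint16 array as a PNG file."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"expected (H, W, 3|4) array, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        Image.fromarray(arr, mode="RGBA" if arr.shape[2] == 4 else "RGB").save(path)
        return
    if arr.dtype != np.uint16:
        raise ValueError(f"unsupported dtype {arr.dtype}; use uint8 or uint16")
    h, w, c = arr.shape
    color_type = 6 if c == 4 else 2
    ihdr = struct.pack(">IIBBBBB", w, h, 16, color_type, 0, 0, 0)
    big_endian = arr.astype(">u2")
    raw = b"".join(b"\x00" + big_endian[r].tobytes() for r in range(h))
    payload = (
        _SIGNATURE
        + _chunk(b"IHDR", ihdr)
        + _chunk(b"IDAT", zlib.compress(raw, level=6))
        + _chunk(b"IEND", b"")
    )
    Path(path).write_bytes(payload)


def _unfilter(raw: bytes, h: int, w: int, channels: int, bytes_per_sample: int) -> np.ndarray:
    bpp = channels * bytes_per_sample  # filter unit: one full pixel
    stride = w * bpp
    out = np.zeros((h, stride), dtype=np.uint8)
    data = np.frombuffer(raw, dtype=np.uint8)
    if data.size != h * (stride + 1):
        raise ValueError("corrupt PNG: unexpected scanline data size")
    prev = np.zeros(stride, dtype=np.int32)
    for r in range(h):
        line = data[r * (stride + 1) : (r + 1) * (stride + 1)]
        ftype, scan = int(line[0]), line[1:].astype(np.int32)
        if ftype == 0:
            cur = scan
        elif ftype == 2:  # Up
            cur = (scan + prev) & 0xFF
        elif ftype in (1, 3, 4):  # Sub / Average / Paeth need a pixel loop
            cur = np.zeros(stride, dtype=np.int32)
            for i in range(stride):
                a = cur[i - bpp] if i >= bpp else 0
                b = prev[i]
                cc = prev[i - bpp] if i >= bpp else 0
                if ftype == 1:
                    pred = a
                elif ftype == 3:
                    pred = (a + b) // 2
                else:
                    p = a + b - cc
                    pa, pb, pc = abs(p - a), abs(p - b), abs(p - cc)
                    pred = a if pa <= pb and pa <= pc else (b if pb <= pc else cc)
                cur[i] = (scan[i] + pred) & 0xFF
        else:
            raise ValueError(f"unsupported PNG filter type {ftype}")
        out[r] = cur.astype(np.uint8)
        prev = cur
    return out


def read_png(path: str | Path) -> np.ndarray:
    """Read a PNG as an (H, W, 3|4) array, preserving 16-bit samples."""
    blob = Path(path).read_bytes()
    if blob[:8] != _SIGNATURE:
        raise ValueError(f"{path} is not a PNG file")
    w, h, depth, color_type, _comp, _filt, interlace = struct.unpack(
        ">IIBBBBB", blob[16:29]
    )
    if depth == 16 and color_type in (2, 6):
        if interlace != 0:
            raise ValueError("interlaced 16-bit PNGs are not supported")
        channels = 4 if color_type == 6 else 3
        idat = b""
        pos = 8
        while pos < len(blob):
            (length,) = struct.unpack(">I", blob[pos : pos + 4])
            tag = blob[pos + 4 : pos + 8]
            if tag == b"IDAT":
                idat += blob[pos + 8 : pos + 8 + length]
            pos += 12 + length
        raw = zlib.decompress(idat)
        bytes_out = _unfilter(raw, h, w, channels, 2)
        return bytes_out.view(">u2").astype(np.uint16).reshape(h, w, channels)
    img = Image.open(path)
    if img.mode not in ("RGB", "RGBA"):
        img = img.convert("RGBA" if "A" in img.mode else "RGB")
    return np.asarray(img)
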