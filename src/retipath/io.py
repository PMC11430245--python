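"""Image readers and writers.

PNG goes through Pillow. Binary netpbm (P6 PPM, P5 PGM) is written and
read directly so that output bytes are fully deterministic, including the
16-bit offset-encoded PGM used for signed channel maps:

    stored = round(value) + 32768, big-endian uint16

which keeps signed opponent responses in an ordinary grayscale container.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import FormatError

OFFSET_16BIT = 32768


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/PPM/PGM into an HxWx3 uint8 array.

    Grayscale input is replicated into three equal channels. 16-bit or
    paletted input is rejected rather than silently rescaled.
    """
    path = Path(path)
    if path.suffix.lower() in {".ppm", ".pgm", ".pnm"}:
        arr = read_netpbm(path)
    else:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "F"):
                raise FormatError(
                    f"{path}: bit depth of mode {im.mode!r} is not 8-bit; "
                    "only 8-bit-per-channel input is accepted"
                )
            if im.mode == "P":
                im = im.convert("RGB")
            arr = np.asarray(im)
    if arr.dtype == np.uint16:
        raise FormatError(f"{path}: 16-bit samples; only 8-bit input is accepted")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported sample type {arr.dtype}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(
            f"{path}: expected 1, 3 or 4 channels, got shape {arr.shape}"
        )
    return np.ascontiguousarray(arr[:, :, :3])


_PNM_HEADER = re.compile(rb"^(P[56])\s+(?:#.*\s+)*(\d+)\s+(\d+)\s+(\d+)\s")


def read_netpbm(path: str | Path) -> np.ndarray:
    """Read binary PPM (P6) or PGM (P5); returns uint8 or uint16 array."""
    data = Path(path).read_bytes()
    m = _PNM_HEADER.match(data)
    if not m:
        raise FormatError(f"{path}: not a binary P5/P6 netpbm file")
    magic, width, height, maxval = m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4))
    channels = 3 if magic == b"P6" else 1
    dtype = np.dtype(">u2") if maxval > 255 else np.dtype("u1")
    count = width * height * channels
    raster = np.frombuffer(data, dtype=dtype, count=count, offset=m.end())
    if raster.size != count:
        raise FormatError(f"{path}: truncated raster")
    arr = raster.reshape(height, width, channels) if channels == 3 else raster.reshape(height, width)
    return arr.astype(np.uint16) if maxval > 255 else arr.copy()


def write_netpbm(path: str | Path, arr: np.ndarray) -> None:
    """Write uint8 HxWx3 as P6, uint8/uint16 HxW as P5."""
    path = Path(path)
    if arr.ndim == 3:
        if arr.dtype != np.uint8 or arr.shape[2] != 3:
            raise FormatError("P6 output requires uint8 HxWx3")
        magic, maxval, payload = b"P6", 255, arr.astype("u1").tobytes()
    elif arr.ndim == 2:
        if arr.dtype == np.uint8:
            magic, maxval, payload = b"P5", 255, arr.tobytes()
        elif arr.dtype == np.uint16:
            magic, maxval, payload = b"P5", 65535, arr.astype(">u2").tobytes()
        else:
            raise FormatError(f"P5 output requires uint8/uint16, got {arr.dtype}")
    else:
        raise FormatError(f"cannot write array of shape {arr.shape} as netpbm")
    h, w = arr.shape[:2]
    path.write_bytes(magic + b"\n%d %d\n%d\n" % (w, h, maxval) + payload)


def write_png(path: str | Path, arr: np.ndarray) -> None:
    Image.fromarray(arr).save(Path(path), format="PNG")


def write_image(path: str | Path, arr: np.ndarray) -> None:
    """Dispatch on suffix: .png via Pillow, .ppm/.pgm via the netpbm writer."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        write_png(path, arr)
    else:
        write_netpbm(path, arr)


def encode_signed_map(values: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Encode a signed response map as offset uint16 (stored = round(v)+32768).

    Invalid positions encode as exactly OFFSET_16BIT (i.e. value 0).
    """
    enc = np.rint(values).astype(np.int64) + OFFSET_16BIT
    if valid_mask is not None:
        enc = np.where(valid_mask, enc, OFFSET_16BIT)
    if enc.min() < 0 or enc.max() > 65535:
        raise FormatError("signed map exceeds the 16-bit offset encoding range")
    return enc.astype(np.uint16)


def decode_signed_map(stored: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_signed_map` (invalid positions decode to 0)."""
    return stored.astype(np.int64) - OFFSET_16BIT
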