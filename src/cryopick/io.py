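"""Micrograph input/output: frame stacks, normalization, box files, masks.

Cryo-EM movies arrive either as multi-frame MRC stacks (the common archive
format for direct-detector data) or as single-frame 8/16-bit grayscale
images. Frame averaging collapses a stack to one micrograph; z-score
normalization puts micrographs from different sessions on a common intensity
scale before contrast enhancement.

Conventions
-----------
Arrays are indexed row/col (y/x), 0-based, origin at the top-left. Box files
follow the EMAN convention ``x_left y_top width height`` with one particle
per line; here ``y_top`` is measured downward from the top edge.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image

from cryopick.errors import DegenerateInputError, FormatError, InvalidInputError
from cryopick.picks import PickSet

logger = logging.getLogger(__name__)

_MIN_DIM = 32

# MRC modes this reader accepts: int8, int16, float32, uint16
_MRC_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass
class FrameStack:
    """A stack of raw frames from one exposure (n_frames x height x width)."""

    frames: np.ndarray
    pixel_size_angstrom: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidInputError("frames must be a non-empty 3D array")
        if min(self.frames.shape[1:]) < _MIN_DIM:
            raise InvalidInputError(f"frame dimensions must be >= {_MIN_DIM}")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidInputError("frames contain non-finite values")
        if self.pixel_size_angstrom is not None and self.pixel_size_angstrom <= 0:
            raise InvalidInputError("pixel_size_angstrom must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape


@dataclass
class Micrograph:
    """A single 2D micrograph with a declared value range."""

    pixels: np.ndarray
    value_range: Tuple[float, float] = (0.0, 1.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise InvalidInputError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("pixels contain non-finite values")
        lo, hi = self.value_range
        if not lo < hi:
            raise InvalidInputError("value_range must satisfy lo < hi")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray,
                    value_range: Optional[Tuple[float, float]] = None) -> "Micrograph":
        return Micrograph(pixels=pixels,
                          value_range=value_range or self.value_range,
                          source_id=self.source_id)


# ---------------------------------------------------------------------------
# MRC reading/writing (minimal, header-respecting)
# ---------------------------------------------------------------------------

def _parse_mrc_header(header: bytes) -> Tuple[str, int, int, int, int, int]:
    """Return (byteorder, nx, ny, nz, mode, nsymbt) or raise FormatError."""
    if len(header) < 1024:
        raise FormatError(
            f"MRC header truncated: got {len(header)} of 1024 bytes")
    for order in ("<", ">"):
        nx, ny, nz, mode = struct.unpack(order + "4i", header[0:16])
        (nsymbt,) = struct.unpack(order + "i", header[92:96])
        plausible = (
            mode in _MRC_DTYPES
            and 0 < nx < 1 << 20 and 0 < ny < 1 << 20 and 0 < nz < 1 << 20
            and 0 <= nsymbt < 1 << 24
        )
        if plausible:
            return order, nx, ny, nz, mode, nsymbt
    mode_le = struct.unpack("<i", header[12:16])[0]
    raise FormatError(
        f"unsupported or corrupt MRC header (mode word at bytes 12:16 = {mode_le}; "
        f"accepted modes: {sorted(_MRC_DTYPES)})")


def read_mrc_stack(path) -> FrameStack:
    """Read a multi-section MRC file as a frame stack.

    Only the common modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16)
    are accepted; anything else is rejected rather than guessed.
    """
    data = Path(path).read_bytes()
    order, nx, ny, nz, mode, nsymbt = _parse_mrc_header(data[:1024])
    dtype = np.dtype(_MRC_DTYPES[mode]).newbyteorder(order)
    offset = 1024 + nsymbt
    n_expected = nx * ny * nz
    raw = data[offset:offset + n_expected * dtype.itemsize]
    if len(raw) < n_expected * dtype.itemsize:
        raise FormatError(
            f"MRC data truncated at byte {offset + len(raw)}: expected "
            f"{n_expected * dtype.itemsize} data bytes for {nz}x{ny}x{nx} mode {mode}")
    frames = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    return FrameStack(frames=frames.astype(np.float64))


def write_mrc_stack(frames: np.ndarray, path) -> None:
    """Write a float32 (mode 2) little-endian MRC stack."""
    frames = np.ascontiguousarray(np.asarray(frames, dtype=np.float32))
    if frames.ndim == 2:
        frames = frames[None]
    nz, ny, nx = frames.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, float(nx), float(ny), float(nz))
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into("<3f", header, 76, float(frames.min()),
                     float(frames.max()), float(frames.mean()))
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0, 0))  # little-endian machine stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(frames.tobytes())


# ---------------------------------------------------------------------------
# Reading micrographs
# ---------------------------------------------------------------------------

def read_micrograph(path, fmt: str = "auto") -> FrameStack:
    """Read a micrograph file as a FrameStack.

    Single-frame images yield ``n_frames == 1``. Integer pixel data is
    promoted to float without rescaling so the original counts survive.

    Parameters
    ----------
    fmt : {"auto", "mrc_stack", "image"}
        "auto" dispatches on the file suffix (``.mrc``/``.mrcs`` vs common
        image suffixes), falling back to MRC header sniffing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".mrc", ".mrcs", ".map"):
            fmt = "mrc_stack"
        elif suffix in _IMAGE_SUFFIXES:
            fmt = "image"
        else:
            fmt = "mrc_stack" if _sniff_mrc(path) else "image"
    if fmt == "mrc_stack":
        stack = read_mrc_stack(path)
        if stack.frames.size == 0:
            raise InvalidInputError(f"empty stack in {path}")
        return stack
    if fmt == "image":
        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except Exception as exc:  # Pillow raises many codec errors
            raise FormatError(f"cannot decode image {path}: {exc}") from exc
        if arr.ndim == 3:  # collapse RGB(A) to luminance-free mean
            arr = arr[..., :3].mean(axis=2)
        return FrameStack(frames=arr.astype(np.float64)[None])
    raise InvalidInputError(f"unknown format {fmt!r}")


def _sniff_mrc(path) -> bool:
    try:
        _parse_mrc_header(Path(path).read_bytes()[:1024])
        return True
    except FormatError:
        return False


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def average_frames(stack: FrameStack) -> Micrograph:
    """Collapse a frame stack to one micrograph by the per-pixel mean.

    Plain signal averaging suppresses shot noise by ~1/sqrt(n_frames); no
    per-frame alignment is attempted (motion correction is upstream).
    """
    pixels = stack.frames.mean(axis=0)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        hi = lo + 1.0
    return Micrograph(pixels=pixels, value_range=(lo, hi))


def zscore_normalize(img: Micrograph) -> Micrograph:
    """Standardize pixel intensities: x' = (x - mean) / std.

    After this, the (whole-image) mean is 0 and the standard deviation 1,
    so intensities read as sigmas above the noise floor.
    """
    std = float(img.pixels.std())
    if std == 0.0:
        raise DegenerateInputError("constant image: standard deviation is zero")
    pixels = (img.pixels - img.pixels.mean()) / std
    lo, hi = float(pixels.min()), float(pixels.max())
    return img.with_pixels(pixels, value_range=(lo, hi))


def to_unit_range(img: Micrograph) -> Micrograph:
    """Affinely map [min, max] to [0, 1], preserving pixel order."""
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    if hi <= lo:
        raise DegenerateInputError("constant image: cannot map to unit range")
    pixels = (img.pixels - lo) / (hi - lo)
    return img.with_pixels(pixels, value_range=(0.0, 1.0))


# ---------------------------------------------------------------------------
# Box files and masks
# ---------------------------------------------------------------------------

def write_box_file(picks: PickSet, path, box_size: int,
                   image_shape: Optional[Tuple[int, int]] = None,
                   clip_policy: str = "drop") -> int:
    """Write an EMAN-style ``.box`` file; returns the number of records.

    Each line is ``x_left y_top box_size box_size`` with the top-left pixel of
    the image as origin and y increasing downward. Centers convert to corners
    by ``x_left = round(cx - box_size/2)``. With ``clip_policy="drop"`` any
    box that does not lie fully inside ``image_shape`` is dropped and logged;
    with ``"clip"`` it is shifted to fit.
    """
    if box_size <= 0:
        raise InvalidInputError("box_size must be positive")
    if clip_policy not in ("drop", "clip"):
        raise InvalidInputError(f"unknown clip policy {clip_policy!r}")
    lines: List[str] = []
    for p in picks:
        cy, cx = p.center
        x_left = round(cx - box_size / 2)
        y_top = round(cy - box_size / 2)
        if image_shape is not None:
            h, w = image_shape
            inside = 0 <= x_left and x_left + box_size <= w \
                and 0 <= y_top and y_top + box_size <= h
            if not inside:
                if clip_policy == "drop":
                    logger.info("dropping out-of-bounds box at (%d, %d)",
                                x_left, y_top)
                    continue
                x_left = min(max(x_left, 0), w - box_size)
                y_top = min(max(y_top, 0), h - box_size)
        lines.append(f"{x_left}\t{y_top}\t{box_size}\t{box_size}")
    try:
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    except OSError as exc:
        raise InvalidInputError(f"cannot write box file {path}: {exc}") from exc
    return len(lines)


def read_box_file(path) -> List[Tuple[int, int, int, int]]:
    """Parse a ``.box`` file into (x_left, y_top, w, h) integer tuples."""
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"malformed box line: {line!r}")
        records.append(tuple(int(round(float(v))) for v in parts[:4]))
    return records


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (0 background, 255 foreground)."""
    arr = (np.asarray(mask).astype(bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127
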