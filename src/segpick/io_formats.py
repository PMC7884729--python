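"""Micrograph, mask and coordinate I/O.

Formats handled:

* MRC2014 single-image maps (modes 0, 1, 2, 6 read; mode 2 written) for
  motion-corrected micrographs.
* EMAN ``.box`` particle coordinates (lower-left corner ``x y w h`` dialect).
* Minimal RELION coordinate ``.star`` files (``_rlnCoordinateX/Y`` in pixels).
* PNG class-mask images with a fixed four-colour palette.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` = column, ``y`` = row, origin at the top-left of the array as read
from the MRC file.  ``.box`` corners are recovered as ``center - size/2``
and centres as ``corner + size/2``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Micrograph",
    "ParticleSet",
    "ClassMask",
    "FormatError",
    "MASK_PALETTE",
    "CLASS_BACKGROUND",
    "CLASS_PROTEIN",
    "CLASS_ICE",
    "CLASS_CARBON",
    "read_mrc",
    "write_mrc",
    "read_box",
    "write_box",
    "read_star",
    "write_star",
    "read_mask_image",
    "write_mask_image",
]

CLASS_BACKGROUND = 0
CLASS_PROTEIN = 1
CLASS_ICE = 2
CLASS_CARBON = 3

#: label -> RGB colour (background cyan, protein red, ice yellow, carbon green)
MASK_PALETTE = {
    CLASS_BACKGROUND: (0, 255, 255),
    CLASS_PROTEIN: (255, 0, 0),
    CLASS_ICE: (255, 255, 0),
    CLASS_CARBON: (0, 255, 0),
}

N_CLASSES = 4


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


@dataclass
class Micrograph:
    """A single 2D real-valued micrograph.

    Parameters
    ----------
    pixels
        2D array of intensities, row-major (``pixels[y, x]``).
    pixel_size_angstrom
        Physical pixel size in Å/px, if known.
    source_path
        Where the image was read from, if anywhere.
    """

    pixels: np.ndarray
    pixel_size_angstrom: Optional[float] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"micrograph must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph contains non-finite intensities")
        if self.pixel_size_angstrom is not None and self.pixel_size_angstrom <= 0:
            raise ValueError("pixel_size_angstrom must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ParticleSet:
    """Particle centres (x, y) with a common radius and optional scores."""

    centers: np.ndarray
    radius_px: int
    image_shape: tuple[int, int]
    scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        h, w = self.image_shape
        if len(self.centers):
            x, y = self.centers[:, 0], self.centers[:, 1]
            if (x < 0).any() or (y < 0).any() or (x > w - 1).any() or (y > h - 1).any():
                raise ValueError("particle centre outside image bounds")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float).ravel()
            if len(self.scores) != len(self.centers):
                raise ValueError("scores and centers length mismatch")

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class ClassMask:
    """Per-pixel class labels over {background, protein, ice, carbon}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= N_CLASSES):
            raise ValueError("mask labels must lie in {0,1,2,3}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_SIZE = 1024


def read_mrc(path) -> Micrograph:
    """Read a single-section MRC2014 file as a :class:`Micrograph`.

    Accepts data modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16);
    values are converted to float32.  The pixel size is taken from the cell
    dimensions when they are non-zero.
    """
    path = Path(path)
    raw = path.read_bytes()  # missing file raises FileNotFoundError
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: header truncated ({len(raw)} < {_HEADER_SIZE} bytes)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if nx < 1 or ny < 1 or nz < 1:
        raise FormatError(f"{path}: invalid dimensions nx={nx} ny={ny} nz={nz}")
    if mode not in _MRC_DTYPES:
        raise FormatError(f"{path}: unsupported mode {mode}")
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    cella = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if nsymbt < 0:
        raise FormatError(f"{path}: negative nsymbt {nsymbt}")
    dtype = np.dtype(_MRC_DTYPES[mode]).newbyteorder("<")
    n_expected = nx * ny * nz
    offset = _HEADER_SIZE + nsymbt
    available = len(raw) - offset
    if available < n_expected * dtype.itemsize:
        raise FormatError(
            f"{path}: data truncated (need {n_expected * dtype.itemsize} bytes "
            f"after header, found {available})"
        )
    data = np.frombuffer(raw, dtype=dtype, count=n_expected, offset=offset)
    data = data.reshape(nz, ny, nx)[0].astype(np.float32)
    pixel_size = None
    if mx > 0 and cella[0] > 0:
        pixel_size = float(cella[0]) / mx
    return Micrograph(pixels=data, pixel_size_angstrom=pixel_size, source_path=str(path))


def write_mrc(micrograph: Micrograph, path) -> None:
    """Write a micrograph as a mode-2 (float32) MRC2014 file.

    The header is fully deterministic so identical images produce
    byte-identical files.
    """
    px = np.asarray(micrograph.pixels, dtype=np.float32)
    if not np.all(np.isfinite(px)):
        raise ValueError("refusing to write non-finite pixel values")
    ny, nx = px.shape
    apix = micrograph.pixel_size_angstrom or 1.0
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)          # nx ny nz mode
    struct.pack_into("<3i", header, 16, 0, 0, 0)              # nxstart
    struct.pack_into("<3i", header, 28, nx, ny, 1)            # mx my mz
    struct.pack_into("<3f", header, 40, nx * apix, ny * apix, apix)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)     # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)              # mapc mapr maps
    struct.pack_into("<3f", header, 76, float(px.min()), float(px.max()), float(px.mean()))
    struct.pack_into("<i", header, 88, 1)                     # ispg (2D image: 1 is common)
    struct.pack_into("<i", header, 92, 0)                     # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])         # little-endian stamp
    struct.pack_into("<f", header, 216, float(px.std()))      # rms
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(px.astype("<f4").tobytes())


# ---------------------------------------------------------------------------
# EMAN .box
# ---------------------------------------------------------------------------


def write_box(particles: ParticleSet, path, box_size: int) -> None:
    """Write EMAN ``.box`` lines: ``x_corner y_corner box box`` per particle."""
    if box_size < 1:
        raise ValueError("box_size must be >= 1")
    lines = []
    for x, y in particles.centers:
        xc = round(x - box_size / 2)
        yc = round(y - box_size / 2)
        lines.append(f"{xc}\t{yc}\t{box_size}\t{box_size}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_box(path, image_shape: Optional[tuple[int, int]] = None) -> ParticleSet:
    """Read an EMAN ``.box`` file; centres are ``corner + size/2``."""
    path = Path(path)
    centers: list[tuple[float, float]] = []
    box_size = 2
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 4:
            raise FormatError(f"{path}: line {ln}: expected 4 fields, got {len(fields)}")
        try:
            xc, yc, w, h = (float(v) for v in fields[:4])
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln}: non-numeric field") from exc
        box_size = int(w)
        centers.append((xc + w / 2, yc + h / 2))
    if image_shape is None:
        if centers:
            arr = np.array(centers)
            image_shape = (int(arr[:, 1].max()) + box_size, int(arr[:, 0].max()) + box_size)
        else:
            image_shape = (1, 1)
    return ParticleSet(
        centers=np.array(centers, dtype=float).reshape(-1, 2),
        radius_px=max(1, box_size // 2),
        image_shape=image_shape,
    )


# ---------------------------------------------------------------------------
# RELION coordinate .star (minimal dialect: CoordinateX/Y only, pixels)
# ---------------------------------------------------------------------------

_STAR_HEADER = """data_

loop_
_rlnCoordinateX #1
_rlnCoordinateY #2
"""


def write_star(particles: ParticleSet, path) -> None:
    """Write a minimal RELION coordinate STAR file (pixel coordinates, 0-based)."""
    rows = "".join(f"{x:.6f} {y:.6f}\n" for x, y in particles.centers)
    Path(path).write_text(_STAR_HEADER + rows)


def read_star(path, radius_px: int = 1, image_shape: Optional[tuple[int, int]] = None) -> ParticleSet:
    """Read coordinates from a RELION coordinate STAR file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    col_x = col_y = None
    n_cols = 0
    centers: list[tuple[float, float]] = []
    in_loop = False
    for ln, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("data_"):
            continue
        if s == "loop_":
            in_loop = True
            continue
        if s.startswith("_rln"):
            name = s.split()[0]
            if name == "_rlnCoordinateX":
                col_x = n_cols
            elif name == "_rlnCoordinateY":
                col_y = n_cols
            n_cols += 1
            continue
        if in_loop:
            fields = s.split()
            if col_x is None or col_y is None:
                raise FormatError(f"{path}: data row before coordinate columns (line {ln})")
            if len(fields) < n_cols:
                raise FormatError(f"{path}: line {ln}: expected {n_cols} fields, got {len(fields)}")
            try:
                centers.append((float(fields[col_x]), float(fields[col_y])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: non-numeric coordinate") from exc
    if col_x is None or col_y is None:
        raise FormatError(f"{path}: missing _rlnCoordinateX/_rlnCoordinateY columns")
    if image_shape is None:
        if centers:
            arr = np.array(centers)
            image_shape = (int(np.ceil(arr[:, 1].max())) + 1, int(np.ceil(arr[:, 0].max())) + 1)
        else:
            image_shape = (1, 1)
    return ParticleSet(
        centers=np.array(centers, dtype=float).reshape(-1, 2),
        radius_px=radius_px,
        image_shape=image_shape,
    )


# ---------------------------------------------------------------------------
# Class-mask PNG (fixed palette)
# ---------------------------------------------------------------------------


def write_mask_image(mask: ClassMask, path) -> None:
    """Write a class mask as a paletted RGB PNG (lossless)."""
    h, w = mask.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for label, color in MASK_PALETTE.items():
        rgb[mask.labels == label] = color
    iio.imwrite(Path(path), rgb, extension=".png")


def read_mask_image(path) -> ClassMask:
    """Read a palette PNG back into a class mask; unknown colours are errors."""
    rgb = iio.imread(Path(path))
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise FormatError(f"{path}: expected an RGB image")
    rgb = rgb[:, :, :3]
    h, w = rgb.shape[:2]
    labels = np.full((h, w), 255, dtype=np.uint8)
    for label, color in MASK_PALETTE.items():
        labels[np.all(rgb == np.array(color, dtype=np.uint8), axis=2)] = label
    if (labels == 255).any():
        ys, xs = np.nonzero(labels == 255)
        y, x = int(ys[0]), int(xs[0])
        raise FormatError(
            f"{path}: colour {tuple(int(v) for v in rgb[y, x])} at ({x},{y}) is not in the mask palette"
        )
    return ClassMask(labels=labels)
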