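"""Readers and writers for the formats the pipeline touches.

Micrographs come in as single-frame MRC2014 images (modes 0, 1, 2 and the
common unsigned mode 6); particle coordinates go in and out as RELION STAR
coordinate files or EMAN2 ``.box`` files.

Coordinate convention, used uniformly across the package: 0-based pixel
coordinates with the origin at the top-left, ``x`` indexing columns and
``y`` indexing rows.  STAR files are written with ``rlnCoordinateX`` /
``rlnCoordinateY`` in original-micrograph pixels.  ``.box`` files store the
top-left corner of the box; centers are recovered by adding half the box
size per axis.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ContractViolationError, FormatError, UnsupportedInputError

__all__ = [
    "MicrographImage",
    "ParticleSet",
    "read_mrc",
    "write_mrc",
    "read_coords",
    "write_coords",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MicrographImage:
    """A 2-D real-valued micrograph with identity and pixel-size metadata.

    ``pixels`` is row-major: axis 0 is y (rows), axis 1 is x (columns).
    ``original_shape`` records the shape before any resize so coordinates
    can be mapped back; for freshly read images it equals ``pixels.shape``.
    """

    pixels: np.ndarray
    id: str = ""
    pixel_size_A: float | None = None
    original_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ContractViolationError("micrograph pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ContractViolationError("micrograph contains non-finite values")
        if min(self.pixels.shape) < 64:
            raise ContractViolationError("micrograph smaller than 64 px per axis")
        if self.original_shape is None:
            self.original_shape = self.pixels.shape

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ParticleSet:
    """Particle centers (x, y) with a shared radius, in a declared frame.

    ``frame`` is ``"original"`` (native micrograph pixels) or ``"working"``
    (the resized frame the pipeline operates in).  Coordinates are 0-based,
    x = column, y = row.
    """

    centers: np.ndarray
    radius_px: float
    frame: str = "original"
    scores: np.ndarray | None = None
    radii_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 2)
        if self.frame not in ("original", "working"):
            raise ContractViolationError(f"unknown frame {self.frame!r}")
        if not self.radius_px > 0:
            raise ContractViolationError("radius_px must be > 0")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
            if self.scores.shape[0] != len(self):
                raise ContractViolationError("scores length mismatch")
        if self.radii_px is not None:
            self.radii_px = np.asarray(self.radii_px, dtype=np.float64).reshape(-1)
            if self.radii_px.shape[0] != len(self):
                raise ContractViolationError("radii length mismatch")

    def __len__(self) -> int:
        return self.centers.shape[0]


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_SIZE = 1024


def read_mrc(path: str | Path) -> MicrographImage:
    """Read a single 2-D image from an MRC2014 file.

    Supports modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16).
    Stacks and volumes (nz > 1) are rejected.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: file shorter than an MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    map_id = raw[208:212]
    if map_id not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: missing MRC2014 'MAP ' identifier")
    if nz > 1:
        raise UnsupportedInputError(
            f"{path}: contains {nz} sections; only single 2-D images are supported"
        )
    if mode not in _MRC_MODES:
        raise UnsupportedInputError(f"{path}: MRC mode {mode} not supported")
    if nx <= 0 or ny <= 0 or nz <= 0:
        raise FormatError(f"{path}: non-positive dimensions in header")
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    offset = _HEADER_SIZE + nsymbt
    count = nx * ny
    if len(raw) < offset + count * dtype.itemsize:
        raise FormatError(f"{path}: truncated data block")
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    pixels = data.reshape(ny, nx).astype(np.float64)

    # pixel size from cell dimension / sampling, when present
    mx = struct.unpack_from("<i", raw, 28)[0]
    cella_x = struct.unpack_from("<f", raw, 40)[0]
    pixel_size = None
    if mx > 0 and cella_x > 0:
        pixel_size = float(cella_x) / mx
    return MicrographImage(pixels=pixels, id=path.stem, pixel_size_A=pixel_size)


def write_mrc(
    image: MicrographImage | np.ndarray,
    path: str | Path,
    pixel_size_A: float | None = None,
) -> None:
    """Write a 2-D image as a mode-2 (float32) MRC2014 file."""
    if isinstance(image, MicrographImage):
        pixels = image.pixels
        if pixel_size_A is None:
            pixel_size_A = image.pixel_size_A
    else:
        pixels = np.asarray(image, dtype=np.float64)
    if pixels.ndim != 2:
        raise ContractViolationError("only 2-D images can be written")
    ny, nx = pixels.shape
    data = pixels.astype("<f4")
    psize = pixel_size_A if pixel_size_A else 1.0

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)  # nx, ny, nz, mode
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * psize, ny * psize, psize)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 0)  # ispg
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# STAR / .box coordinates
# ---------------------------------------------------------------------------


def _parse_star_coords(text: str, path: Path) -> np.ndarray:
    """Extract (x, y) rows from the first STAR loop carrying coordinates."""
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    n = len(lines)
    while i < n:
        if lines[i] == "loop_":
            i += 1
            columns: list[str] = []
            while i < n and lines[i].startswith("_"):
                columns.append(lines[i].split()[0].lstrip("_"))
                i += 1
            rows: list[list[str]] = []
            while i < n and lines[i] and not lines[i].startswith(("data_", "loop_", "_")):
                if not lines[i].startswith("#"):
                    rows.append(lines[i].split())
                i += 1
            if "rlnCoordinateX" in columns and "rlnCoordinateY" in columns:
                ix = columns.index("rlnCoordinateX")
                iy = columns.index("rlnCoordinateY")
                if not rows:
                    return np.empty((0, 2))
                try:
                    return np.array(
                        [[float(r[ix]), float(r[iy])] for r in rows], dtype=np.float64
                    )
                except (ValueError, IndexError) as exc:
                    raise FormatError(f"{path}: malformed STAR data row") from exc
        else:
            i += 1
    raise FormatError(f"{path}: no loop with rlnCoordinateX/rlnCoordinateY found")


def read_coords(path: str | Path, fmt: str | None = None, radius_px: float = 1.0) -> ParticleSet:
    """Read particle centers from a STAR or ``.box`` file (original frame).

    ``fmt`` defaults to the file extension.  For ``.box`` files the stored
    top-left corners are converted to centers by adding half the box size,
    and the radius is taken as half the box size.
    """
    path = Path(path)
    if fmt is None:
        fmt = "box" if path.suffix.lower() == ".box" else "star"
    if fmt not in ("star", "box"):
        raise ContractViolationError(f"unknown coordinate format {fmt!r}")

    if fmt == "star":
        centers = _parse_star_coords(path.read_text(), path)
        return ParticleSet(centers=centers, radius_px=radius_px, frame="original")

    centers = []
    box_half = radius_px
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: .box line needs 4 columns: {ln!r}")
        try:
            x0, y0, w, h = (float(p) for p in parts[:4])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric .box entry: {ln!r}") from exc
        centers.append([x0 + w / 2.0, y0 + h / 2.0])
        box_half = w / 2.0
    arr = np.array(centers, dtype=np.float64) if centers else np.empty((0, 2))
    return ParticleSet(centers=arr, radius_px=box_half, frame="original")


def write_coords(ps: ParticleSet, path: str | Path, fmt: str | None = None) -> None:
    """Write a ParticleSet as STAR or ``.box``; requires the original frame."""
    path = Path(path)
    if ps.frame != "original":
        raise ContractViolationError(
            "coordinates must be mapped to the original frame before writing"
        )
    if fmt is None:
        fmt = "box" if path.suffix.lower() == ".box" else "star"
    if fmt not in ("star", "box"):
        raise ContractViolationError(f"unknown coordinate format {fmt!r}")

    if fmt == "star":
        lines = [
            "data_particles",
            "",
            "loop_",
            "_rlnCoordinateX #1",
            "_rlnCoordinateY #2",
        ]
        for x, y in ps.centers:
            lines.append(f"{x:.6f} {y:.6f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        box = 2.0 * ps.radius_px
        lines = []
        for x, y in ps.centers:
            lines.append(f"{x - box / 2:.6f} {y - box / 2:.6f} {box:.6f} {box:.6f}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
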