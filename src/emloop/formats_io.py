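"""File formats and data transfer.

Covers the interchange formats the pipeline touches — MRC2014 images and
stacks, multi-page LZW-compressed TIFF movies, per-micrograph box
coordinate files in corner- and center-based dialects — plus EPU-style
session XML metadata extraction and checksum-verified multi-destination
transfer with optional compression.

The MRC reader/writer is a compact MRC2014 implementation: mode 2
(float32) for writing, modes 1 (int16) and 2 accepted on read, with the
pixel size recorded in the cell dimensions.
"""

from __future__ import annotations

import hashlib
import math
import shutil
import struct
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import tifffile

from .types import Box, MovieStack

__all__ = [
    "FormatError",
    "BoxFileError",
    "TransferError",
    "MetadataRecord",
    "TransferReport",
    "DestinationResult",
    "read_mrc",
    "write_mrc",
    "read_movie",
    "compress_stack",
    "decompress_stack",
    "read_boxes",
    "write_boxes",
    "extract_epu_metadata",
    "transfer_file",
]


class FormatError(ValueError):
    """Raised for files that violate a format contract."""


class BoxFileError(FormatError):
    """Raised for malformed box-coordinate files; carries the line number."""


class TransferError(OSError):
    """Raised when a transfer cannot proceed at all (missing source)."""


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

_MRC_HEADER_SIZE = 1024
_MRC_MODE_DTYPES = {1: np.dtype("<i2"), 2: np.dtype("<f4")}


def write_mrc(data: np.ndarray, pixel_size: float, path: Union[str, Path]) -> Path:
    """Write a 2D image or 3D stack as MRC2014 mode 2 (32-bit float).

    The header records the array dimensions and the pixel size (Å/px)
    via the cell dimensions; write followed by read is value-identical.
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        data = data[np.newaxis, :, :]
    if data.ndim != 3:
        raise FormatError("MRC data must be 2D or 3D")
    nz, ny, nx = data.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)                     # mode
    struct.pack_into("<3i", header, 28, nx, ny, nz)           # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * pixel_size,
                     ny * pixel_size, nz * pixel_size)        # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)     # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)              # mapc/r/s
    struct.pack_into("<3f", header, 76, float(data.min()),
                     float(data.max()), float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                     # ispg
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])         # little-endian
    struct.pack_into("<f", header, 216, float(data.std()))
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
    return path


def read_mrc(path: Union[str, Path]) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns ``(array, pixel_size)``.

    Single-section files come back 2D, stacks as (n, h, w).  Modes 1
    (int16) and 2 (float32) are supported; any other mode raises a
    :class:`FormatError` naming the mode.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_SIZE)
        if len(header) < _MRC_HEADER_SIZE:
            raise FormatError(f"{path}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode not in _MRC_MODE_DTYPES:
            raise FormatError(
                f"{path}: unsupported MRC mode {mode} (modes 1 and 2 supported)")
        (mx,) = struct.unpack_from("<i", header, 28)
        (xlen,) = struct.unpack_from("<f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        pixel_size = xlen / mx if mx > 0 and xlen > 0 else 1.0
        fh.seek(_MRC_HEADER_SIZE + nsymbt)
        dtype = _MRC_MODE_DTYPES[mode]
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise FormatError(f"{path}: truncated MRC data block")
    data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    data = data.astype(np.float32) if mode == 1 else np.array(data)
    if nz == 1:
        data = data[0]
    return data, float(pixel_size)


def read_movie(path: Union[str, Path]) -> MovieStack:
    """Read a movie from MRC or (multi-page) TIFF, by extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return decompress_stack(path)
    data, pixel_size = read_mrc(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    return MovieStack(data, pixel_size=pixel_size, micrograph_id=path.stem)


# ---------------------------------------------------------------------------
# TIFF-LZW movie compression
# ---------------------------------------------------------------------------

def compress_stack(movie: Union[MovieStack, np.ndarray],
                   path: Union[str, Path]) -> Path:
    """Write a movie as a multi-page LZW-compressed TIFF (lossless)."""
    frames = movie.frames if isinstance(movie, MovieStack) else np.asarray(movie)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3 or frames.shape[0] < 1 or frames.size == 0:
        raise FormatError("compress_stack requires a non-empty frame stack")
    path = Path(path)
    tifffile.imwrite(path, frames.astype(np.float32), compression="lzw",
                     photometric="minisblack")
    return path


def decompress_stack(path: Union[str, Path]) -> MovieStack:
    """Read a (compressed) multi-page TIFF back into a movie stack."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    return MovieStack(frames, micrograph_id=Path(path).stem)


# ---------------------------------------------------------------------------
# Box coordinate files
# ---------------------------------------------------------------------------

_DIALECTS = ("corner4", "center5")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _fmt(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else repr(float(x))


def write_boxes(boxes: Sequence[Box], path: Union[str, Path],
                dialect: str = "center5") -> Path:
    """Write one micrograph's boxes.

    ``center5`` lines are ``x_center y_center w h confidence``;
    ``corner4`` lines are ``x_corner y_corner w h`` with
    ``corner = center - size/2`` rounded half-up, dropping confidence.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown box dialect {dialect!r}")
    path = Path(path)
    lines = []
    for b in boxes:
        if dialect == "center5":
            lines.append(" ".join([_fmt(b.center_x), _fmt(b.center_y),
                                   str(b.box_size), str(b.box_size),
                                   _fmt(b.confidence)]))
        else:
            cx = _round_half_up(b.center_x - b.box_size / 2)
            cy = _round_half_up(b.center_y - b.box_size / 2)
            lines.append(f"{cx} {cy} {b.box_size} {b.box_size}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_boxes(path: Union[str, Path], dialect: str = "center5",
               micrograph_id: str = "") -> list[Box]:
    """Read a box file; malformed lines raise with their line number."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown box dialect {dialect!r}")
    path = Path(path)
    boxes: list[Box] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if dialect == "center5":
                if len(parts) != 5:
                    raise ValueError("expected 5 fields")
                x, y, w, h, conf = (float(p) for p in parts)
            else:
                if len(parts) != 4:
                    raise ValueError("expected 4 fields")
                cx, cy, w, h = (float(p) for p in parts)
                x, y, conf = cx + w / 2, cy + h / 2, 1.0
        except ValueError as exc:
            raise BoxFileError(f"{path}: line {lineno}: {exc}") from exc
        boxes.append(Box(x, y, int(w), conf, micrograph_id=micrograph_id))
    return boxes


# ---------------------------------------------------------------------------
# EPU session metadata
# ---------------------------------------------------------------------------

@dataclass
class MetadataRecord:
    """Metadata extracted from one acquisition's session XML.

    Every field is optional: a field absent from the document stays
    ``None`` rather than being defaulted.
    """

    stage_x: Optional[float] = None          # µm
    stage_y: Optional[float] = None          # µm
    microscope_defocus: Optional[float] = None  # µm
    applied_defocus: Optional[float] = None     # µm
    pixel_size: Optional[float] = None       # Å/px
    exposure_time: Optional[float] = None    # s
    n_fractions: Optional[int] = None
    image_w: Optional[int] = None            # px
    image_h: Optional[int] = None            # px
    voltage: Optional[float] = None          # kV
    dose: Optional[float] = None             # e/Å²
    phase_plate: Optional[str] = None        # flag or position label
    super_resolution: Optional[bool] = None
    gridsquare: Optional[str] = None
    hole_id: Optional[str] = None
    spotscan_id: Optional[str] = None
    acquisition_time: Optional[str] = None
    beam_tilt_x: Optional[float] = None      # mrad
    beam_tilt_y: Optional[float] = None      # mrad

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if getattr(self, f.name) is not None}


# Tag-localname -> (field, parser).  Matching is namespace-agnostic: only
# the local part of each element tag is compared, so EPU schema-version
# namespace drift does not break extraction.
_EPU_TAG_MAP = {
    "StageX": ("stage_x", float),
    "StageY": ("stage_y", float),
    "MicroscopeDefocus": ("microscope_defocus", float),
    "AppliedDefocus": ("applied_defocus", float),
    "PixelSize": ("pixel_size", float),
    "ExposureTime": ("exposure_time", float),
    "NumberOfFractions": ("n_fractions", int),
    "ImageWidth": ("image_w", int),
    "ImageHeight": ("image_h", int),
    "AccelerationVoltage": ("voltage", float),
    "Dose": ("dose", float),
    "PhasePlate": ("phase_plate", str),
    "SuperResolution": ("super_resolution",
                        lambda s: s.strip().lower() in {"true", "1", "yes"}),
    "GridSquare": ("gridsquare", str),
    "HoleId": ("hole_id", str),
    "SpotScanId": ("spotscan_id", str),
    "AcquisitionTime": ("acquisition_time", str),
    "BeamTiltX": ("beam_tilt_x", float),
    "BeamTiltY": ("beam_tilt_y", float),
}


def extract_epu_metadata(xml_text: str) -> MetadataRecord:
    """Extract acquisition metadata from EPU-style session XML.

    Elements are matched by tag local name against the documented
    tag-to-field mapping; numeric fields must parse to finite numbers.
    """
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:
        raise FormatError(f"malformed session XML: {exc}") from exc
    record = MetadataRecord()
    for elem in root.iter():
        local = elem.tag.rsplit("}", 1)[-1]
        if local in _EPU_TAG_MAP and elem.text is not None:
            name, parser = _EPU_TAG_MAP[local]
            value = parser(elem.text.strip())
            if isinstance(value, float) and not math.isfinite(value):
                raise FormatError(f"non-finite value for {name}: {elem.text!r}")
            setattr(record, name, value)
    if record.n_fractions is not None and record.n_fractions < 1:
        raise FormatError("n_fractions must be >= 1 when present")
    return record


# ---------------------------------------------------------------------------
# Checksum-verified transfer
# ---------------------------------------------------------------------------

_CHECKSUM_ALGORITHM = "sha256"


def _file_checksum(path: Path) -> str:
    digest = hashlib.new(_CHECKSUM_ALGORITHM)
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _pixel_checksum(frames: np.ndarray) -> str:
    return hashlib.new(_CHECKSUM_ALGORITHM,
                       np.ascontiguousarray(frames, dtype="<f4").tobytes()
                       ).hexdigest()


@dataclass
class DestinationResult:
    path: Path
    checksum: str
    algorithm: str
    success: bool
    compressed: bool
    error: Optional[str] = None


@dataclass
class TransferReport:
    source: Path
    destinations: list[DestinationResult] = field(default_factory=list)
    renamed_to: Optional[str] = None
    source_deleted: bool = False

    @property
    def all_succeeded(self) -> bool:
        return bool(self.destinations) and all(d.success for d in self.destinations)


def transfer_file(
    src: Union[str, Path],
    destinations: Sequence[Union[str, Path]],
    compress_for: Sequence[Union[str, Path]] = (),
    rename_to: Optional[str] = None,
    delete_source: bool = False,
) -> TransferReport:
    """Copy ``src`` to every destination directory, verifying each copy.

    Destinations listed in ``compress_for`` receive the movie as a
    lossless TIFF-LZW file instead of a verbatim copy; verification for
    those reads the file back and compares decompressed pixel checksums
    against the source movie.  The source is deleted only when
    ``delete_source`` is set *and* every destination verified — a single
    failure always retains the source.  Re-running with identical
    arguments yields identical destination checksums.
    """
    src = Path(src)
    if not src.exists():
        raise TransferError(f"source does not exist: {src}")
    compress_set = {Path(p) for p in compress_for}
    name = rename_to if rename_to is not None else src.name
    source_checksum = _file_checksum(src)
    report = TransferReport(source=src, renamed_to=rename_to)
    source_movie: Optional[MovieStack] = None
    for dest_dir in destinations:
        dest_dir = Path(dest_dir)
        compressed = dest_dir in compress_set
        target = dest_dir / (Path(name).stem + ".tif" if compressed else name)
        try:
            dest_dir.mkdir(parents=True, exist_ok=True)
            if compressed:
                if source_movie is None:
                    source_movie = read_movie(src)
                compress_stack(source_movie, target)
                back = decompress_stack(target)
                ok = (_pixel_checksum(back.frames)
                      == _pixel_checksum(source_movie.frames))
                checksum = _file_checksum(target)
            else:
                shutil.copy2(src, target)
                checksum = _file_checksum(target)
                ok = checksum == source_checksum
            report.destinations.append(DestinationResult(
                target, checksum, _CHECKSUM_ALGORITHM, ok, compressed,
                None if ok else "checksum mismatch"))
        except OSError as exc:
            report.destinations.append(DestinationResult(
                target, "", _CHECKSUM_ALGORITHM, False, compressed, str(exc)))
    if delete_source and report.all_succeeded:
        src.unlink()
        report.source_deleted = True
    return report
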