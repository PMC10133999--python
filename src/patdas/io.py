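"""Sinogram file formats and image export.

Two sinogram dialects share one plain-text header (``key: value`` lines):

* binary — header followed by an ``end_header`` line and the payload as
  row-major little-endian 32-bit floats; round-trips bit-exactly.
* csv — header lines prefixed with ``#`` followed by one comma-separated
  A-line per row; round-trips to the printed decimal precision.

Headers carry the full acquisition geometry so a file is self-describing.
Unknown header keys are ignored with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import FormatError, ReconImage, ScanGeometry, Sinogram, ValidationError

logger = logging.getLogger(__name__)

_MAGIC_BINARY = "#patdas-sinogram binary"
_MAGIC_CSV = "#patdas-sinogram csv"

_GEOMETRY_KEYS = {
    "n_positions": int,
    "n_samples": int,
    "radius_m": float,
    "angle_step_deg": float,
    "start_angle_deg": float,
    "fs_hz": float,
    "vs_mps": float,
    "time_offset_s": float,
}


def _header_lines(sinogram: Sinogram) -> list[str]:
    g = sinogram.geometry
    return [
        f"n_positions: {g.n_positions}",
        f"n_samples: {g.n_samples}",
        f"radius_m: {g.radius!r}",
        f"angle_step_deg: {g.angle_step!r}",
        f"start_angle_deg: {g.start_angle!r}",
        f"fs_hz: {g.sampling_frequency!r}",
        f"vs_mps: {g.speed_of_sound!r}",
        f"time_offset_s: {g.time_offset!r}",
    ]


def _parse_header(lines: list[str], path) -> ScanGeometry:
    fields: dict[str, float] = {}
    for line in lines:
        if ":" not in line:
            raise FormatError(f"{path}: malformed header line {line!r}")
        key, _, value = line.partition(":")
        key = key.strip()
        if key not in _GEOMETRY_KEYS:
            logger.warning("%s: ignoring unknown header key %r", path, key)
            continue
        try:
            fields[key] = _GEOMETRY_KEYS[key](value.strip())
        except ValueError as exc:
            raise FormatError(f"{path}: bad value for {key}: {value.strip()!r}") from exc
    missing = set(_GEOMETRY_KEYS) - {"start_angle_deg", "time_offset_s"} - set(fields)
    if missing:
        raise FormatError(f"{path}: missing header keys {sorted(missing)}")
    return ScanGeometry(
        radius=fields["radius_m"],
        n_positions=int(fields["n_positions"]),
        angle_step=fields["angle_step_deg"],
        speed_of_sound=fields["vs_mps"],
        sampling_frequency=fields["fs_hz"],
        n_samples=int(fields["n_samples"]),
        start_angle=fields.get("start_angle_deg", 0.0),
        time_offset=fields.get("time_offset_s", 0.0),
    )


def write_sinogram(sinogram: Sinogram, path: str | Path, fmt: str | None = None) -> None:
    """Write a sinogram; ``fmt`` is ``"binary"`` or ``"csv"``.

    When ``fmt`` is omitted it is inferred from the extension: ``.csv``
    selects the text dialect, anything else the binary one.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "binary"
    if fmt == "binary":
        header = "\n".join([_MAGIC_BINARY, *_header_lines(sinogram), "end_header"]) + "\n"
        payload = np.ascontiguousarray(sinogram.data, dtype="<f4").tobytes()
        path.write_bytes(header.encode("ascii") + payload)
    elif fmt == "csv":
        lines = [_MAGIC_CSV] + [f"# {line}" for line in _header_lines(sinogram)]
        for row in sinogram.data:
            lines.append(",".join(f"{v:.9e}" for v in row))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown sinogram format {fmt!r}")


def read_sinogram(path: str | Path) -> Sinogram:
    """Read either sinogram dialect, sniffing the magic line."""
    path = Path(path)
    raw = path.read_bytes()
    first, _, _ = raw.partition(b"\n")
    magic = first.decode("ascii", errors="replace").strip()
    if magic == _MAGIC_BINARY:
        return _read_binary(raw, path)
    if magic == _MAGIC_CSV:
        return _read_csv(raw.decode("ascii"), path)
    raise FormatError(f"{path}: not a patdas sinogram file (magic line {magic!r})")


def _read_binary(raw: bytes, path: Path) -> Sinogram:
    head, sep, rest = raw.partition(b"\nend_header\n")
    if not sep:
        raise FormatError(f"{path}: missing end_header line")
    lines = head.decode("ascii").splitlines()[1:]
    geometry = _parse_header(lines, path)
    expected = geometry.n_positions * geometry.n_samples * 4
    if len(rest) != expected:
        raise FormatError(
            f"{path}: header declares {geometry.n_positions} x {geometry.n_samples} "
            f"float32 values ({expected} bytes) but payload has {len(rest)} bytes"
        )
    data = np.frombuffer(rest, dtype="<f4").reshape(
        geometry.n_positions, geometry.n_samples
    )
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: payload contains non-finite values")
    return Sinogram(data.astype(np.float64), geometry)


def _read_csv(text: str, path: Path) -> Sinogram:
    header_lines: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or lineno == 1:
            continue
        if line.startswith("#"):
            header_lines.append(line.lstrip("# "))
            continue
        try:
            rows.append(np.array(line.split(","), dtype=np.float64))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable row") from exc
    geometry = _parse_header(header_lines, path)
    if len(rows) != geometry.n_positions:
        raise FormatError(
            f"{path}: header declares {geometry.n_positions} rows, found {len(rows)}"
        )
    widths = {row.size for row in rows}
    if widths != {geometry.n_samples}:
        raise FormatError(
            f"{path}: header declares {geometry.n_samples} samples per row, "
            f"found widths {sorted(widths)}"
        )
    data = np.vstack(rows)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: payload contains non-finite values")
    return Sinogram(data, geometry)


def write_image(image: ReconImage, path: str | Path, depth: int = 8) -> None:
    """Export a reconstruction as a grayscale PNG or TIFF.

    Values are mapped linearly, minimum to 0 and maximum to full scale
    (255 or 65535); a constant image maps to all zeros. ``depth`` selects
    8- or 16-bit output.
    """
    path = Path(path)
    if path.suffix.lower() not in (".png", ".tif", ".tiff"):
        raise ValidationError(
            f"unsupported image extension {path.suffix!r} (use .png/.tif/.tiff)"
        )
    if depth not in (8, 16):
        raise ValidationError(f"depth must be 8 or 16, got {depth}")
    values = image.values
    lo, hi = float(values.min()), float(values.max())
    full_scale = 255 if depth == 8 else 65535
    if hi > lo:
        scaled = (values - lo) / (hi - lo) * full_scale
    else:
        scaled = np.zeros_like(values)
    dtype = np.uint8 if depth == 8 else np.uint16
    iio.imwrite(path, np.rint(scaled).astype(dtype))


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image (PNG/TIFF) or CSV matrix as float64."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2)
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:  # collapse any colour channels
        arr = arr.mean(axis=2)
    return arr
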